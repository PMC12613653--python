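"""Stratification of regions into environment types and development stages.

Two orthogonal three-way classifications drive the whole analysis:

* **natural-environment type** I/II/III from population-weighted elevation,
  default cut points 300 m and 950 m;
* **development stage** 1/2/3 from the urbanization rate, default cut
  points 30% and 70% (the classic Northam-curve phases: initial,
  intermediate, advanced).

Boundary values belong to the middle class (300 m -> II, 70% -> 2); the
convention is configurable via the threshold pairs.

Thresholds of this kind are usually derived with the Fisher–Jenks natural
breaks classifier; :func:`jenks_breaks` implements it exactly (dynamic
programming over contiguous partitions of the sorted values, not the
common greedy approximation), and ``assign_strata`` can use it instead of
the fixed cut points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ENV_THRESHOLDS = (300.0, 950.0)  # metres
STAGE_THRESHOLDS = (30.0, 70.0)  # percent urban

#: roman-numeral display names for environment types
ROMAN = {1: "I", 2: "II", 3: "III"}


class ClassificationError(ValueError):
    """A region could not be classified (e.g. missing exposure)."""


# ---------------------------------------------------------------------------
# Fisher–Jenks natural breaks (exact)
# ---------------------------------------------------------------------------

def _prefix_ssd(x: np.ndarray) -> callable:
    """Return ssd(i, j): within-class sum of squared deviations of the
    sorted slice x[i:j], computed from prefix sums in O(1)."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:
        n = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / n

    return ssd


def jenks_breaks(values, k: int) -> np.ndarray:
    """Exact natural-breaks class bounds for ``values`` into ``k`` classes.

    Minimises the total within-class sum of squared deviations over all
    contiguous partitions of the sorted data (dynamic programming; global
    optimum, cost ties broken deterministically toward smaller split
    indices). Returns the k-1 breakpoints, each the maximum value of its
    class.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot split {n} values into {k} classes")
    if k == 1:
        return np.empty(0)

    ssd = _prefix_ssd(x)
    # cost[j][i]: optimal SSD for first i values in j+1 classes
    INF = np.inf
    cost = np.full((k, n + 1), INF)
    split = np.zeros((k, n + 1), dtype=int)
    for i in range(1, n + 1):
        cost[0][i] = ssd(0, i)
    for j in range(1, k):
        for i in range(j + 1, n + 1):
            best, arg = INF, j
            # last class is x[m:i]; scan m ascending and keep strict
            # improvement so ties pick the smallest split -> lexicographically
            # smallest breaks after backtracking from the left
            for m in range(j, i):
                c = cost[j - 1][m] + ssd(m, i)
                if best == INF or c < best - 1e-12 * (1.0 + abs(best)):
                    best, arg = c, m
            cost[j][i] = best
            split[j][i] = arg

    bounds = []
    i = n
    for j in range(k - 1, 0, -1):
        m = split[j][i]
        bounds.append(x[m - 1])  # top of the class ending at m
        i = m
    return np.array(bounds[::-1])


def jenks_assign(values, k: int) -> np.ndarray:
    """Class index (0-based) for each value under the exact Jenks partition."""
    x = np.asarray(values, dtype=float)
    bounds = jenks_breaks(x, k)
    return np.searchsorted(bounds, x, side="left").astype(int)


def within_class_ssd(values, labels) -> float:
    """Total within-class sum of squared deviations for a given labelling."""
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        g = x[labels == lab]
        total += float(np.sum((g - g.mean()) ** 2))
    return total


# ---------------------------------------------------------------------------
# Fixed-threshold classifiers (Table-2-style rules)
# ---------------------------------------------------------------------------

def classify_environment(wdem: float, thresholds=ENV_THRESHOLDS) -> int:
    """Environment type from population-weighted elevation (m):
    below the lower cut -> 1 (I), between the cuts inclusive -> 2 (II),
    above the upper cut -> 3 (III)."""
    lo, hi = thresholds
    if wdem is None or not np.isfinite(wdem):
        raise ClassificationError(f"population-weighted elevation is missing ({wdem!r})")
    if wdem < lo:
        return 1
    if wdem <= hi:
        return 2
    return 3


def classify_stage(urbanization: float, thresholds=STAGE_THRESHOLDS) -> int:
    """Development stage from urbanization rate (%): <lo -> 1 (initial),
    [lo, hi] -> 2 (intermediate), >hi -> 3 (advanced)."""
    if not np.isfinite(urbanization) or not (0.0 <= urbanization <= 100.0):
        raise ValueError(f"urbanization rate must be in [0, 100], got {urbanization!r}")
    lo, hi = thresholds
    if urbanization < lo:
        return 1
    if urbanization <= hi:
        return 2
    return 3


@dataclass(frozen=True)
class StratumAssignment:
    region: int
    year: int
    env_type: int  # 1..3 == I..III
    stage: int     # 1..3


def assign_strata(
    panel: pd.DataFrame,
    env_exposure: "pd.Series | dict",
    mode: str = "fixed",
    env_thresholds=ENV_THRESHOLDS,
    stage_thresholds=STAGE_THRESHOLDS,
) -> pd.DataFrame:
    """Assign (env_type, stage) to every region-year of a panel.

    ``env_exposure`` maps region -> population-weighted elevation (base-year
    weighting); the resulting type is time-invariant per region. The stage is
    recomputed per year from the panel's ``urbanization`` column.

    ``mode="fixed"`` applies the default threshold rules; ``mode="jenks"``
    derives the three environment classes from the exposure values with the
    exact natural-breaks classifier instead.
    """
    exp = pd.Series(dict(env_exposure) if not isinstance(env_exposure, pd.Series)
                    else env_exposure)
    regions = pd.unique(panel["region"])
    missing = sorted(
        int(r) for r in regions if r not in exp.index or not np.isfinite(exp[r])
    )
    if missing:
        raise ClassificationError(
            f"missing population-weighted elevation for regions: {missing}"
        )

    if mode == "fixed":
        env_type = {r: classify_environment(exp[r], env_thresholds) for r in regions}
    elif mode == "jenks":
        vals = exp.loc[regions].to_numpy()
        k = min(3, len(regions))
        cls = jenks_assign(vals, k) + 1
        env_type = dict(zip(regions, (int(c) for c in cls)))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for _, row in panel.sort_values(["region", "year"]).iterrows():
        r, y = int(row["region"]), int(row["year"])
        rows.append(
            {
                "region": r,
                "year": y,
                "env_type": env_type[r],
                "stage": classify_stage(float(row["urbanization"]), stage_thresholds),
            }
        )
    return pd.DataFrame(rows)
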