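"""Scenario projection of life expectancy and inequality metrics.

Given a fitted multilevel model and a scenario covariate table for a
target year, each region's LE is predicted after reclassifying its
development stage from the scenario urbanization rate (the environment
type is carried over unchanged — terrain does not move). The national
figure is the population-weighted mean of the regional projections, with
the interval propagated under cross-region independence of prediction
errors. Convergence or divergence across regions is summarised by a
four-metric inequality panel (range, SD, CV, population-weighted Gini).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import mlm as _mlm
from .stratify import STAGE_THRESHOLDS, classify_stage


def project_regions(
    fit: "_mlm.MLMFit",
    scenario: pd.DataFrame,
    env_types: "pd.Series | dict",
    level: float = 0.95,
    stage_thresholds=STAGE_THRESHOLDS,
) -> pd.DataFrame:
    """Per-region projections for the scenario year.

    ``scenario`` needs one row per region with the model covariates, an
    ``urbanization`` column (used to reclassify the stage) and optionally
    ``population`` (carried through as the aggregation weight);
    ``env_types`` maps region -> environment type.
    """
    env_types = pd.Series(dict(env_types) if not isinstance(env_types, pd.Series)
                          else env_types)
    missing_cov = [c for c in fit.covariates if c not in scenario.columns]
    if missing_cov:
        raise ValueError(f"scenario table lacks model covariates: {missing_cov}")
    missing_env = [r for r in scenario["region"] if r not in env_types.index]
    if missing_env:
        raise ValueError(f"no environment type for regions: {sorted(missing_env)}")

    rows = scenario.copy()
    rows["env_type"] = [int(env_types[r]) for r in rows["region"]]
    rows["stage"] = [
        classify_stage(float(u), stage_thresholds) for u in rows["urbanization"]
    ]
    pred = _mlm.predict(fit, rows, level=level)
    out = pd.DataFrame(
        {
            "region": rows["region"].to_numpy(),
            "year": rows["year"].to_numpy() if "year" in rows else np.nan,
            "le_hat": pred["fit"].to_numpy(),
            "lo": pred["lo"].to_numpy(),
            "hi": pred["hi"].to_numpy(),
            "se": pred["se"].to_numpy(),
            "env_type": rows["env_type"].to_numpy(),
            "stage": rows["stage"].to_numpy(),
        }
    )
    if "population" in rows:
        out["population"] = rows["population"].to_numpy()
    return out


def national_le(
    projections: pd.DataFrame,
    weights=None,
    level: float = 0.95,
) -> dict:
    """Population-weighted national LE with a propagated interval.

    The variance of the weighted mean is sum_i w_i^2 var_i (regional
    prediction errors treated as independent).
    """
    w = np.asarray(
        weights if weights is not None else projections["population"], dtype=float
    )
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("population weights must be nonnegative with positive total")
    w = w / w.sum()
    le = projections["le_hat"].to_numpy(dtype=float)
    se = projections["se"].to_numpy(dtype=float)
    mean = float(w @ le)
    var = float(np.sum((w * se) ** 2))
    z = stats.norm.ppf(0.5 + level / 2.0) if level > 0 else 0.0
    half = z * math.sqrt(var)
    return {"le": mean, "lo": mean - half, "hi": mean + half, "se": math.sqrt(var)}


def decadal_change(le_by_year: pd.Series, step: int = 10) -> pd.DataFrame:
    """Absolute and percent LE change per decade for one region.

    ``le_by_year`` is indexed by year (observed years plus the projection).
    Decade endpoints must both be present; a gap raises.
    """
    years = sorted(int(y) for y in le_by_year.index)
    rows = []
    for y0 in years[:-1]:
        y1 = y0 + step
        if y1 not in years:
            raise ValueError(f"missing decade endpoint {y1} after {y0}")
        le0, le1 = float(le_by_year[y0]), float(le_by_year[y1])
        rows.append(
            {
                "period": f"{y0}-{y1}",
                "start_year": y0,
                "increase_years": le1 - le0,
                "growth_pct": 100.0 * (le1 - le0) / le0,
            }
        )
    return pd.DataFrame(rows)


def inequality_metrics(values, weights=None) -> dict:
    """Cross-region inequality panel: range, SD, CV and weighted Gini.

    SD and CV use the population-weighted mean/variance (divide-by-sum-of-
    weights); the Gini is the population-weighted mean absolute difference
    scaled by twice the weighted mean. All metrics are invariant to weight
    normalisation, and CV and Gini to uniform scaling of the values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 regions")
    if np.any(x <= 0):
        raise ValueError("life expectancy values must be positive")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    w = w / w.sum()

    mean = float(w @ x)
    sd = math.sqrt(float(w @ (x - mean) ** 2))
    gini = float(np.sum(w[:, None] * w[None, :] * np.abs(x[:, None] - x[None, :])))
    gini /= 2.0 * mean
    return {
        "range": float(x.max() - x.min()),
        "sd": sd,
        "cv": sd / mean,
        "gini": gini,
    }
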