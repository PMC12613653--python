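"""Synthetic world generator.

Emulates the statistical structure the analysis assumes — 31 region-like
zones observed at three decadal time points, an elevation-driven
environment typing, an urbanization-driven staging, and a life expectancy
produced *exactly* by the crossed-random-intercepts linear model — while
shipping no real geography or yearbook data. Every artifact is a
deterministic function of a single seed, and the realized group effects
are recorded so recovery tests can compare estimates against truth.

What is emulated: the covariance structure (two crossed group effects plus
i.i.d. residual), covariate drift across decades (development), a static
environment type per region, and population-weighted elevations falling
in the three classification bands in controllable proportions. What is
not: spatial autocorrelation of outcomes, measurement error in
covariates, demographic cohort structure, or real SSP2 trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grids import GridLayer, ZoneMap
from .stratify import classify_environment, classify_stage

DEFAULT_SEED = 20301231

#: per-covariate (low, high, additive drift per decade); units as named
DEFAULT_PROFILE = {
    "gdp_pc": (0.5, 3.0, 2.5),        # 10k currency units per capita
    "urbanization": (15.0, 60.0, 14.0),  # percent, clipped to [0, 100]
    "schooling": (6.0, 10.0, 1.0),    # years
    "physicians": (1.0, 2.5, 0.5),    # per 1,000 population
    "oop": (25.0, 60.0, -8.0),        # out-of-pocket share, percent
    "dependency": (35.0, 55.0, -3.0),  # gross dependency ratio, percent
    "sex_ratio": (100.0, 110.0, -1.0),  # males per 100 females
}

#: fixed-effect truth: five active covariates, the rest null
DEFAULT_BETA = {
    "intercept": 75.0,
    "gdp_pc": 0.30,
    "schooling": 0.80,
    "oop": -0.05,
    "dependency": -0.05,
    "sex_ratio": -0.05,
    "urbanization": 0.0,
    "physicians": 0.0,
    "wdem": 0.0,
    "year": 0.0,
}

#: population-weighted-elevation sampling band per environment type (m);
#: chosen strictly inside the classification bands (<300, [300,950], >950)
ELEV_BANDS = {1: (60.0, 280.0), 2: (320.0, 920.0), 3: (1000.0, 4200.0)}

#: relative population density per environment type (plains dense, plateau sparse)
DENSITY = {1: 100.0, 2: 30.0, 3: 2.0}


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated panel: fixed effects, variance
    components, and the realized group effects."""

    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma2_t: float = 1.0
    sigma2_s: float = 0.5
    sigma2_e: float = 0.25
    u_t: dict = None
    u_s: dict = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if min(self.sigma2_t, self.sigma2_s, self.sigma2_e) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.u_t is None or self.u_s is None:
            rng = np.random.default_rng(self.seed)
            if self.u_t is None:
                self.u_t = {k: float(v) for k, v in zip(
                    (1, 2, 3), rng.normal(0.0, np.sqrt(self.sigma2_t), 3))}
            if self.u_s is None:
                self.u_s = {k: float(v) for k, v in zip(
                    (1, 2, 3), rng.normal(0.0, np.sqrt(self.sigma2_s), 3))}
        self.u_t = {int(k): float(v) for k, v in self.u_t.items()}
        self.u_s = {int(k): float(v) for k, v in self.u_s.items()}


def write_truth(path, truth: SyntheticTruth) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return SyntheticTruth(**doc)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def _type_counts(n_regions: int, type_mix) -> list[int]:
    mix = np.asarray(type_mix, dtype=float)
    if mix.size != 3 or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise ValueError("type_mix must be three nonnegative fractions summing to 1")
    raw = mix * n_regions
    counts = np.floor(raw).astype(int)
    # largest-remainder rounding
    for i in np.argsort(-(raw - counts))[: n_regions - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def make_grids(
    n_regions: int = 31,
    grid_shape: tuple[int, int] = (64, 64),
    type_mix=(0.70, 0.23, 0.07),
    seed: int = DEFAULT_SEED,
):
    """Generate aligned elevation and population rasters plus a zone map.

    Zones are a Voronoi partition of the grid (contiguous under the
    Euclidean metric). Each region is assigned an environment type in the
    ``type_mix`` proportions and its elevations are drawn inside that
    type's classification band, so the population-weighted elevation lands
    in the intended class. Population is positive everywhere, dense on the
    plains and sparse on the plateau.
    """
    nrows, ncols = grid_shape
    if nrows * ncols < 4 * n_regions:
        raise ValueError(
            f"grid {grid_shape} too small for {n_regions} regions "
            f"(need >= {4 * n_regions} cells)"
        )
    rng = np.random.default_rng(seed)

    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    for _attempt in range(100):
        flat = rng.choice(nrows * ncols, size=n_regions, replace=False)
        sr, sc = flat // ncols, flat % ncols
        d2 = (rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2
        labels = np.argmin(d2, axis=2) + 1  # regions are 1-based
        sizes = np.bincount(labels.ravel(), minlength=n_regions + 1)[1:]
        if sizes.min() >= 4:
            break
    else:
        raise RuntimeError("could not draw a Voronoi partition with >= 4 cells/region")

    counts = _type_counts(n_regions, type_mix)
    types = np.repeat([1, 2, 3], counts)
    rng.shuffle(types)
    env_type = {r: int(types[r - 1]) for r in range(1, n_regions + 1)}

    elev = np.zeros(grid_shape)
    pop = np.zeros(grid_shape)
    for r in range(1, n_regions + 1):
        m = labels == r
        lo, hi = ELEV_BANDS[env_type[r]]
        base = rng.uniform(lo, hi)
        cells = rng.normal(base, 15.0, size=int(m.sum()))
        elev[m] = np.clip(cells, lo - 40.0, hi + 40.0)
        pop[m] = rng.gamma(shape=2.0, scale=DENSITY[env_type[r]], size=int(m.sum()))

    return (
        GridLayer(values=elev),
        GridLayer(values=pop),
        ZoneMap(labels=labels),
    )


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def make_panel(
    truth: SyntheticTruth | None = None,
    n_regions: int = 31,
    years=(2000, 2010, 2020),
    covariate_profile: dict | None = None,
    type_mix=(0.70, 0.23, 0.07),
    wdem_by_region: dict | None = None,
) -> pd.DataFrame:
    """Region-year panel whose LE obeys the crossed-effects model exactly.

    Each region gets a time-invariant environment type (and a matching
    population-weighted elevation drawn in the type's band); covariates
    start uniform in their declared ranges and drift by their per-decade
    increments; the stage follows the year's urbanization. LE is the
    linear predictor plus the realized u_t, u_s and a fresh residual.

    When ``wdem_by_region`` is given (e.g. exposures measured on generated
    rasters) the environment types are derived from those values instead of
    ``type_mix``, keeping panel and rasters consistent.
    """
    truth = truth or SyntheticTruth()
    years = list(years)
    if not years:
        raise ValueError("years must be nonempty")
    profile = dict(DEFAULT_PROFILE, **(covariate_profile or {}))
    rng = np.random.default_rng(truth.seed + 1)

    if wdem_by_region is not None:
        if sorted(wdem_by_region) != list(range(1, n_regions + 1)):
            raise ValueError("wdem_by_region must cover regions 1..n_regions")
        types = np.array([
            classify_environment(wdem_by_region[r])
            for r in range(1, n_regions + 1)
        ])
    else:
        counts = _type_counts(n_regions, type_mix)
        types = np.repeat([1, 2, 3], counts)
        rng.shuffle(types)

    rows = []
    for r in range(1, n_regions + 1):
        t = int(types[r - 1])
        lo, hi = ELEV_BANDS[t]
        wdem = (float(wdem_by_region[r]) if wdem_by_region is not None
                else float(rng.uniform(lo, hi)))
        base = {c: rng.uniform(lo_, hi_) for c, (lo_, hi_, _) in profile.items()}
        population = float(rng.lognormal(3.0, 0.8))
        for yr in years:
            decades = (yr - years[0]) / 10.0
            cov = {
                c: base[c] + drift * decades
                for c, (_, _, drift) in profile.items()
            }
            cov["urbanization"] = float(np.clip(cov["urbanization"], 0.0, 100.0))
            stage = classify_stage(cov["urbanization"])
            xbeta = truth.beta.get("intercept", 0.0)
            for name, coef in truth.beta.items():
                if name == "intercept" or coef == 0.0:
                    continue
                if name == "year":
                    xbeta += coef * yr
                elif name == "wdem":
                    xbeta += coef * wdem
                else:
                    xbeta += coef * cov[name]
            le = (
                xbeta
                + truth.u_t[t]
                + truth.u_s[stage]
                + rng.normal(0.0, np.sqrt(truth.sigma2_e))
            )
            rows.append(
                {
                    "region": r,
                    "year": yr,
                    "le": float(le),
                    **{c: float(v) for c, v in cov.items()},
                    "wdem": wdem,
                    "population": population * (1.05 ** decades),
                    "env_type": t,
                    "stage": stage,
                }
            )
    return pd.DataFrame(rows)


def linear_predictor(truth: SyntheticTruth, panel: pd.DataFrame) -> np.ndarray:
    """x'beta for every panel row under the truth's fixed effects."""
    out = np.full(len(panel), truth.beta.get("intercept", 0.0))
    for name, coef in truth.beta.items():
        if name != "intercept" and coef != 0.0:
            out += coef * panel[name].to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# scenario
# ---------------------------------------------------------------------------

def make_scenario(
    panel: pd.DataFrame,
    target_year: int = 2030,
    drift: dict | None = None,
) -> pd.DataFrame:
    """Project the latest panel year's covariates to ``target_year``.

    ``drift`` maps covariate -> total additive increment; the default
    continues each covariate's per-decade drift for the elapsed decades
    (a middle-of-the-road continuation of recent trends). Urbanization is
    clipped to [0, 100] and the stage recomputed; the environment type and
    elevation exposure carry over unchanged.
    """
    last = int(panel["year"].max())
    if target_year <= last:
        raise ValueError(f"target year {target_year} must follow last panel "
                         f"year {last}")
    decades = (target_year - last) / 10.0
    if drift is None:
        drift = {c: d * decades for c, (_, _, d) in DEFAULT_PROFILE.items()}

    rows = []
    for row in panel[panel["year"] == last].sort_values("region").itertuples():
        rec = {"region": int(row.region), "year": target_year}
        for c in DEFAULT_PROFILE:
            rec[c] = float(getattr(row, c) + drift.get(c, 0.0))
        rec["urbanization"] = float(np.clip(rec["urbanization"], 0.0, 100.0))
        rec["stage"] = classify_stage(rec["urbanization"])
        rec["wdem"] = float(row.wdem)
        rec["env_type"] = int(row.env_type)
        rec["population"] = float(row.population * (1.05 ** decades))
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generic crossed design (for estimator recovery/coverage studies)
# ---------------------------------------------------------------------------

def make_crossed_dataset(
    n_t: int = 10,
    n_s: int = 10,
    n_obs: int = 500,
    beta=(70.0, 1.0, -0.5),
    sigma2=(1.0, 0.5, 0.25),
    seed: int = 0,
):
    """Plain crossed two-factor dataset for estimator studies.

    Returns ``(df, truth)`` where df has columns y, x1, x2, t, s and truth
    records beta, the variance components and the realized group effects.
    Group labels are drawn uniformly; larger designs than the 3x3 of the
    default panel make the variance components well identified.
    """
    s2t, s2s, s2e = sigma2
    rng = np.random.default_rng(seed)
    t = rng.integers(0, n_t, n_obs)
    s = rng.integers(0, n_s, n_obs)
    x1 = rng.normal(0.0, 1.0, n_obs)
    x2 = rng.normal(0.0, 1.0, n_obs)
    ut = rng.normal(0.0, np.sqrt(s2t), n_t)
    us = rng.normal(0.0, np.sqrt(s2s), n_s)
    y = beta[0] + beta[1] * x1 + beta[2] * x2 + ut[t] + us[s] \
        + rng.normal(0.0, np.sqrt(s2e), n_obs)
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "t": t, "s": s})
    truth = {
        "beta": np.asarray(beta, dtype=float),
        "sigma2": {"t": s2t, "s": s2s, "resid": s2e},
        "u_t": ut,
        "u_s": us,
    }
    return df, truth
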