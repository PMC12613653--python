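"""Geodetector q-statistic: stratified-heterogeneity variance decomposition.

For an outcome y partitioned into L strata h = 1..L,

    q = 1 - (sum_h N_h * sigma2_h) / (N * sigma2) = 1 - SSW / SST,

where sigma2_h and sigma2 are *population* (divide-by-N) variances, so that
N_h * sigma2_h is exactly the within-stratum sum of squares and the
identity holds for unbalanced strata. q lies in [0, 1] and is read as the
fraction of outcome variance the stratification explains ("deterministic
power"); it is reported as a percent in most applications.

No significance test is attached: only the point statistic is in scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class UndefinedQError(ValueError):
    """q is undefined because the outcome has zero total variance."""


@dataclass
class QResult:
    q: float                  # fraction in [0, 1]
    L: int                    # stratum count
    N: int
    sigma2: float             # population variance of y
    ssw: float                # within-stratum sum of squares
    sst: float                # total sum of squares
    n_h: dict = field(default_factory=dict)
    sigma2_h: dict = field(default_factory=dict)

    @property
    def percent(self) -> str:
        return f"{100.0 * self.q:.1f}%"


def q_statistic(y, strata) -> QResult:
    """Compute the q-statistic of ``y`` under the stratification ``strata``."""
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if y.shape != strata.shape:
        raise ValueError("y and strata must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")

    N = y.size
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        raise UndefinedQError("outcome is constant; q is undefined (SST = 0)")

    labels = pd.unique(strata)
    n_h, sigma2_h = {}, {}
    ssw = 0.0
    for lab in labels:
        g = y[strata == lab]
        n_h[lab] = int(g.size)
        sigma2_h[lab] = float(np.var(g))  # population convention; 0 for singletons
        ssw += g.size * sigma2_h[lab]

    q = 1.0 - ssw / sst
    # guard against roundoff only; q is mathematically in [0, 1]
    q = min(1.0, max(0.0, q))
    return QResult(
        q=q,
        L=len(labels),
        N=N,
        sigma2=sst / N,
        ssw=ssw,
        sst=sst,
        n_h=n_h,
        sigma2_h=sigma2_h,
    )


def q_table(
    panel: pd.DataFrame,
    outcome: str,
    factor_columns: list[str],
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Per-year q-values of ``outcome`` explained by each (categorical) factor.

    Returns a DataFrame with one row per year and one column per factor.
    A degenerate cell (constant outcome or single stratum making q
    undefined) is reported as NaN with a warning, never silently as 0 or 1.
    """
    if years is None:
        years = sorted(panel["year"].unique())
    else:
        absent = [yr for yr in years if yr not in set(panel["year"])]
        if absent:
            raise ValueError(f"years not in panel: {absent}")

    out = pd.DataFrame(index=pd.Index(years, name="year"),
                       columns=factor_columns, dtype=float)
    for yr in years:
        sub = panel[panel["year"] == yr]
        for col in factor_columns:
            try:
                out.loc[yr, col] = q_statistic(sub[outcome], sub[col]).q
            except UndefinedQError as exc:
                logger.warning("q undefined for factor %r in %s: %s", col, yr, exc)
                out.loc[yr, col] = np.nan
    return out
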