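"""Crossed-random-effects linear multilevel model, fitted by REML.

The model for region-year life expectancy y with environment type t and
development stage s is

    y = x'beta + u_t + u_s + e,
    u_t ~ N(0, s2_t),  u_s ~ N(0, s2_s),  e ~ N(0, s2_e),

with the two random intercepts *crossed*: every (type, stage) combination
can occur. The marginal covariance is

    V = s2_t Zt Zt' + s2_s Zs Zs' + s2_e I.

Estimation profiles beta out by GLS and maximises the restricted
likelihood over the variance components on the log scale (Nelder–Mead;
components may collapse to a 1e-10 floor, in which case they are reported
as exactly 0 and the fit is recomputed at the reported values, so the GLS
identity holds at the published V). All linear algebra goes through the
Woodbury identity, so the per-evaluation cost is O(n q^2) for q total
group levels rather than O(n^3).

BLUPs, their conditional covariance, and the cross-covariance between the
fixed-effect estimator and the BLUP errors are retained so that prediction
intervals can use the full joint prediction-error variance (an additive
variance mode that ignores the cross terms is also available, as is a
"new observation" mode that adds the residual variance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-10
#: covariates retained in the default explanatory model for life expectancy
DEFAULT_MODEL = ["gdp_pc", "schooling", "oop", "dependency", "sex_ratio"]


class MLMError(RuntimeError):
    pass


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable fixed-effects design."""


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, response: str, covariates: list[str],
            groups: tuple[str, ...]):
    y = df[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates]
    )
    names = ["intercept"] + list(covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag))
               if diag[i] < 1e-10 * diag[0]] or [names[piv[rank]]]
        raise DesignError(f"collinear fixed-effect columns: {bad}")
    if X.shape[0] <= X.shape[1]:
        raise DesignError("need more observations than fixed-effect columns")

    levels, Zs = {}, {}
    for g in groups:
        lev = sorted(pd.unique(df[g]))
        if len(lev) < 2:
            raise DesignError(f"grouping factor {g!r} needs >= 2 levels, "
                              f"found {lev}")
        idx = {l: i for i, l in enumerate(lev)}
        Z = np.zeros((len(df), len(lev)))
        Z[np.arange(len(df)), [idx[v] for v in df[g]]] = 1.0
        levels[g], Zs[g] = lev, Z
    return y, X, names, Zs, levels


def _profile(s2g: dict[str, float], s2e: float, y, X, Zs):
    """GLS pieces at given variance components via Woodbury.

    Returns beta, vcov_beta, resid, quad = r'V^-1 r, logdetV,
    logdet(X'V^-1 X), and a V^-1 applier.
    """
    n = y.size
    s2e = max(s2e, VAR_FLOOR)
    active = [g for g in Zs if s2g[g] > 0.0]
    if active:
        U = np.hstack([math.sqrt(s2g[g]) * Zs[g] for g in active])
        M = s2e * np.eye(U.shape[1]) + U.T @ U
        cho = np.linalg.cholesky(M)

        def vinv(A):
            UA = U.T @ A
            return (A - U @ np.linalg.solve(cho.T, np.linalg.solve(cho, UA))) / s2e

        logdetV = (n - U.shape[1]) * math.log(s2e) + 2.0 * float(
            np.sum(np.log(np.diag(cho)))
        )
    else:
        def vinv(A):
            return A / s2e

        logdetV = n * math.log(s2e)

    VinvX = vinv(X)
    XtVinvX = X.T @ VinvX
    Vinvy = vinv(y)
    beta = np.linalg.solve(XtVinvX, X.T @ Vinvy)
    vcov = np.linalg.inv(XtVinvX)
    r = y - X @ beta
    quad = float(r @ vinv(r))
    sign, logdetXtVinvX = np.linalg.slogdet(XtVinvX)
    return beta, vcov, r, quad, logdetV, float(logdetXtVinvX), vinv


def _neg2ll(s2g, s2e, y, X, Zs, reml: bool) -> float:
    n, p = X.shape
    _, _, _, quad, logdetV, logdetXtX, _ = _profile(s2g, s2e, y, X, Zs)
    if reml:
        return logdetV + logdetXtX + quad + (n - p) * math.log(2 * math.pi)
    return logdetV + quad + n * math.log(2 * math.pi)


# ---------------------------------------------------------------------------
# the fit object
# ---------------------------------------------------------------------------

@dataclass
class MLMFit:
    beta: pd.Series
    vcov_beta: pd.DataFrame
    sigma2: dict                      # factor -> variance; key "resid" for s2_e
    blups: dict                       # factor -> pd.Series indexed by level
    groups: tuple
    levels: dict
    response: str
    covariates: list
    criterion: float                  # -2 log (restricted) likelihood at optimum
    reml: bool
    converged: bool
    n: int
    n_evals: int = 0
    cond_cov: np.ndarray | None = None    # stacked var(u_hat - u), q x q
    cross_cov: np.ndarray | None = None   # cov(beta_hat, u_hat - u), p x q
    _offsets: dict = field(default_factory=dict)  # factor -> slice into stack

    @property
    def k_params(self) -> int:
        return len(self.beta) + sum(1 for g in self.groups) + 1

    def aic(self) -> float:
        if self.reml:
            raise MLMError("AIC requires an ML fit (reml=False)")
        return self.criterion + 2 * self.k_params

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "covariates": list(self.covariates),
            "groups": list(self.groups),
            "beta": {k: float(v) for k, v in self.beta.items()},
            "sigma2": {k: float(v) for k, v in self.sigma2.items()},
            "blups": {g: {str(k): float(v) for k, v in s.items()}
                      for g, s in self.blups.items()},
            "criterion": float(self.criterion),
            "reml": self.reml,
            "converged": self.converged,
            "n": self.n,
        }


def fit_mlm(
    df: pd.DataFrame,
    response: str = "le",
    covariates: list[str] | None = None,
    groups: tuple[str, ...] = ("env_type", "stage"),
    reml: bool = True,
    fixed_variances: dict | None = None,
    maxiter: int = 4000,
) -> MLMFit:
    """Fit the crossed-random-intercepts model by REML (or ML).

    ``fixed_variances`` pins chosen components, e.g.
    ``{"env_type": 0.0, "stage": 0.0}`` reduces the fit to exact OLS.
    Raises :class:`MLMError` on non-convergence (with the optimizer message)
    and :class:`DesignError` on rank-deficient designs.
    """
    covariates = DEFAULT_MODEL if covariates is None else list(covariates)
    fixed_variances = dict(fixed_variances or {})
    if any(v < 0 for v in fixed_variances.values()):
        raise ValueError("variances cannot be negative")

    y, X, names, Zs, levels = _design(df, response, covariates, groups)
    n, p = X.shape
    free = [g for g in groups if g not in fixed_variances]
    fit_s2e = "resid" not in fixed_variances

    # moment-based start: split the OLS residual variance
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    v0 = max(float(np.var(y - X @ beta0)), 1e-6)
    theta0 = np.log(np.full(len(free) + int(fit_s2e), v0 / (len(groups) + 1.0)))

    # components live on the log scale inside [-23, 23]; exp(-23) < 1e-9 is
    # the de-facto boundary at which a component is declared collapsed
    LOG_LO, LOG_HI = -23.0, 23.0

    def unpack(theta):
        s2g = {g: fixed_variances.get(g, 0.0) for g in groups}
        for i, g in enumerate(free):
            s2g[g] = float(np.exp(np.clip(theta[i], LOG_LO, LOG_HI)))
        s2e = (float(np.exp(np.clip(theta[-1], LOG_LO, LOG_HI))) if fit_s2e
               else float(fixed_variances["resid"]))
        return s2g, max(s2e, VAR_FLOOR)

    n_evals = 0
    if theta0.size:
        def obj(theta):
            nonlocal n_evals
            n_evals += 1
            s2g, s2e = unpack(theta)
            return _neg2ll(s2g, s2e, y, X, Zs, reml)

        bounds = [(LOG_LO, LOG_HI)] * theta0.size
        res = optimize.minimize(obj, theta0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter})
        converged = bool(res.success)
        if not converged:
            # rescue with a simplex pass; numerical gradients can fail the
            # line search near a collapsed-component boundary
            res2 = optimize.minimize(
                obj, res.x, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-9, "fatol": 1e-11},
            )
            if res2.fun <= res.fun:
                res = res2
            converged = bool(res2.success)
        if not converged:
            # a component collapsed to the boundary leaves the objective
            # flat in that direction and both optimizers hit their
            # iteration caps without formally "converging"; accept the
            # point iff a coordinate probe confirms a local minimum
            f0 = res.fun
            at_optimum = True
            for i in range(res.x.size):
                for step in (-0.02, 0.02):
                    probe = res.x.copy()
                    probe[i] += step
                    if obj(probe) < f0 - 1e-8 * (1 + abs(f0)):
                        at_optimum = False
            if not at_optimum:
                raise MLMError(
                    f"REML optimizer did not converge: {res.message} "
                    f"(nfev={res.nfev}, x={res.x})"
                )
            converged = True
        s2g, s2e = unpack(res.x)
    else:
        s2g, s2e = unpack(np.empty(0))
        converged = True

    # snap numerically-collapsed components to exactly 0 and recompute the
    # published fit at the reported variances
    scale = max(float(np.var(y)), 1e-12)
    for g in free:
        if s2g[g] < 1e-8 * scale:
            s2g[g] = 0.0
    beta, vcov, r, quad, logdetV, logdetXtX, vinv = _profile(s2g, s2e, y, X, Zs)
    crit = _neg2ll(s2g, s2e, y, X, Zs, reml)

    # BLUPs and joint prediction-error covariances over the stacked effects
    q_tot = sum(len(levels[g]) for g in groups)
    offsets, pos = {}, 0
    for g in groups:
        offsets[g] = slice(pos, pos + len(levels[g]))
        pos += len(levels[g])
    Zall = np.hstack([Zs[g] for g in groups])
    dvec = np.concatenate([np.full(len(levels[g]), s2g[g]) for g in groups])
    Vinv_r = vinv(r)
    u_hat = dvec * (Zall.T @ Vinv_r)
    VinvZ = vinv(Zall)
    # P = Vinv - Vinv X A X' Vinv ;  var(u_hat - u) = D - D Z'PZ D
    XtVinvZ = X.T @ VinvZ
    ZPZ = Zall.T @ VinvZ - XtVinvZ.T @ vcov @ XtVinvZ
    cond_cov = np.diag(dvec) - (dvec[:, None] * ZPZ) * dvec[None, :]
    cross_cov = -vcov @ XtVinvZ * dvec[None, :]

    blups = {
        g: pd.Series(u_hat[offsets[g]], index=levels[g], name=g) for g in groups
    }
    sigma2 = {g: s2g[g] for g in groups}
    sigma2["resid"] = s2e

    return MLMFit(
        beta=pd.Series(beta, index=names),
        vcov_beta=pd.DataFrame(vcov, index=names, columns=names),
        sigma2=sigma2,
        blups=blups,
        groups=tuple(groups),
        levels=levels,
        response=response,
        covariates=covariates,
        criterion=crit,
        reml=reml,
        converged=converged,
        n=n,
        n_evals=n_evals,
        cond_cov=cond_cov,
        cross_cov=cross_cov,
        _offsets=offsets,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(
    fit: MLMFit,
    newdata: pd.DataFrame,
    level: float = 0.95,
    mode: str = "mean",
    cov_mode: str = "joint",
) -> pd.DataFrame:
    """Predict the response for new rows with covariates and group labels.

    Point prediction is x'beta + BLUP_t + BLUP_s. The interval at ``level``
    uses the joint prediction-error variance (fixed-effect covariance,
    BLUP conditional covariance, and their cross term); ``cov_mode=
    "additive"`` drops the cross terms. ``mode="new_observation"`` adds the
    residual variance for a realized (not expected) response. Rows naming
    an unseen group level fall back to fixed-effects-only prediction with
    the full prior variance of that effect added (and a warning).
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("interval level must be in [0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0) if level > 0 else 0.0

    p = len(fit.beta)
    rows = []
    for _, row in newdata.iterrows():
        x = np.concatenate(
            [[1.0], [float(row[c]) for c in fit.covariates]]
        )
        point = float(x @ fit.beta.to_numpy())
        var = float(x @ fit.vcov_beta.to_numpy() @ x)
        m = np.zeros(fit.cond_cov.shape[0])
        extra = 0.0
        for g in fit.groups:
            lev = row[g]
            if lev in fit.levels[g]:
                j = fit.levels[g].index(lev)
                point += float(fit.blups[g].iloc[j])
                m[fit._offsets[g].start + j] = 1.0
            else:
                logger.warning(
                    "unknown %s level %r: fixed-effects-only prediction "
                    "with widened interval", g, lev
                )
                extra += fit.sigma2[g]
        if cov_mode == "joint":
            var += float(m @ fit.cond_cov @ m) + 2.0 * float(x @ fit.cross_cov @ m)
        elif cov_mode == "additive":
            var += float(m @ (np.diag(np.diag(fit.cond_cov))) @ m)
        else:
            raise ValueError(f"unknown cov_mode {cov_mode!r}")
        var += extra
        if mode == "new_observation":
            var += fit.sigma2["resid"]
        elif mode != "mean":
            raise ValueError(f"unknown mode {mode!r}")
        var = max(var, 0.0)
        half = z * math.sqrt(var)
        rows.append({"fit": point, "lo": point - half, "hi": point + half,
                     "se": math.sqrt(var)})
    return pd.DataFrame(rows, index=newdata.index)


# ---------------------------------------------------------------------------
# stepwise covariate selection
# ---------------------------------------------------------------------------

def stepwise_select(
    df: pd.DataFrame,
    response: str = "le",
    candidates: list[str] | None = None,
    groups: tuple[str, ...] = ("env_type", "stage"),
    criterion: str = "aic",
) -> tuple[list[str], list[dict]]:
    """Forward–backward covariate selection on ML fits scored by AIC.

    Deterministic given the panel: candidates are probed in their given
    order and a move is taken only if it strictly improves the score.
    Returns the selected columns (in inclusion order) and a trace of every
    accepted move. ``criterion="bic"`` substitutes the BIC penalty.
    """
    if candidates is None:
        candidates = DEFAULT_MODEL + ["urbanization", "physicians", "wdem", "year"]
    if not candidates:
        raise ValueError("need at least one candidate covariate")

    def score(cols):
        fit = fit_mlm(df, response, cols, groups, reml=False)
        if criterion == "aic":
            return fit.aic()
        if criterion == "bic":
            return fit.criterion + math.log(fit.n) * fit.k_params
        raise ValueError(f"unknown criterion {criterion!r}")

    selected: list[str] = []
    current = score(selected)
    trace = [{"action": "start", "column": None, "score": current}]
    improved = True
    while improved:
        improved = False
        best_move, best_score = None, current
        for col in candidates:
            if col in selected:
                continue
            try:
                s = score(selected + [col])
            except DesignError:
                continue
            if s < best_score - 1e-6:
                best_move, best_score = ("add", col), s
        for col in selected:
            s = score([c for c in selected if c != col])
            if s < best_score - 1e-6:
                best_move, best_score = ("drop", col), s
        if best_move is not None:
            action, col = best_move
            if action == "add":
                selected.append(col)
            else:
                selected.remove(col)
            current = best_score
            trace.append({"action": action, "column": col, "score": current})
            improved = True
    if not selected and all_collinear(df, candidates):
        raise DesignError("all candidate covariates are collinear")
    return selected, trace


def all_collinear(df: pd.DataFrame, candidates: list[str]) -> bool:
    X = np.column_stack([np.ones(len(df))] +
                        [df[c].to_numpy(float) for c in candidates])
    return np.linalg.matrix_rank(X) <= 1


# ---------------------------------------------------------------------------
# cross-validation against pooled OLS
# ---------------------------------------------------------------------------

def cross_validate(
    df: pd.DataFrame,
    response: str = "le",
    covariates: list[str] | None = None,
    groups: tuple[str, ...] = ("env_type", "stage"),
    n_folds: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Grouped-by-region out-of-fold comparison of the multilevel model
    against pooled linear regression.

    ``n_folds=None`` means leave-one-region-out. MLM predictions for
    held-out rows use BLUPs estimated from the training fold; a row whose
    (type, stage) cell is unobserved in training falls back to
    fixed-effects-only prediction (logged by :func:`predict`). Returns a
    table with RMSE and MAE per specification, plus per-row predictions as
    ``.attrs["predictions"]``.
    """
    covariates = DEFAULT_MODEL if covariates is None else list(covariates)
    regions = sorted(pd.unique(df["region"]))
    if n_folds is None:
        n_folds = len(regions)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(regions))
    fold_of = {regions[i]: int(perm[i] % n_folds) for i in range(len(regions))}

    pred_mlm = pd.Series(index=df.index, dtype=float)
    pred_ols = pd.Series(index=df.index, dtype=float)
    for fold in range(n_folds):
        test_mask = df["region"].map(fold_of) == fold
        train, test = df[~test_mask], df[test_mask]
        if test.empty:
            continue
        fit = fit_mlm(train, response, covariates, groups)
        pred_mlm.loc[test.index] = predict(fit, test, level=0.0)["fit"].to_numpy()

        Xtr = np.column_stack([np.ones(len(train))] +
                              [train[c].to_numpy(float) for c in covariates])
        b, *_ = np.linalg.lstsq(Xtr, train[response].to_numpy(float), rcond=None)
        Xte = np.column_stack([np.ones(len(test))] +
                              [test[c].to_numpy(float) for c in covariates])
        pred_ols.loc[test.index] = Xte @ b

    y = df[response].to_numpy(float)
    out = pd.DataFrame(
        {
            "rmse": [
                float(np.sqrt(np.mean((y - pred_mlm.to_numpy()) ** 2))),
                float(np.sqrt(np.mean((y - pred_ols.to_numpy()) ** 2))),
            ],
            "mae": [
                float(np.mean(np.abs(y - pred_mlm.to_numpy()))),
                float(np.mean(np.abs(y - pred_ols.to_numpy()))),
            ],
        },
        index=pd.Index(["mlm", "ols"], name="model"),
    )
    out.attrs["predictions"] = pd.DataFrame(
        {"mlm": pred_mlm, "ols": pred_ols, "observed": y}, index=df.index
    )
    out.attrs["folds"] = fold_of
    return out
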