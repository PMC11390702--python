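"""Mixed-effects modelling of monthly richness and hierarchical partitioning.

Monthly flowering richness (log-transformed) is modelled as a function of the
log-transformed null-model prediction and three climate covariates — mean
minimum monthly temperature, mean monthly precipitation and mean monthly
sunshine duration — with a random intercept per region, fitted by REML
(statsmodels MixedLM; the lme4::lmer analogue). Multicollinearity is screened
with variance inflation factors. Each predictor's individual contribution is
obtained by hierarchical partitioning of the model's marginal R^2: all
fixed-effect subsets are fitted (random intercept always retained) and the
R^2 increment from adding a predictor is averaged over all orderings of entry
(the glmm.hp approach). Marginal R^2 is the fixed-effects variance over the
sum of fixed, random-intercept and residual variances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .flora import ClimateRecord, RichnessCurve
from .null_model import MdePrediction

PREDICTORS = ("log_mde", "t_min", "mmp", "sunshine")

_T_CAP = 1e6  # cap for t statistics when the residual variance degenerates
_OPTIMIZERS = ("lbfgs", "bfgs", "powell", "nm")


@dataclass(frozen=True)
class ModelFrame:
    """Model-ready rows: one per (region, domain month).

    response is log richness; predictors default to the log null-model mean
    plus the three climate covariates. At least 2 regions are required for the
    random intercept to be estimable.
    """

    data: pd.DataFrame
    predictors: tuple[str, ...] = PREDICTORS
    response: str = "log_richness"
    group_col: str = "region"

    def __post_init__(self) -> None:
        cols = [self.response, *self.predictors, self.group_col]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"frame missing columns: {missing}")
        numeric = self.data[[self.response, *self.predictors]]
        if not np.all(np.isfinite(numeric.to_numpy(dtype=float))):
            raise ValueError("frame contains non-finite values")
        if self.data[self.group_col].nunique() < 2:
            raise ValueError("need >= 2 regions for a random intercept")

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_groups(self) -> int:
        return self.data[self.group_col].nunique()


@dataclass(frozen=True)
class LmmResult:
    """Fixed-effect estimates and variance components from the REML fit."""

    params: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    var_region: float
    var_resid: float
    marginal_r2: float
    conditional_r2: float
    df_resid: int
    singular: bool


@dataclass(frozen=True)
class PartitionResult:
    """Per-predictor diagnostics and individual contributions (the published
    table-2 shape): t, p, VIF and I.perc, plus the full model's marginal R^2."""

    predictors: tuple[str, ...]
    t: dict[str, float]
    p: dict[str, float]
    vif: dict[str, float]
    contributions: dict[str, float]  # R^2 units; sum equals marginal_r2
    i_perc: dict[str, float]  # percentages; sum to 100
    marginal_r2: float
    singular: bool = False


# ---------------------------------------------------------------------------
# Frame assembly
# ---------------------------------------------------------------------------


def assemble_frame(
    richness: Mapping[str, RichnessCurve],
    predictions: Mapping[str, MdePrediction],
    climate: Iterable[ClimateRecord],
    offset: float = 1.0,
    predictors: tuple[str, ...] = PREDICTORS,
) -> ModelFrame:
    """Build the model frame from per-region curves, predictions and climate.

    response = ln(observed + offset); log_mde = ln(null mean + offset). Rows
    exist only for months inside each region's domain; a domain month with no
    climate record is an error listing the gaps.
    """
    clim: dict[tuple[str, int], ClimateRecord] = {}
    for rec in climate:
        clim[(rec.region_id, rec.month)] = rec
    rows = []
    gaps = []
    for region, curve in richness.items():
        pred = predictions[region]
        if pred.domain != curve.domain:
            raise ValueError(f"{region}: prediction domain differs from observed domain")
        for i, month in enumerate(curve.domain.months()):
            c = clim.get((region, month))
            if c is None:
                gaps.append((region, month))
                continue
            obs = curve.counts[i] + offset
            mde = pred.mean[i] + offset
            if obs <= 0 or mde <= 0:
                raise ValueError(
                    f"{region} month {month}: nonpositive value under log "
                    f"(observed+offset={obs}, mde+offset={mde})"
                )
            rows.append(
                {
                    "region": region,
                    "month": month,
                    "log_richness": math.log(obs),
                    "log_mde": math.log(mde),
                    "t_min": c.t_min,
                    "mmp": c.mmp,
                    "sunshine": c.sunshine,
                }
            )
    if gaps:
        raise ValueError(f"missing climate months: {gaps}")
    return ModelFrame(data=pd.DataFrame(rows), predictors=predictors)


# ---------------------------------------------------------------------------
# REML fitting
# ---------------------------------------------------------------------------


def _full_rank_columns(X: np.ndarray) -> list[int]:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if X.shape[1] == 0:
        return []
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return sorted(piv[:rank])


class _DegenerateFit:
    """Least-squares stand-in used when REML degenerates (e.g. a noise-free
    response): fixed effects are the OLS projection, variance components the
    residual moments (zero random-intercept variance)."""

    def __init__(self, y: np.ndarray, X: np.ndarray):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        n, p = X.shape
        scale = float(resid @ resid) / max(n - p, 1)
        self.fe_params = beta
        self.scale = scale
        self.cov_re = np.zeros((1, 1))
        XtX_inv = np.linalg.pinv(X.T @ X)
        self.bse_fe = np.sqrt(np.maximum(np.diag(XtX_inv) * scale, 0.0))


def _fit_mixedlm(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """REML MixedLM fit with optimizer fallbacks; returns the fitted result.

    A response that the fixed effects reproduce (near-)exactly leaves REML
    nothing to estimate; such fits fall back to the least-squares projection
    with zero variance components.
    """
    import statsmodels.api as sm

    # near-exact fixed-effect fit: REML surface is degenerate
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss_resid = float(np.sum((y - X @ beta) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0 or ss_resid <= 1e-12 * ss_tot:
        return _DegenerateFit(y, X)
    # an optimizer can report convergence at a spurious point (e.g. lbfgs
    # pinning the intercept at zero on boundary fits), so fit with the first
    # two methods and keep the best restricted log-likelihood; the remaining
    # methods are fallbacks only
    last_exc: Exception | None = None
    candidates = []
    for i, method in enumerate(_OPTIMIZERS):
        if i >= 2 and candidates:
            break
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=groups)
                res = model.fit(reml=True, method=method, maxiter=200)
            if np.all(np.isfinite(res.fe_params)) and np.isfinite(res.llf):
                candidates.append(res)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    if candidates:
        return max(candidates, key=lambda r: r.llf)
    raise RuntimeError(f"mixed model failed to converge: {last_exc}")


def _variance_components(res, X: np.ndarray) -> tuple[float, float, float]:
    """(var_fixed, var_region, var_resid) with var_fixed the population
    variance of the fixed-effects fitted values (Nakagawa decomposition)."""
    fitted_fixed = X @ res.fe_params
    var_f = float(np.var(fitted_fixed))
    var_re = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    var_resid = float(res.scale)
    return var_f, max(var_re, 0.0), var_resid


def fit_lmm(frame: ModelFrame, predictors: Sequence[str] | None = None) -> LmmResult:
    """REML linear mixed model with random intercept per region.

    t = estimate / SE; p is two-sided from a t distribution on n - p residual
    degrees of freedom (p counts fixed effects including the intercept) — a
    residual-df approximation, recorded in the result. A degenerate residual
    variance (response fully explained) caps |t| at 1e6 with p -> 0. A
    boundary (zero) random-intercept variance sets ``singular=True`` rather
    than raising.
    """
    preds = tuple(predictors) if predictors is not None else frame.predictors
    df = frame.data
    y = df[frame.response].to_numpy(dtype=float)
    Xp = df[list(preds)].to_numpy(dtype=float) if preds else np.empty((len(df), 0))
    keep = _full_rank_columns(Xp)
    if len(keep) < Xp.shape[1]:
        raise ValueError("fixed design is rank deficient; drop collinear predictors")
    X = np.column_stack([np.ones(len(df)), Xp])
    names = ["intercept", *preds]
    groups = df[frame.group_col].to_numpy()
    res = _fit_mixedlm(y, X, groups)
    var_f, var_re, var_resid = _variance_components(res, X)
    denom = var_f + var_re + var_resid
    marginal = var_f / denom if denom > 0 else 0.0
    conditional = (var_f + var_re) / denom if denom > 0 else 0.0
    df_resid = max(int(len(df) - X.shape[1]), 1)
    params, se, tstat, pval = {}, {}, {}, {}
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bse = np.asarray(res.bse_fe)
    for j, name in enumerate(names):
        est = float(res.fe_params[j])
        s = float(bse[j])
        if not np.isfinite(s) or s <= 0 or abs(est) / max(s, 1e-300) > _T_CAP:
            t_j = math.copysign(_T_CAP, est) if est != 0 else 0.0
        else:
            t_j = est / s
        params[name], se[name], tstat[name] = est, s, t_j
        pval[name] = float(2.0 * stats.t.sf(abs(t_j), df_resid))
    singular = var_re <= 1e-10 * max(var_resid, 1e-300) or var_resid <= 1e-12 * max(denom, 1e-300)
    return LmmResult(
        params=params,
        se=se,
        t=tstat,
        p=pval,
        var_region=var_re,
        var_resid=var_resid,
        marginal_r2=marginal,
        conditional_r2=conditional,
        df_resid=df_resid,
        singular=singular,
    )


# ---------------------------------------------------------------------------
# Collinearity diagnostics
# ---------------------------------------------------------------------------


def compute_vif(frame: ModelFrame, predictors: Sequence[str] | None = None) -> dict[str, float]:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j) from OLS of
    predictor j on the remaining predictors (with intercept)."""
    preds = tuple(predictors) if predictors is not None else frame.predictors
    if len(preds) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = frame.data[list(preds)].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(preds):
        others = np.column_stack(
            [np.ones(len(X)), np.delete(X, j, axis=1)]
        )
        yj = X[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError(f"predictor {name} is constant")
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        if r2 >= 1.0 - 1e-12:
            raise ValueError(f"infinite VIF: predictor {name} is perfectly collinear")
        out[name] = 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# Hierarchical partitioning
# ---------------------------------------------------------------------------


def _subset_r2(frame: ModelFrame, subset: tuple[str, ...], conditional: bool) -> float:
    """Marginal (or conditional) R^2 of the mixed model with the given fixed
    predictors; the random intercept is always retained. Collinear columns
    within the subset are reduced to a full-rank basis (fitted values, and
    hence R^2, are unchanged)."""
    df = frame.data
    y = df[frame.response].to_numpy(dtype=float)
    groups = df[frame.group_col].to_numpy()
    Xp = df[list(subset)].to_numpy(dtype=float) if subset else np.empty((len(df), 0))
    keep = _full_rank_columns(Xp)
    X = np.column_stack([np.ones(len(df)), Xp[:, keep]]) if keep else np.ones((len(df), 1))
    try:
        res = _fit_mixedlm(y, X, groups)
    except RuntimeError as exc:
        raise RuntimeError(f"submodel {subset or '(intercept)'} failed: {exc}") from exc
    var_f, var_re, var_resid = _variance_components(res, X)
    denom = var_f + var_re + var_resid
    if denom <= 0:
        return 0.0
    return (var_f + var_re) / denom if conditional else var_f / denom


def hierarchical_partition(
    frame: ModelFrame,
    predictors: Sequence[str] | None = None,
    conditional: bool = False,
) -> PartitionResult:
    """Average marginal-R^2 increments over all orderings of predictor entry.

    For k predictors, all 2^k - 1 non-empty fixed-effect subsets are fitted
    (k <= 6). Predictor j's contribution is

        I_j = sum over subsets S not containing j of
              |S|! (k - |S| - 1)! / k! * (R^2(S + j) - R^2(S)),

    with R^2(empty) = 0, so the contributions telescope to the full model's
    marginal R^2. I.perc is each contribution as a percent of their sum.
    """
    preds = tuple(predictors) if predictors is not None else frame.predictors
    k = len(preds)
    if k == 0:
        raise ValueError("no predictors to partition")
    if k > 6:
        raise ValueError(f"{k} predictors would need {2**k} submodels; limit is 6")
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, k + 1):
        for subset in combinations(preds, size):
            r2[frozenset(subset)] = _subset_r2(frame, subset, conditional)
    fact = [math.factorial(i) for i in range(k + 1)]
    contrib: dict[str, float] = {}
    for j in preds:
        others = [p for p in preds if p != j]
        total = 0.0
        for size in range(0, k):
            w = fact[size] * fact[k - size - 1] / fact[k]
            for subset in combinations(others, size):
                s = frozenset(subset)
                total += w * (r2[s | {j}] - r2[s])
        contrib[j] = total
    full_r2 = r2[frozenset(preds)]
    pos_total = sum(contrib.values())
    if pos_total <= 0:
        i_perc = {p: 100.0 / k for p in preds}
    else:
        i_perc = {p: 100.0 * c / pos_total for p, c in contrib.items()}
    if k >= 2:
        try:
            vif = compute_vif(frame, preds)
        except ValueError:
            vif = {p: float("inf") for p in preds}
    else:
        vif = {preds[0]: 1.0}
    try:
        lmm = fit_lmm(frame, preds)
        t = {p: lmm.t[p] for p in preds}
        pvals = {p: lmm.p[p] for p in preds}
        singular = lmm.singular
    except ValueError:
        # full fixed design rank deficient (e.g. duplicated predictors):
        # per-predictor t/p are undefined; the partition itself is still valid
        t = {p: float("nan") for p in preds}
        pvals = {p: float("nan") for p in preds}
        singular = True
    return PartitionResult(
        predictors=preds,
        t=t,
        p=pvals,
        vif=vif,
        contributions=contrib,
        i_perc=i_perc,
        marginal_r2=full_r2,
        singular=singular,
    )
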