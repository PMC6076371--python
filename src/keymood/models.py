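"""Severity models: outcome transforms, predictor scaling, random-intercept
mixed-effects and OLS fits, and the associated fit statistics.

Two outcomes are modeled: the raw 17-item HDRS score and ln(YMRS + 1) (the
log transform removes the right-tailed skew of raw YMRS scores). The seven
weekly typing features enter as fixed effects after pooled z-scaling, so
coefficients read as "outcome units per SD of predictor". The mixed model
adds a Normal(0, sigma_u^2) random intercept per subject and is estimated by
maximum likelihood (not REML): the likelihood-ratio test compares models
that differ in fixed effects, and the information-criterion comparison of
mixed vs OLS is only coherent under ML.

Information criteria use the explicit parameter counts
k_mixed = (#fixed coefficients incl. intercept) + 2 (random-intercept and
residual variances) and k_ols = (#fixed coefficients incl. intercept) + 1
(residual variance), with AIC = 2k - 2ll and BIC = k ln(n) - 2ll.

Variance explained for the mixed model follows the Nakagawa–Schielzeth
decomposition: with sigma_f^2 the (population) variance of the fixed-effects
linear predictor over the fitted observations,

    marginal R^2    = sigma_f^2 / (sigma_f^2 + sigma_u^2 + sigma_e^2)
    conditional R^2 = (sigma_f^2 + sigma_u^2) / (sigma_f^2 + sigma_u^2 + sigma_e^2)

When the estimated random-intercept variance is at the zero boundary the
mixed fit collapses to OLS (identical likelihood, AIC higher by 2); the
recommended fallback is then the OLS model.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .errors import ContractError, FittingError, UndefinedResultError
from .features import PREDICTORS
from .types import Scale

__all__ = [
    "ModelSpec", "FitResult", "LrtResult", "SpearmanResult",
    "log_transform_ymrs", "sample_skewness", "scale_predictors",
    "apply_pairwise_deletion", "prepare_model_frame", "fit_mixed_model",
    "fit_ols", "likelihood_ratio_test", "nakagawa_schielzeth_r2",
    "wald_chisq_tests", "information_criteria", "spearman_total_keys",
    "OUTCOME_COLUMN",
]

#: Name of the (possibly transformed) outcome column in model frames.
OUTCOME_COLUMN = "outcome"

#: Relative tolerance below which a random-intercept variance estimate is
#: treated as sitting on the zero boundary.
BOUNDARY_RTOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, predictors, grouping, estimation flavor."""

    outcome: str  # "hdrs17_raw" or "log_ymrs"
    predictors: tuple[str, ...] = tuple(PREDICTORS)
    grouping: str = "subject_id"
    include_random_intercept: bool = True

    def __post_init__(self):
        if self.outcome not in {"hdrs17_raw", "log_ymrs"}:
            raise ContractError(f"unknown outcome {self.outcome!r}")
        preds = tuple(self.predictors)
        if len(set(preds)) != len(preds):
            raise ContractError("predictor list contains duplicates")
        object.__setattr__(self, "predictors", preds)

    @property
    def scale(self) -> Scale:
        return Scale.HDRS17 if self.outcome == "hdrs17_raw" else Scale.YMRS


@dataclass
class FitResult:
    """Coefficients, uncertainty, variance components and fit indices."""

    model: str  # "mixed" or "ols"
    spec: ModelSpec
    names: list[str]  # "const" + predictors
    params: dict[str, float]
    bse: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    pvalues: dict[str, float]
    llf: float
    k_params: int
    aic: float
    bic: float
    n_obs: int
    n_groups: int | None = None
    sigma_u2: float | None = None
    sigma_e2: float | None = None
    sigma_f2: float | None = None
    marginal_r2: float | None = None
    conditional_r2: float | None = None
    boundary: bool = False
    multiple_r2: float | None = None
    adjusted_r2: float | None = None
    rmse: float | None = None
    resid_se: float | None = None
    f_stat: float | None = None
    f_df: tuple[int, int] | None = None
    f_pvalue: float | None = None
    converged: bool = True

    def to_dict(self) -> dict:
        d = {}
        for key, val in self.__dict__.items():
            if key == "spec":
                d[key] = {
                    "outcome": val.outcome,
                    "predictors": list(val.predictors),
                    "grouping": val.grouping,
                    "include_random_intercept": val.include_random_intercept,
                }
            elif isinstance(val, tuple):
                d[key] = list(val)
            else:
                d[key] = val
        return d


@dataclass(frozen=True)
class LrtResult:
    chi_square: float
    df: int
    pvalue: float
    llf_null: float
    llf_full: float


@dataclass(frozen=True)
class SpearmanResult:
    s_statistic: float
    rho: float
    pvalue: float
    n: int


def log_transform_ymrs(score) -> float:
    """ln(score + 1) — the variance-stabilizing transform for YMRS scores."""
    score = float(score)
    if score < 0:
        raise ContractError(f"YMRS score must be nonnegative, got {score}")
    return math.log(score + 1.0)


def sample_skewness(values) -> float:
    """Bias-corrected sample skewness G1 = g1 * sqrt(n(n-1)) / (n-2)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise UndefinedResultError("skewness needs at least 3 values")
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0.0:
        raise UndefinedResultError("skewness undefined for zero-variance input")
    g1 = ((x - m) ** 3).mean() / m2**1.5
    return float(g1 * math.sqrt(n * (n - 1)) / (n - 2))


def scale_predictors(
    table: pd.DataFrame, predictors: tuple[str, ...] | list[str] = tuple(PREDICTORS)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center and scale each predictor by its pooled mean and SD.

    The pooled statistics are computed over all non-missing values of the
    given table (call after pairwise deletion to scale over the retained
    observation set). SD uses the n-1 denominator. Returns the scaled table
    and a frame of (mean, sd) per predictor for the inverse transform.

    Raises on a zero-SD predictor, naming it.
    """
    scaled = table.copy()
    stats = []
    for p in predictors:
        col = table[p].astype(float)
        mean = col.mean()
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            raise UndefinedResultError(
                f"predictor {p!r} has zero or undefined SD; cannot scale"
            )
        scaled[p] = (col - mean) / sd
        stats.append({"predictor": p, "mean": mean, "sd": sd})
    return scaled, pd.DataFrame(stats).set_index("predictor")


def apply_pairwise_deletion(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Drop rows missing the outcome or any predictor the spec names."""
    needed = [OUTCOME_COLUMN if OUTCOME_COLUMN in table.columns else "score"]
    needed += list(spec.predictors)
    retained = table.dropna(subset=needed)
    if len(retained) == 0:
        raise ContractError("pairwise deletion retained zero rows")
    return retained.reset_index(drop=True)


def prepare_model_frame(
    features: pd.DataFrame, spec: ModelSpec, scale_features: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Feature table -> model-ready frame for one outcome.

    Selects the rows of the spec's rating scale, applies the outcome
    transform (raw HDRS / ln(YMRS+1)), performs pairwise deletion, then
    z-scales the predictors over the retained rows. Returns (frame,
    scaling parameters); scaling is skipped (None returned) when
    ``scale_features`` is false.
    """
    sub = features[features["scale"] == spec.scale.value].copy()
    if len(sub) == 0:
        raise ContractError(f"no rows for scale {spec.scale.value}")
    if spec.outcome == "log_ymrs":
        sub[OUTCOME_COLUMN] = np.log(sub["score"].astype(float) + 1.0)
    else:
        sub[OUTCOME_COLUMN] = sub["score"].astype(float)
    sub = apply_pairwise_deletion(sub, spec)
    if not scale_features:
        return sub, None
    scaled, params = scale_predictors(sub, spec.predictors)
    return scaled, params


def _design(frame: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = frame[OUTCOME_COLUMN].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[p].to_numpy(dtype=float) for p in spec.predictors]
    )
    return y, X, ["const", *spec.predictors]


def _wald_columns(params: np.ndarray, bse: np.ndarray):
    z = np.divide(params, bse, out=np.zeros_like(params), where=bse > 0)
    pvals = scipy.stats.chi2.sf(z**2, df=1)
    lo = params - 1.96 * bse
    hi = params + 1.96 * bse
    return pvals, lo, hi


def _profile_reint_ml(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """ML fit of a random-intercept linear model by 1-D likelihood profiling.

    For a fixed variance ratio lam = sigma_u^2 / sigma_e^2 the GLS estimate
    of beta and the profiled sigma_e^2 are closed-form (per-group inverse
    V_i^{-1} = I - lam/(1 + lam n_i) J), leaving a scalar concave-ish profile
    in lam that is maximized on a log grid plus golden-section refinement.
    Robust at the lam = 0 boundary, where statsmodels' Hessian is singular.
    Returns (fe, bse, sigma_u2, sigma_e2, llf).
    """
    n, p = X.shape
    codes = pd.factorize(groups)[0]
    n_g = np.bincount(codes).astype(float)

    def _profile(lam: float):
        c = lam / (1.0 + lam * n_g)  # per-group shrinkage
        Sx = np.zeros((len(n_g), p))
        np.add.at(Sx, codes, X)
        Sy = np.bincount(codes, weights=y)
        XtVX = X.T @ X - (Sx * c[:, None]).T @ Sx
        XtVy = X.T @ y - Sx.T @ (c * Sy)
        fe = np.linalg.solve(XtVX, XtVy)
        r = y - X @ fe
        Sr = np.bincount(codes, weights=r)
        quad = float(r @ r - c @ Sr**2)
        sigma_e2 = quad / n
        llf = -0.5 * n * (math.log(2.0 * math.pi * sigma_e2) + 1.0) - 0.5 * float(
            np.log1p(lam * n_g).sum()
        )
        return llf, fe, sigma_e2, XtVX

    # coarse log-grid over the ratio, then golden-section refinement
    lams = np.concatenate(([0.0], np.exp(np.linspace(-8.0, 6.0, 57))))
    lls = np.array([_profile(l)[0] for l in lams])
    j = int(np.argmax(lls))
    lo = lams[max(j - 1, 0)]
    hi = lams[min(j + 1, len(lams) - 1)]
    if hi > lo:
        res = scipy.optimize.minimize_scalar(
            lambda l: -_profile(l)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(res.x) if -res.fun >= lls[j] else float(lams[j])
    else:
        lam = float(lams[j])
    llf, fe, sigma_e2, XtVX = _profile(lam)
    bse = np.sqrt(np.diag(sigma_e2 * np.linalg.inv(XtVX)))
    return fe, bse, lam * sigma_e2, sigma_e2, llf


def fit_mixed_model(frame: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """ML fit of outcome ~ fixed effects + per-subject random intercept.

    An estimated random-intercept variance of (numerically) zero is allowed
    and flagged via ``result.boundary``; at that boundary the fit is
    equivalent to OLS. statsmodels' MixedLM is the primary optimizer; when
    its Hessian-based variance step fails (which happens precisely at the
    boundary), the closed-form 1-D profile fit takes over.
    """
    if not spec.include_random_intercept:
        raise ContractError("fit_mixed_model requires include_random_intercept")
    groups = frame[spec.grouping].to_numpy()
    n_groups = len(pd.unique(groups))
    if n_groups < 2:
        raise ContractError("mixed model needs at least 2 subjects")
    y, X, names = _design(frame, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FittingError("rank-deficient fixed-effects design")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=False, method=["lbfgs", "bfgs", "cg"])
            if not np.all(np.isfinite(np.asarray(res.fe_params, dtype=float))):
                raise FittingError("non-finite coefficients")
            fe = np.asarray(res.fe_params, dtype=float)
            bse = np.asarray(res.bse_fe, dtype=float)
            sigma_u2 = float(np.asarray(res.cov_re)[0, 0])
            sigma_e2 = float(res.scale)
            llf = float(res.llf)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            try:
                fe, bse, sigma_u2, sigma_e2, llf = _profile_reint_ml(y, X, groups)
            except Exception as exc:
                raise FittingError(f"mixed model fit failed: {exc!r}") from exc
    eta = X @ fe
    sigma_f2 = float(np.var(eta))  # population variance, per the R2 convention
    marginal, conditional = nakagawa_schielzeth_r2((sigma_f2, sigma_u2, sigma_e2))
    pvals, lo, hi = _wald_columns(fe, bse)
    k = len(names) + 2
    n = len(y)
    aic, bic = information_criteria(llf, k, n)
    boundary = sigma_u2 <= BOUNDARY_RTOL * (sigma_u2 + sigma_e2)
    return FitResult(
        model="mixed",
        spec=spec,
        names=names,
        params=dict(zip(names, fe.tolist())),
        bse=dict(zip(names, bse.tolist())),
        ci_low=dict(zip(names, lo.tolist())),
        ci_high=dict(zip(names, hi.tolist())),
        pvalues=dict(zip(names, np.asarray(pvals, dtype=float).tolist())),
        llf=llf,
        k_params=k,
        aic=aic,
        bic=bic,
        n_obs=n,
        n_groups=n_groups,
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        sigma_f2=sigma_f2,
        marginal_r2=marginal,
        conditional_r2=conditional,
        boundary=bool(boundary),
        converged=converged,
    )


def fit_ols(frame: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Ordinary least squares fit with the full set of summary fit indices.

    Coefficient p-values come from t-tests (df = n - p - 1); confidence
    intervals are Wald normal intervals (±1.96 SE), matching the symmetric
    intervals of the reporting tables.
    """
    if spec.include_random_intercept:
        raise ContractError("fit_ols requires include_random_intercept = False")
    y, X, names = _design(frame, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending predictors for the error message
        bad = []
        for j in range(1, X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise FittingError(f"rank-deficient design; collinear predictors: {bad or names[1:]}")
    res = sm.OLS(y, X).fit()
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    _, lo, hi = _wald_columns(params, bse)
    n = len(y)
    p = len(names) - 1
    k = p + 1 + 1
    aic, bic = information_criteria(float(res.llf), k, n)
    rss = float(res.ssr)
    r2 = float(res.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else float("nan")
    f_df = (p, n - p - 1)
    return FitResult(
        model="ols",
        spec=spec,
        names=names,
        params=dict(zip(names, params.tolist())),
        bse=dict(zip(names, bse.tolist())),
        ci_low=dict(zip(names, lo.tolist())),
        ci_high=dict(zip(names, hi.tolist())),
        pvalues=dict(zip(names, np.asarray(res.pvalues, dtype=float).tolist())),
        llf=float(res.llf),
        k_params=k,
        aic=aic,
        bic=bic,
        n_obs=n,
        n_groups=len(pd.unique(frame[spec.grouping])) if spec.grouping in frame else None,
        sigma_u2=0.0,
        sigma_e2=rss / n,  # ML residual variance
        multiple_r2=r2,
        adjusted_r2=float(adj),
        rmse=math.sqrt(rss / n),
        resid_se=math.sqrt(rss / (n - p - 1)) if n - p - 1 > 0 else float("nan"),
        f_stat=float(res.fvalue) if p > 0 else None,
        f_df=f_df,
        f_pvalue=float(res.f_pvalue) if p > 0 else None,
    )


def likelihood_ratio_test(null_fit: FitResult, full_fit: FitResult) -> LrtResult:
    """LRT of nested ML fits on the same observations.

    The statistic 2(ll_full - ll_null) is clamped at zero; df is the
    parameter-count difference; p comes from the chi-square upper tail.
    """
    if null_fit.n_obs != full_fit.n_obs:
        raise ContractError(
            f"LRT requires identical observation sets (n={null_fit.n_obs} vs {full_fit.n_obs})"
        )
    df = full_fit.k_params - null_fit.k_params
    if df <= 0:
        raise ContractError("full model must have more parameters than the null")
    stat = max(0.0, 2.0 * (full_fit.llf - null_fit.llf))
    p = float(scipy.stats.chi2.sf(stat, df=df))
    return LrtResult(chi_square=stat, df=df, pvalue=p, llf_null=null_fit.llf, llf_full=full_fit.llf)


def nakagawa_schielzeth_r2(fit) -> tuple[float, float]:
    """(marginal R^2, conditional R^2) from variance components.

    Accepts a mixed :class:`FitResult` or a (sigma_f2, sigma_u2, sigma_e2)
    triple.
    """
    if isinstance(fit, FitResult):
        comps = (fit.sigma_f2, fit.sigma_u2, fit.sigma_e2)
    else:
        comps = tuple(fit)
    sigma_f2, sigma_u2, sigma_e2 = (float(c) for c in comps)
    total = sigma_f2 + sigma_u2 + sigma_e2
    if total <= 0:
        raise UndefinedResultError("total variance must be positive")
    return sigma_f2 / total, (sigma_f2 + sigma_u2) / total


def wald_chisq_tests(fit: FitResult) -> pd.DataFrame:
    """Per-coefficient Wald chi-square statistics, p-values and 95% CIs."""
    rows = []
    for name in fit.names:
        b = fit.params[name]
        se = fit.bse[name]
        stat = (b / se) ** 2 if se > 0 else 0.0
        rows.append(
            {
                "term": name,
                "estimate": b,
                "se": se,
                "chi_square": stat,
                "pvalue": float(scipy.stats.chi2.sf(stat, df=1)),
                "ci_low": b - 1.96 * se,
                "ci_high": b + 1.96 * se,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def information_criteria(log_likelihood: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2ll and BIC = k ln(n) - 2ll for an ML fit."""
    if k < 1 or n < 1:
        raise ContractError("k and n must be >= 1")
    aic = 2.0 * k - 2.0 * log_likelihood
    bic = k * math.log(n) - 2.0 * log_likelihood
    return float(aic), float(bic)


def spearman_total_keys(totals, covariate) -> SpearmanResult:
    """Spearman rank correlation between per-subject key totals and a covariate.

    Reported via the S = sum(d^2) statistic over midranks (the convention of
    classical rank-correlation output); rho = 1 - 6S / (n(n^2-1)) in the
    untied case, Pearson correlation of midranks otherwise.
    """
    x = np.asarray(totals, dtype=float)
    y = np.asarray(covariate, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ContractError("need >= 3 paired observations")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise UndefinedResultError("rank correlation undefined for a constant variable")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    s = float(((rx - ry) ** 2).sum())
    ties = (len(np.unique(rx)) < n) or (len(np.unique(ry)) < n)
    if ties:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    else:
        rho = 1.0 - 6.0 * s / (n * (n**2 - 1))
    pvalue = float(scipy.stats.spearmanr(x, y).pvalue)
    return SpearmanResult(s_statistic=s, rho=rho, pvalue=pvalue, n=n)
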