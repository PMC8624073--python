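"""Reliability estimation: ICC(A,1), reliability categories, and the
covariate-adjusted ICC from random-intercept mixed-model variance components.

The unadjusted statistic is the two-way mixed-effects, single-measurement,
absolute-agreement intraclass correlation ICC(A,1) of McGraw & Wong, with
the F-based confidence interval using Satterthwaite degrees of freedom and
an F test of MSR/MSE for H0: ICC = 0. Estimates are interpreted with the
Koo & Li bands: < 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, > 0.90
excellent.

The adjusted statistic conditions on covariates (glucose, HbA1c, physical
activity, dietary habits): a linear mixed model with those fixed effects and
a participant random intercept is fitted by REML, and the adjusted ICC is
sigma2_between / (sigma2_between + sigma2_residual). Its confidence interval
comes from a seeded parametric bootstrap (simulate from the fitted model,
refit, percentile interval) — appropriate at the very small cohort sizes
this analysis targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .permutation import PairedMatrix, as_paired_matrix

__all__ = [
    "AnovaDecomposition",
    "ICCEstimate",
    "VarianceComponents",
    "anova_decomposition",
    "icc_a1",
    "classify_reliability",
    "fit_random_intercept_lmm",
    "adjusted_icc",
]

_CATEGORY_ORDER = ("poor", "moderate", "good", "excellent")


@dataclass(frozen=True)
class AnovaDecomposition:
    """Two-way (participants x assessments) mean squares for an n x k table."""

    msr: float  # between-rows (participants)
    msc: float  # between-columns (assessments)
    mse: float  # residual
    n: int
    k: int

    @property
    def df_rows(self) -> int:
        return self.n - 1

    @property
    def df_cols(self) -> int:
        return self.k - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)


@dataclass(frozen=True)
class ICCEstimate:
    """An intraclass correlation with its 95% CI, test and interpretation."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: Optional[float]
    category: Optional[str]
    method: str  # "icc_a1" | "adjusted_lmm"
    conf_level: float = 0.95
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "category": self.category,
            "method": self.method,
            "conf_level": self.conf_level,
            "degenerate": self.degenerate,
        }


def anova_decomposition(data: Union[PairedMatrix, Sequence, np.ndarray]) -> AnovaDecomposition:
    """Row/column/residual mean squares of a complete n x k matrix.

    The sums of squares satisfy SS_total = SS_rows + SS_cols + SS_error
    exactly (two-way decomposition without replication).
    """
    x = data.values if isinstance(data, PairedMatrix) else np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an n x k matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 assessments")
    if not np.isfinite(x).all():
        raise ValueError("missing cells: the two-way decomposition requires a complete matrix")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())
    return AnovaDecomposition(
        msr=ss_rows / (n - 1),
        msc=ss_cols / (k - 1),
        mse=ss_err / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def classify_reliability(estimate: float) -> str:
    """Koo & Li interpretation of an ICC value.

    Bands: < 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.90] good, > 0.90
    excellent. The quoted bands overlap at their edges; the convention here
    is left-closed with 0.90 still 'good', matching the strict '> 0.90 means
    excellent'. Negative estimates (possible for the ICC estimator) are poor.
    """
    if not math.isfinite(estimate):
        raise ValueError("estimate must be finite")
    if estimate > 1:
        raise ValueError(f"ICC cannot exceed 1, got {estimate}")
    if estimate > 0.90:
        return "excellent"
    if estimate >= 0.75:
        return "good"
    if estimate >= 0.5:
        return "moderate"
    return "poor"


def icc_a1(
    data: Union[PairedMatrix, Sequence, np.ndarray], conf: float = 0.95
) -> ICCEstimate:
    """ICC(A,1): absolute agreement of single measurements, two-way model.

    estimate = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)); the CI is
    the F-based interval with Satterthwaite degrees of freedom for the
    column/error mixture, and the p-value tests H0: ICC = 0 via
    F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.

    A matrix with zero total variance carries no reliability information and
    returns a degenerate-flagged estimate (NaN) rather than a number.
    """
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    dec = anova_decomposition(data)
    n, k = dec.n, dec.k
    msr, msc, mse = dec.msr, dec.msc, dec.mse
    if msr == 0 and msc == 0 and mse == 0:
        return ICCEstimate(
            estimate=math.nan, ci_low=math.nan, ci_high=math.nan, p_value=None,
            category=None, method="icc_a1", conf_level=conf, degenerate=True,
        )

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    est = (msr - mse) / denom

    alpha = 1 - conf
    if mse == 0 and msc == 0:
        # perfect absolute agreement: no residual or assessment variation
        ci_low, ci_high, p = 1.0, 1.0, 0.0
        return ICCEstimate(1.0, ci_low, ci_high, p, classify_reliability(1.0),
                           "icc_a1", conf, False)

    if mse > 0:
        f_obs = msr / mse
        p = float(stats.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0

    # Satterthwaite df for the a*MSC + b*MSE mixture at the point estimate
    with np.errstate(divide="ignore", invalid="ignore"):
        a = k * est / (n * (1 - est)) if est < 1 else math.inf
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else math.inf
    if math.isfinite(a) and math.isfinite(b) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        ci_low = ci_high = est
    ci_low = float(min(ci_low, est))
    ci_high = float(min(max(ci_high, est), 1.0))
    return ICCEstimate(
        estimate=float(est),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        category=classify_reliability(est),
        method="icc_a1",
        conf_level=conf,
    )


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (REML) and the adjusted ICC
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """REML variance components and fixed effects of a random-intercept model."""

    sigma2_between: float
    sigma2_residual: float
    beta: pd.Series
    reml_neg2loglik: float
    converged: bool
    truncated: bool  # between-variance estimate hit the zero boundary
    n_obs: int
    n_groups: int
    response: str = ""
    _design: Optional[dict] = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "sigma2_between": self.sigma2_between,
            "sigma2_residual": self.sigma2_residual,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "reml_neg2loglik": self.reml_neg2loglik,
            "converged": self.converged,
            "truncated": self.truncated,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "response": self.response,
        }


def _group_sums(v: np.ndarray, gidx: np.ndarray, n_groups: int) -> np.ndarray:
    if v.ndim == 1:
        return np.bincount(gidx, weights=v, minlength=n_groups)
    return np.column_stack(
        [np.bincount(gidx, weights=v[:, j], minlength=n_groups) for j in range(v.shape[1])]
    )


def reml_neg2loglik(
    lam: float, y: np.ndarray, X: np.ndarray, gidx: np.ndarray, counts: np.ndarray
) -> float:
    """Profiled REML -2 log-likelihood (up to a constant) at variance ratio
    lam = sigma2_between / sigma2_residual.

    beta and sigma2_residual are profiled out in closed form using the block
    structure of V = I + lam Z Z' (per-group inverse
    I - lam/(1 + k_g lam) J)."""
    n_groups = counts.shape[0]
    shrink = lam / (1.0 + counts * lam)  # per group

    def apply_winv(v: np.ndarray) -> np.ndarray:
        gs = _group_sums(v, gidx, n_groups)
        if v.ndim == 1:
            return v - (shrink * gs)[gidx]
        return v - (shrink[:, None] * gs)[gidx]

    Wy = apply_winv(y)
    WX = apply_winv(X)
    xtwx = X.T @ WX
    xtwy = X.T @ Wy
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return math.inf
    r = y - X @ beta
    q = float(r @ apply_winv(r))
    n, p = X.shape
    if q <= 0:
        return -math.inf
    sigma2 = q / (n - p)
    logdet_v = float(np.log1p(counts * lam).sum())
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return math.inf
    return (n - p) * math.log(sigma2) + logdet_v + logdet_xtwx + (n - p)


def fit_random_intercept_lmm(
    cohort: pd.DataFrame,
    response: str,
    covariates: Sequence[str] = (),
    group_col: str = "participant_id",
) -> VarianceComponents:
    """REML fit of ``response ~ 1 + covariates + (1 | participant)``.

    Expects one row per participant x assessment with the response and all
    covariate columns present; rows with missing values fail loudly (the
    analysis is complete-case by design). The variance ratio is optimised on
    a log scale by bounded scalar search; a between-variance estimate at the
    zero boundary is truncated to 0 and flagged.
    """
    cols = [group_col, response, *covariates]
    missing_cols = [c for c in cols if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort table is missing columns {missing_cols}")
    sub = cohort[cols]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(
            f"missing values in {bad}: complete cases are required (no imputation)"
        )
    groups, gidx = np.unique(sub[group_col].to_numpy(), return_inverse=True)
    counts = np.bincount(gidx).astype(float)
    if counts.min() < 2:
        raise ValueError("every included participant needs at least 2 observations")
    y = sub[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in covariates]
    )
    names = ["intercept", *covariates]

    def objective(log_lam: float) -> float:
        return reml_neg2loglik(math.exp(log_lam), y, X, gidx, counts)

    res = optimize.minimize_scalar(
        objective, bounds=(-25.0, 15.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam_hat = math.exp(res.x)
    best = res.fun
    converged = bool(res.success)
    truncated = False
    # compare with the zero-boundary (no between-participant variance) fit
    at_zero = reml_neg2loglik(0.0, y, X, gidx, counts)
    if at_zero <= best or res.x < -24.0:
        if at_zero <= best:
            lam_hat, best = 0.0, at_zero
        else:
            lam_hat = 0.0
            best = at_zero
        truncated = True

    # recover beta and sigma2 at the optimum
    n_groups = counts.shape[0]
    shrink = lam_hat / (1.0 + counts * lam_hat)

    def apply_winv(v: np.ndarray) -> np.ndarray:
        gs = _group_sums(v, gidx, n_groups)
        if v.ndim == 1:
            return v - (shrink * gs)[gidx]
        return v - (shrink[:, None] * gs)[gidx]

    WX = apply_winv(X)
    xtwx = X.T @ WX
    beta = np.linalg.solve(xtwx, X.T @ apply_winv(y))
    r = y - X @ beta
    sigma2_e = float(r @ apply_winv(r)) / (len(y) - X.shape[1])
    sigma2_b = lam_hat * sigma2_e
    return VarianceComponents(
        sigma2_between=float(sigma2_b),
        sigma2_residual=float(sigma2_e),
        beta=pd.Series(beta, index=names),
        reml_neg2loglik=float(best),
        converged=converged,
        truncated=truncated,
        n_obs=len(y),
        n_groups=len(groups),
        response=response,
        _design={"y": y, "X": X, "gidx": gidx, "counts": counts,
                 "covariates": list(covariates), "group_col": group_col},
    )


def adjusted_icc(
    vc: VarianceComponents,
    bootstrap_reps: int = 500,
    seed: Optional[Union[int, np.random.Generator]] = None,
    conf: float = 0.95,
) -> ICCEstimate:
    """Covariate-adjusted ICC from mixed-model variance components.

    estimate = sigma2_between / (sigma2_between + sigma2_residual), i.e.
    reliability conditional on the fixed-effect covariates. The CI is a
    seeded parametric bootstrap: simulate response vectors from the fitted
    model (fixed effects + Gaussian random intercept + Gaussian residual),
    refit by REML, and take the percentile interval of the ratio.
    """
    if not vc.converged:
        raise ValueError("variance components did not converge; refusing to bootstrap")
    total = vc.sigma2_between + vc.sigma2_residual
    if total == 0:
        return ICCEstimate(math.nan, math.nan, math.nan, None, None,
                           "adjusted_lmm", conf, degenerate=True)
    est = vc.sigma2_between / total

    ci_low = ci_high = est
    if bootstrap_reps > 0:
        if vc._design is None:
            raise ValueError("VarianceComponents lacks its design; refit before bootstrap")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        d = vc._design
        X, gidx, counts = d["X"], d["gidx"], d["counts"]
        mean = X @ vc.beta.to_numpy()
        sd_b = math.sqrt(vc.sigma2_between)
        sd_e = math.sqrt(vc.sigma2_residual)
        n_groups = counts.shape[0]
        ratios = np.empty(bootstrap_reps)
        frame = pd.DataFrame(X[:, 1:], columns=d["covariates"])
        frame[d["group_col"]] = gidx
        for rep in range(bootstrap_reps):
            b = rng.normal(0.0, sd_b, size=n_groups)
            ystar = mean + b[gidx] + rng.normal(0.0, sd_e, size=len(mean))
            frame["_y"] = ystar
            fit = fit_random_intercept_lmm(
                frame, "_y", d["covariates"], group_col=d["group_col"]
            )
            tot = fit.sigma2_between + fit.sigma2_residual
            ratios[rep] = fit.sigma2_between / tot if tot > 0 else 0.0
        alpha = 1 - conf
        ci_low = float(np.quantile(ratios, alpha / 2))
        ci_high = float(np.quantile(ratios, 1 - alpha / 2))
        ci_low = min(ci_low, est)
        ci_high = max(ci_high, est)
    return ICCEstimate(
        estimate=float(est),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=None,
        category=classify_reliability(est),
        method="adjusted_lmm",
        conf_level=conf,
    )
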