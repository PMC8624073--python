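"""Random-intercept REML fit and the covariate-adjusted ICC."""

import math

import numpy as np
import pandas as pd
import pytest

from ghrelkit.icc import (
    adjusted_icc,
    fit_random_intercept_lmm,
    icc_a1,
    reml_neg2loglik,
)


def balanced_frame(n, k, sigma_b, sigma_e, seed, beta_cov=0.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n), k)
    cov = rng.normal(size=n * k)
    y = 5.0 + beta_cov * cov + rng.normal(0, sigma_b, n)[g] + rng.normal(0, sigma_e, n * k)
    return pd.DataFrame({"participant_id": g, "y": y, "cov": cov})


def test_intercept_only_matches_oneway_anova_closed_form():
    """With no covariates on balanced data the REML solution is the one-way
    ANOVA estimator: sigma_e^2 = MSW, sigma_b^2 = (MSB - MSW)/k."""
    for seed in (0, 1, 2):
        n, k = 12, 2
        df = balanced_frame(n, k, 1.3, 0.7, seed)
        x = df["y"].to_numpy().reshape(n, k)
        msb = k * ((x.mean(axis=1) - x.mean()) ** 2).sum() / (n - 1)
        msw = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
        vc = fit_random_intercept_lmm(df, "y")
        assert vc.sigma2_residual == pytest.approx(msw, rel=1e-6)
        assert vc.sigma2_between == pytest.approx(max((msb - msw) / k, 0.0), rel=1e-6, abs=1e-8)
        assert vc.converged


def test_parameter_recovery_large_n():
    """Mean REML estimates over replicates at n=500 recover (1, 1) within
    +/-0.1 (a single replicate's sampling SE is ~0.09, so replicates are
    averaged to test the estimator rather than one draw)."""
    fits = [
        fit_random_intercept_lmm(balanced_frame(500, 2, 1.0, 1.0, seed=s), "y", ["cov"])
        for s in range(5)
    ]
    assert np.mean([f.sigma2_between for f in fits]) == pytest.approx(1.0, abs=0.1)
    assert np.mean([f.sigma2_residual for f in fits]) == pytest.approx(1.0, abs=0.1)
    assert np.mean([f.beta["intercept"] for f in fits]) == pytest.approx(5.0, abs=0.15)
    assert np.mean([f.beta["cov"] for f in fits]) == pytest.approx(0.0, abs=0.1)


def test_reml_objective_beats_profile_grid():
    """The returned variance components minimise the REML -2ll over a 50x50
    grid in (sigma_b^2, sigma_e^2)."""
    df = balanced_frame(25, 2, 0.9, 0.6, seed=3, beta_cov=0.4)
    vc = fit_random_intercept_lmm(df, "y", ["cov"])
    y = df["y"].to_numpy()
    X = np.column_stack([np.ones(len(df)), df["cov"].to_numpy()])
    gidx = df["participant_id"].to_numpy()
    counts = np.bincount(gidx).astype(float)

    def neg2ll(s2b, s2e):
        # full REML criterion at arbitrary (s2b, s2e): lam = s2b/s2e plus the
        # unprofiled scale term
        lam = s2b / s2e
        shrink = lam / (1.0 + counts * lam)

        def winv(v):
            gs = np.column_stack([
                np.bincount(gidx, weights=v[:, j]) for j in range(v.shape[1])
            ]) if v.ndim == 2 else np.bincount(gidx, weights=v)
            return v - (shrink[:, None] * gs)[gidx] if v.ndim == 2 else v - (shrink * gs)[gidx]

        xtwx = X.T @ winv(X)
        beta = np.linalg.solve(xtwx, X.T @ winv(y))
        r = y - X @ beta
        q = float(r @ winv(r))
        npar = X.shape[1]
        logdet_v = len(y) * math.log(s2e) + float(np.log1p(counts * lam).sum())
        sign, logdet_xtwx = np.linalg.slogdet(xtwx / s2e)
        return q / s2e + logdet_v + logdet_xtwx

    best = neg2ll(vc.sigma2_between, vc.sigma2_residual)
    grid_b = np.linspace(0.01, 3.0, 50)
    grid_e = np.linspace(0.05, 3.0, 50)
    grid_min = min(neg2ll(b, e) for b in grid_b for e in grid_e)
    assert best <= grid_min + 1e-6


def test_matches_statsmodels_mixedlm():
    smf = pytest.importorskip("statsmodels.formula.api")
    df = balanced_frame(40, 2, 1.0, 0.8, seed=11, beta_cov=0.5)
    vc = fit_random_intercept_lmm(df, "y", ["cov"])
    fit = smf.mixedlm("y ~ cov", df, groups=df["participant_id"]).fit(reml=True)
    assert vc.sigma2_between == pytest.approx(float(fit.cov_re.iloc[0, 0]), abs=2e-3)
    assert vc.sigma2_residual == pytest.approx(float(fit.scale), abs=2e-3)
    assert vc.beta["cov"] == pytest.approx(float(fit.fe_params["cov"]), abs=1e-4)


def test_boundary_truncation_flagged():
    # anti-correlated pairs: every group mean is exactly 0, so the
    # between-variance REML estimate must sit on the zero boundary
    z = np.random.default_rng(0).normal(size=60)
    df = pd.DataFrame({
        "participant_id": np.repeat(np.arange(60), 2),
        "y": np.column_stack([z, -z]).reshape(-1),
    })
    vc = fit_random_intercept_lmm(df, "y")
    assert vc.sigma2_between == 0.0
    assert vc.truncated


def test_missing_values_fail_loudly():
    df = balanced_frame(6, 2, 1, 1, seed=1)
    df.loc[3, "cov"] = np.nan
    with pytest.raises(ValueError, match="complete"):
        fit_random_intercept_lmm(df, "y", ["cov"])
    with pytest.raises(KeyError):
        fit_random_intercept_lmm(df, "y", ["not_a_column"])


def test_single_observation_groups_rejected():
    df = pd.DataFrame({"participant_id": [0, 0, 1], "y": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="at least 2"):
        fit_random_intercept_lmm(df, "y")


class TestAdjustedICC:
    def test_ratio_by_definition(self):
        df = balanced_frame(30, 2, 2.0, 1.0, seed=5)
        vc = fit_random_intercept_lmm(df, "y")
        est = adjusted_icc(vc, bootstrap_reps=0)
        total = vc.sigma2_between + vc.sigma2_residual
        assert est.estimate == pytest.approx(vc.sigma2_between / total)
        assert est.method == "adjusted_lmm"

    def test_known_variance_ratios(self):
        from ghrelkit.icc import VarianceComponents

        vc = VarianceComponents(3.0, 1.0, pd.Series({"intercept": 0.0}),
                                0.0, True, False, 10, 5)
        assert adjusted_icc(vc, bootstrap_reps=0).estimate == pytest.approx(0.75)
        vc0 = VarianceComponents(0.0, 1.0, pd.Series({"intercept": 0.0}),
                                 0.0, True, True, 10, 5)
        assert adjusted_icc(vc0, bootstrap_reps=0).estimate == 0.0

    def test_bootstrap_ci_is_seeded_and_ordered(self):
        df = balanced_frame(20, 2, 1.0, 1.0, seed=9)
        vc = fit_random_intercept_lmm(df, "y", ["cov"])
        a = adjusted_icc(vc, bootstrap_reps=80, seed=4)
        b = adjusted_icc(vc, bootstrap_reps=80, seed=4)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.estimate <= a.ci_high
        assert 0.0 <= a.ci_low and a.ci_high <= 1.0

    def test_agrees_with_icc_a1_under_null_covariates(self):
        """With zero covariate effects the adjusted ICC tracks ICC(A,1)
        (small cohort sample of replicates; the acceptance suite runs the
        full-size study)."""
        diffs = []
        for seed in range(20):
            df = balanced_frame(100, 2, 1.0, 1.0, seed=seed, beta_cov=0.0)
            x = df["y"].to_numpy().reshape(100, 2)
            vc = fit_random_intercept_lmm(df, "y", ["cov"])
            diffs.append(abs(adjusted_icc(vc, bootstrap_reps=0).estimate
                             - icc_a1(x).estimate))
        assert np.mean(diffs) < 0.05
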