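"""ICC(A,1): ANOVA decomposition, estimate, interval, classification."""

import math

import numpy as np
import pandas as pd
import pytest

from ghrelkit.icc import anova_decomposition, classify_reliability, icc_a1

FOUR_BY_TWO = np.array([(1, 2), (3, 4), (5, 6), (7, 9)], dtype=float)


def ss_oracle(x):
    """Independent sums-of-squares decomposition (direct double loops)."""
    n, k = x.shape
    gm = x.mean()
    ss_rows = sum(k * (x[i].mean() - gm) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - gm) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - gm) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_a1_oracle(x):
    n, k = x.shape
    msr, msc, mse = ss_oracle(x)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def test_anova_decomposition_frozen_example():
    dec = anova_decomposition(FOUR_BY_TWO)
    # hand-computed: grand mean 4.625, SS_rows 46.375, SS_cols 3.125, SS_err 0.375
    assert dec.msr == pytest.approx(46.375 / 3)
    assert dec.msc == pytest.approx(3.125)
    assert dec.mse == pytest.approx(0.375 / 3)
    assert (dec.df_rows, dec.df_cols, dec.df_error) == (3, 1, 3)


def test_anova_identical_columns_and_constant_matrix():
    same = np.column_stack([np.arange(4.0), np.arange(4.0)])
    dec = anova_decomposition(same)
    assert dec.msc == 0.0 and dec.mse == pytest.approx(0.0)
    const = np.full((5, 2), 3.3)
    dec = anova_decomposition(const)
    assert dec.msr == dec.msc == 0.0 and dec.mse == pytest.approx(0.0)


def test_anova_ss_identity_random(rng):
    x = rng.normal(size=(12, 3))
    n, k = x.shape
    dec = anova_decomposition(x)
    ss = dec.msr * (n - 1) + dec.msc * (k - 1) + dec.mse * (n - 1) * (k - 1)
    assert ss == pytest.approx(((x - x.mean()) ** 2).sum(), rel=1e-12)


def test_anova_rejects_missing_cells():
    with pytest.raises(ValueError, match="[Mm]issing"):
        anova_decomposition(np.array([[1.0, np.nan], [2.0, 3.0]]))


def test_icc_frozen_example_matches_oracle_formula():
    est = icc_a1(FOUR_BY_TWO)
    assert est.estimate == pytest.approx(0.897560975609756, abs=1e-12)
    assert est.estimate == pytest.approx(icc_a1_oracle(FOUR_BY_TWO), abs=1e-12)


def test_icc_random_matrices_match_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(3, 25))
        x = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1)) * rng.uniform(0.2, 3)
        assert icc_a1(x).estimate == pytest.approx(icc_a1_oracle(x), abs=1e-10)


def test_perfect_agreement_is_exactly_one():
    est = icc_a1([(1, 1), (2, 2), (3, 3)])
    assert est.estimate == 1.0
    assert est.category == "excellent"
    assert (est.ci_low, est.ci_high) == (1.0, 1.0)


def test_zero_variance_is_degenerate_not_numeric():
    est = icc_a1(np.full((6, 2), 7.0))
    assert est.degenerate
    assert math.isnan(est.estimate) and est.category is None


def test_null_data_estimates_near_zero():
    """Rows iid with no participant effect: mean estimate ~ 0."""
    rng = np.random.default_rng(99)
    ests = [icc_a1(rng.normal(size=(100, 2))).estimate for _ in range(200)]
    assert abs(np.mean(ests)) < 0.02


def test_affine_invariance_and_column_shift_sensitivity(rng):
    x = rng.normal(size=(15, 2)) + rng.normal(size=(15, 1))
    base = icc_a1(x)
    scaled = icc_a1(3.7 * x - 11.0)
    assert scaled.estimate == pytest.approx(base.estimate, abs=1e-12)
    assert scaled.ci_low == pytest.approx(base.ci_low, abs=1e-9)
    assert scaled.ci_high == pytest.approx(base.ci_high, abs=1e-9)
    # absolute agreement: shifting only one column must lower the estimate
    shifted = x.copy()
    shifted[:, 1] += 2.0 * x.std()
    assert icc_a1(shifted).estimate < base.estimate


def test_ci_and_p_match_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    for _ in range(10):
        n = int(rng.integers(6, 20))
        x = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1)) * 1.2
        est = icc_a1(x)
        df = pd.DataFrame({
            "t": np.repeat(np.arange(n), 2),
            "r": ["BL", "FU"] * n,
            "y": x.reshape(-1),
        })
        tab = pg.intraclass_corr(df, "t", "r", "y").set_index("Type")
        row = tab.loc["ICC(A,1)"] if "ICC(A,1)" in tab.index else tab.loc["ICC2"]
        assert est.estimate == pytest.approx(row["ICC"], abs=1e-10)
        assert est.p_value == pytest.approx(row["pval"], abs=1e-10)
        ci_col = "CI95" if "CI95" in row.index else "CI95%"
        assert est.ci_low == pytest.approx(row[ci_col][0], abs=6e-3)
        assert est.ci_high == pytest.approx(row[ci_col][1], abs=6e-3)


@pytest.mark.parametrize(
    "value, expected",
    [
        (0.99, "excellent"),
        (0.91, "excellent"),
        (0.90, "good"),       # the bands overlap at 0.90; strict '>' wins
        (0.89, "good"),
        (0.75, "good"),
        (0.749, "moderate"),
        (0.51, "moderate"),
        (0.50, "moderate"),
        (0.49, "poor"),
        (0.29, "poor"),
        (0.0, "poor"),
        (-0.4, "poor"),       # negative estimates are reported but poor
        (1.0, "excellent"),
    ],
)
def test_reliability_classification(value, expected):
    assert classify_reliability(value) == expected


def test_classification_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_reliability(1.2)
    with pytest.raises(ValueError):
        classify_reliability(math.nan)


def test_classification_is_monotone_step_function():
    grid = np.linspace(-1, 1, 401)
    order = {"poor": 0, "moderate": 1, "good": 2, "excellent": 3}
    ranks = [order[classify_reliability(v)] for v in grid]
    assert ranks == sorted(ranks)
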