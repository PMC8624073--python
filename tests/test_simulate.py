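"""Synthetic cohort generator: determinism, marginals, embedded reliability."""

import numpy as np
import pandas as pd
import pytest

from ghrelkit.icc import icc_a1
from ghrelkit.simulate import (
    HormoneSpec,
    SimulationConfig,
    cohort_to_long,
    default_hormone_specs,
    long_to_cohort,
    simulate_cohort,
    simulate_null_pairs,
)
from conftest import make_single_hormone_config


def log_paired(cohort, hormone):
    wide = cohort.pivot(index="participant_id", columns="assessment", values=hormone)
    return np.log(wide[["BL", "FU"]].to_numpy())


def test_same_seed_identical_tables():
    cfg = SimulationConfig(seed=42)
    assert simulate_cohort(cfg).equals(simulate_cohort(cfg))
    other = simulate_cohort(SimulationConfig(seed=43))
    assert not simulate_cohort(cfg).equals(other)


def test_table_shape_and_keys(small_cohort):
    assert len(small_cohort) == 17 * 2
    assert not small_cohort.duplicated(["participant_id", "assessment"]).any()
    for h in ("ghrelin", "leptin", "glp1", "pp"):
        assert (small_cohort[h] >= 0).all()
    assert set(small_cohort["assessment"]) == {"BL", "FU"}


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="true_icc"):
        HormoneSpec("x", 5.0, 0.5, true_icc=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_participants=1)
    with pytest.raises(ValueError):
        SimulationConfig(n_assessments=1)


def test_config_json_round_trip(tmp_path):
    cfg = SimulationConfig(n_participants=8, weight_drift_sd=1.5, seed=3)
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    back = SimulationConfig.from_json(path)
    assert simulate_cohort(back).equals(simulate_cohort(cfg))


def test_adding_a_hormone_does_not_perturb_others():
    specs = default_hormone_specs()
    one = simulate_cohort(SimulationConfig(
        hormone_specs={"ghrelin": specs["ghrelin"]}, seed=9))
    two = simulate_cohort(SimulationConfig(
        hormone_specs={"ghrelin": specs["ghrelin"], "leptin": specs["leptin"]}, seed=9))
    pd.testing.assert_series_equal(one["ghrelin"], two["ghrelin"])


def test_ghrelin_marginal_median_matches_published_summary():
    cfg = SimulationConfig(n_participants=1000, seed=5)
    cohort = simulate_cohort(cfg)
    bl_median = cohort[cohort.assessment == "BL"]["ghrelin"].median()
    assert bl_median == pytest.approx(771.92, rel=0.10)


def test_log_scale_total_variance_matches_spec():
    cfg = make_single_hormone_config(true_icc=0.6, n=4000, seed=21, log_sd_total=0.5)
    cohort = simulate_cohort(cfg, apply_assay=False)
    logv = np.log(cohort["ghrelin"].to_numpy())
    assert logv.var(ddof=1) == pytest.approx(0.25, rel=0.07)


def test_estimated_icc_recovers_true_icc():
    """Mean log-scale ICC(A,1) over 100 replicates at n=200 sits within
    +/-0.02 of the configured 0.99 preset."""
    ests = []
    for rep in range(100):
        cfg = make_single_hormone_config(true_icc=0.99, n=200, seed=1000 + rep)
        cohort = simulate_cohort(cfg, apply_assay=False)
        ests.append(icc_a1(log_paired(cohort, "ghrelin")).estimate)
    assert np.mean(ests) == pytest.approx(0.99, abs=0.02)


def test_weight_drift_with_leptin_effect_lowers_icc():
    """Between-assessment weight drift plus a weight->hormone effect adds
    occasion-level variance, lowering the estimated reliability on average."""
    specs = {"leptin": default_hormone_specs()["leptin"]}

    def mean_icc(drift_sd):
        ests = []
        for rep in range(30):
            cfg = SimulationConfig(
                n_participants=60,
                hormone_specs=specs,
                covariate_effects={"leptin": {"weight_kg": 0.08}},
                weight_drift_sd=drift_sd,
                seed=500 + rep,
            )
            cohort = simulate_cohort(cfg, apply_assay=False)
            ests.append(icc_a1(log_paired(cohort, "leptin")).estimate)
        return np.mean(ests)

    assert mean_icc(3.0) < mean_icc(0.0)


class TestNullPairs:
    def test_shape_and_reproducibility(self):
        pm = simulate_null_pairs(17, 0.5, seed=1)
        assert pm.values.shape == (17, 2)
        assert np.array_equal(pm.values, simulate_null_pairs(17, 0.5, seed=1).values)
        with pytest.raises(ValueError):
            simulate_null_pairs(1, 0.5, seed=0)

    def test_columns_exchangeable_on_average(self):
        diffs = [simulate_null_pairs(17, 0.5, seed=s).differences.mean()
                 for s in range(2000)]
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 4 * se + 1e-3


def test_long_wide_round_trip(small_cohort):
    hormones = ["ghrelin", "leptin", "glp1", "pp"]
    long = cohort_to_long(small_cohort, hormones)
    assert list(long.columns) == [
        "participant_id", "assessment", "hormone", "value_pgml",
        "glucose_mmol_l", "hba1c_pct", "activity_h_week", "diet_index", "weight_kg",
    ]
    wide = long_to_cohort(long)
    merged = wide.sort_values(["participant_id", "assessment"]).reset_index(drop=True)
    orig = small_cohort.sort_values(["participant_id", "assessment"]).reset_index(drop=True)
    for h in hormones:
        assert np.allclose(merged[h].astype(float), orig[h])
    dup = pd.concat([long, long.iloc[:1]])
    with pytest.raises(ValueError, match="duplicated"):
        long_to_cohort(dup)


def test_pp_upper_standard_censoring_active():
    """The PP preset's heavy right tail gets censored at the kit ceiling."""
    cfg = SimulationConfig(n_participants=800, seed=13)
    cohort = simulate_cohort(cfg)
    assert cohort["pp"].max() <= 2276.02
    assert (cohort["pp"] == 2276.02).any()
    raw = simulate_cohort(cfg, apply_assay=False)
    assert raw["pp"].max() > 2276.02
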