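import numpy as np
import pytest

from ghrelkit.simulate import (
    CovariateSpec,
    HormoneSpec,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210)


@pytest.fixture(scope="session")
def small_cohort():
    """A 17-participant, two-assessment cohort with all four hormone presets."""
    return simulate_cohort(SimulationConfig(seed=42))


def make_single_hormone_config(
    true_icc: float,
    n: int,
    seed: int,
    log_sd_total: float = 0.5,
    with_covariates: bool = False,
    **config_kwargs,
) -> SimulationConfig:
    """A minimal config with one uncensored hormone at a chosen true ICC."""
    spec = HormoneSpec("ghrelin", log_median=6.0, log_sd_total=log_sd_total,
                       true_icc=true_icc)
    cov = None
    if with_covariates:
        cov = {
            "glucose_mmol_l": CovariateSpec("glucose_mmol_l", 4.9, 0.5, 0.4),
            "hba1c_pct": CovariateSpec("hba1c_pct", 5.4, 0.17, 0.10),
            "activity_h_week": CovariateSpec("activity_h_week", 11.0, 4.0, 2.0),
            "diet_index": CovariateSpec("diet_index", 83.0, 7.0, 3.0),
        }
    kwargs = dict(
        n_participants=n,
        hormone_specs={"ghrelin": spec},
        covariate_specs=cov if cov is not None else {},
        seed=seed,
    )
    kwargs.update(config_kwargs)
    return SimulationConfig(**kwargs)
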