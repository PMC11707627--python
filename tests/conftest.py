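import numpy as np
import pytest

from trialtransport.simulate import CovariateSpec, DGPConfig


@pytest.fixture
def null_dgp():
    """Two-arm trial with one covariate and no treatment effect."""
    return DGPConfig(
        covariate_spec={"age": CovariateSpec("normal", mean=65.0, sd=9.0)},
        baseline_shape=1.0, baseline_scale=0.03,
        beta={"age": 0.03}, theta=0.0,
        censor_rate=0.05, target_shift={"age": 8.0}, seed=11,
    )


@pytest.fixture
def effect_dgp():
    """Protective treatment (hazard ratio 0.75), no interaction."""
    return DGPConfig(
        covariate_spec={"age": CovariateSpec("normal", mean=65.0, sd=9.0),
                        "cvd_history": CovariateSpec("bernoulli", p=0.15)},
        baseline_shape=1.2, baseline_scale=0.005,
        beta={"age": 0.04, "cvd_history": 0.5},
        theta=float(np.log(0.75)),
        censor_rate=0.05, target_shift={"age": 8.0}, seed=7,
    )


@pytest.fixture
def interaction_dgp():
    """Treatment effect attenuating with age; older target population."""
    return DGPConfig(
        covariate_spec={"age": CovariateSpec("normal", mean=65.0, sd=9.0)},
        baseline_shape=1.0, baseline_scale=0.004,
        beta={"age": 0.04},
        theta=float(np.log(0.75)) + 0.01 * 65.0,  # centered-at-65 main effect
        delta={"age": -0.01},
        censor_rate=0.05, target_shift={"age": 8.0}, seed=21,
    )
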