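import numpy as np
import pytest

from spikevar import (
    SyntheticConfig,
    TechnicalNoiseModel,
    generate_synthetic_experiment,
)

# study-design constants used across the suite: efficiency laws matching
# reported single-cell capture rates and a 92-species spike dilution series
THETA_MOMENTS = (0.1, 0.001)
GAMMA_MOMENTS = (0.8, 0.04)


@pytest.fixture(scope="session")
def experiment():
    """A mid-sized ground-truthed synthetic experiment shared by tests."""
    cfg = SyntheticConfig(
        n_cells=150,
        mu_theta=THETA_MOMENTS[0],
        var_theta=THETA_MOMENTS[1],
        mu_gamma=GAMMA_MOMENTS[0],
        var_gamma=GAMMA_MOMENTS[1],
    )
    return generate_synthetic_experiment(cfg, seed=11)


@pytest.fixture(scope="session")
def fitted_model(experiment):
    return TechnicalNoiseModel(random_state=0).fit(
        experiment.matrix, experiment.reference
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
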