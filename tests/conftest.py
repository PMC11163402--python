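import numpy as np
import pytest

from fcdecomp import SimulationConfig, generate_cohort, generate_latent_components


@pytest.fixture
def rng():
    return np.random.default_rng(20240606)


@pytest.fixture
def tiny_config():
    """Small balanced cohort in vector mode for fast unit tests."""
    return SimulationConfig(
        n_controls_f=2,
        n_controls_m=2,
        n_patients_f=2,
        n_patients_m=2,
        n_responders=2,
        n_rois=12,
        seed=99,
    )


@pytest.fixture
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture
def tiny_components(tiny_config, tiny_cohort):
    return generate_latent_components(tiny_config, tiny_cohort)
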