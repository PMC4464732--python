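import numpy as np
import pytest

from avrecal import DesignConfig, ObserverParams, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_params():
    """Deterministic observer: no response noise, no LED quantization."""
    return ObserverParams(sigma_V=0.0, sigma_A=0.0, quantize=False)


@pytest.fixture(scope="session")
def noiseless_table(noiseless_params):
    """One subject per mirror group, one repetition of every sequence type."""
    design = DesignConfig(reps_per_type=1, seed=3)
    return simulate_study(design, noiseless_params, n_subjects=2, seed=3)


@pytest.fixture(scope="session")
def default_study():
    """Full default cohort: 11 subjects, 9 reps, noisy quantized observer."""
    return simulate_study(DesignConfig(), ObserverParams(), n_subjects=11, seed=11)
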