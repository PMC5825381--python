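import numpy as np
import pytest

from memdecode.synthetic import DesignSpec, simulate_subject


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down recall design for fast end-to-end tests."""
    return DesignSpec(repetitions=6)


@pytest.fixture(scope="session")
def noiseless_subject(design):
    """Default-design subject with no noise and no drift: the BOLD series
    is exactly the convolved planted signal."""
    return simulate_subject(
        design,
        grid_shape=(10, 10, 12),
        roi_size_targets={"HC": 64},
        seed=7,
        amplitudes=1.0,
        noise_sd=0.0,
        drift_slope=0.0,
        n_studies=1,
    )


@pytest.fixture(scope="session")
def noisy_subject(design):
    """Default-condition subject (unit amplitude, unit noise, drift)."""
    return simulate_subject(
        design,
        grid_shape=(10, 10, 12),
        roi_size_targets={"HC": 64},
        seed=11,
        amplitudes=1.0,
        noise_sd=1.0,
        drift_slope=0.05,
        n_studies=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
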