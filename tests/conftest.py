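import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import srpt
from srpt.simulate import NoiseParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    return srpt.default_subject_model()


@pytest.fixture()
def noiseless_model():
    m = srpt.default_subject_model()
    m.noise = NoiseParams(white_sd=0.0, pink_scale=0.0)
    return m


@pytest.fixture(scope="session")
def single300():
    return srpt.make_protocol("SINGLE", stimulus_duration=300.0)


@pytest.fixture(scope="session")
def abcd300():
    return srpt.make_protocol("ABCD", stimulus_duration=300.0)


def dense_peak_to_peak(kernels, window, step=0.1):
    """Brute-force oracle: max-minus-min of summed lobes on a 0.1 ms grid."""
    grid = np.arange(window[0], window[1], step)
    wave = np.zeros_like(grid)
    for k in kernels:
        wave += srpt.component_kernel(k, grid)
    return float(wave.max() - wave.min()), grid, wave
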