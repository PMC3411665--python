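import numpy as np
import pytest

import msrbf as m


@pytest.fixture(scope="session")
def two_scale():
    """Noiseless wide+narrow overlap fixture (seed 0) and its spec."""
    spec = m.default_two_scale_spec(0)
    return spec, m.gen_two_scale_signal(spec)


@pytest.fixture(scope="session")
def noisy_two_scale():
    spec = m.default_two_scale_spec(1, noise_sd=0.02)
    return spec, m.gen_two_scale_signal(spec)


@pytest.fixture(scope="session")
def clusters():
    """Balanced, well-separated two-class point cloud."""
    return m.gen_binary_clusters(m.default_cluster_spec(0, n_per_class=50))


@pytest.fixture(scope="session")
def waveform():
    """Two-peak 500-bin record with a flat noise floor."""
    spec = m.default_waveform_spec(0)
    return m.gen_waveform(spec, n_bins=500, noise_floor_sd=spec.noise_sd)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
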