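import numpy as np
import pytest

from msfs.phantom import AcquisitionConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """2 sizes x 4 locations x 5 reps + 20 tumor-free = 60 records, 256 points."""
    return AcquisitionConfig(
        n_points=256,
        window_ns=16.32,
        tumor_sizes_mm=(2.0, 6.0),
        locations_cm=((1.0, 1.0, 3.0), (5.0, 1.0, 4.0), (1.0, 5.0, 4.0), (5.0, 5.0, 5.0)),
        reps_per_point=5,
        n_tumor_free=20,
        noise_sd=0.01,
        drift_amplitude=0.05,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)
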