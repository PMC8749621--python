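import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ppgcond as pc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_record():
    """Noise- and artifact-free 60 bpm record with its annotation."""
    cfg = pc.SynthConfig(hr_start=60, hr_end=60, artifact_gain=0.0, noise_sd=0.0, seed=11)
    return pc.generate_record(cfg)


@pytest.fixture(scope="session")
def noisy_record():
    """Motion-corrupted record at default settings."""
    return pc.generate_record(pc.SynthConfig(seed=5))


@pytest.fixture(scope="session")
def tiny_record():
    """Small handmade record for I/O and segmentation tests."""
    rng = np.random.default_rng(0)
    n = 100
    return pc.SignalRecord(
        ppg=rng.uniform(-1, 1, n),
        acc_x=rng.uniform(-1, 1, n),
        acc_y=rng.uniform(-1, 1, n),
        acc_z=rng.uniform(-1, 1, n),
        target=rng.uniform(-1, 1, n),
        sampling_rate=32.0,
        record_id="tiny",
    )
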