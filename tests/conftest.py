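import numpy as np
import pytest

from seizonset import ArtifactSpec, SeizureSpec, SynthConfig, generate_recording


@pytest.fixture(scope="session")
def synth_result():
    """One 10-minute record with a seizure and both artifact kinds."""
    cfg = SynthConfig(
        duration=600.0,
        seizures=[SeizureSpec(onset=200.0, duration=60.0, peak_hz=20.0, gain=5.0)],
        artifacts=[ArtifactSpec("saturation", 400.0, 5.0),
                   ArtifactSpec("movement", 500.0, 2.0)],
        seed=7,
    )
    return generate_recording(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
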