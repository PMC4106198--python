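import logging

import pytest
from hypothesis import HealthCheck, settings

from spectrodict import compute_mel_spectrogram, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# whitening routinely floors the one degenerate direction created by
# per-patch mean subtraction; silence the expected warning spam
logging.getLogger("spectrodict.features").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def clip_dataset():
    """Small single-label clip dataset shared across tests."""
    return generate_dataset(3, 12, "single_label_clip", seed=11, duration_s=1.5)


@pytest.fixture(scope="session")
def clip_mels(clip_dataset):
    return {c.source_id: compute_mel_spectrogram(c) for c in clip_dataset.clips}
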