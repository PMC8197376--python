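import numpy as np
import pytest

import anurapam as ap
from anurapam.classify import features_from_manifest


@pytest.fixture(scope="session")
def tone_clip():
    """A pure 1.5 kHz tone clip (half amplitude, full 5 s)."""
    t = np.arange(ap.CLIP_SAMPLES) / ap.SAMPLE_RATE
    return ap.AudioClip(0.5 * np.sin(2 * np.pi * 1500.0 * t),
                        label="ec_standard", origin_id="tone")


@pytest.fixture(scope="session")
def zero_clip():
    return ap.AudioClip(np.zeros(ap.CLIP_SAMPLES), label="ec_standard",
                        origin_id="silence")


@pytest.fixture(scope="session")
def tiny_aug_manifest():
    """5 origins per class, augmented x11 (275 clips) — smallest dataset the
    1-in-5 grouped split handles with a non-empty test set per class."""
    counts = {name: 5 for name in ap.CLASS_NAMES}
    originals = ap.generate_dataset(counts, seed=42)
    return ap.augment_dataset(originals, ap.AugmentationPlan(rng_seed=42))


@pytest.fixture(scope="session")
def tiny_features(tiny_aug_manifest):
    """Rendered CNN inputs for the tiny dataset (shared across tests)."""
    return features_from_manifest(tiny_aug_manifest)
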