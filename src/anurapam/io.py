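"""WAV input/output (RIFF PCM, 16-bit, mono, 44.1 kHz)."""

from __future__ import annotations

import numpy as np
from scipy.io import wavfile

from .calls import SAMPLE_RATE, AudioClip


def write_wav(clip: AudioClip, path) -> None:
    """Write a clip as 16-bit PCM RIFF."""
    pcm = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate,
                  (pcm * 32767.0).round().astype(np.int16))


def read_wav(path, label: str = "", origin_id: str = "",
             variant_tag: str = "original") -> AudioClip:
    """Read a 16-bit PCM mono WAV into an AudioClip with samples in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono WAV")
    if data.dtype != np.int16:
        raise ValueError(f"expected 16-bit PCM, got {data.dtype}")
    if rate != SAMPLE_RATE:
        raise ValueError(f"expected {SAMPLE_RATE} Hz, got {rate}")
    return AudioClip(samples=data.astype(np.float64) / 32767.0, label=label,
                     origin_id=origin_id, variant_tag=variant_tag)
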