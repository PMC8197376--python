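"""Audio data augmentation: 10 label-preserving variants per original clip.

The recipe enlarges a call corpus elevenfold: for every original, two
white-noise injections (default 20 and 10 dB SNR), four circular time shifts
(1.0, 1.25, 1.75, 2.0 s) and four dynamic-range compressions (quiet content
amplified by +20%/+40%, loud content attenuated by -20%/-40%).  The point is
robustness to noisy environments and to the caller's distance from the
microphone, while keeping the vocalization itself intact — hence circular
shifts (zero-padding could silently delete a call near the window edge; a
``mode="pad"`` escape hatch exists) and a compressor that leaves the loud
call band alone when amplifying the background.

Augmentation operates either on waveforms (:func:`augment_clip`) or lazily
on manifests (:func:`augment_dataset`), which only appends recipe rows; the
audio is rendered on demand via :meth:`DatasetManifest.render`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import AudioClip, DatasetManifest, _derive_seed

#: Loud/quiet classification guard band: frames whose RMS is within this
#: relative distance of the threshold count as loud, so a constant-level
#: signal is uniformly "loud" despite floating-point jitter in the mean.
_THRESHOLD_GUARD = 1e-9


@dataclass(frozen=True)
class AugmentationPlan:
    """The 10-variant recipe applied to every original clip."""

    noise_snrs_db: tuple[float, ...] = (20.0, 10.0)
    shifts_s: tuple[float, ...] = (1.0, 1.25, 1.75, 2.0)
    gain_amounts: tuple[float, ...] = (0.20, 0.40, -0.20, -0.40)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.noise_snrs_db) != 2 or len(self.shifts_s) != 4 \
                or len(self.gain_amounts) != 4:
            raise ValueError("plan must define exactly 2 + 4 + 4 = 10 recipes")
        for s in self.shifts_s:
            if not 0.0 < s < 5.0:
                raise ValueError("shifts must lie strictly inside (0, clip duration)")

    def recipes(self) -> list[tuple[str, str, float]]:
        """(variant_tag, kind, parameter) for each of the 10 variants."""
        out = []
        for i, snr in enumerate(self.noise_snrs_db, start=1):
            out.append((f"noise_{i}", "noise", float(snr)))
        for s in self.shifts_s:
            out.append((f"shift_{float(s)}", "shift", float(s)))
        for g in self.gain_amounts:
            out.append((f"gain_{g * 100:+.0f}", "gain", float(g)))
        return out


# ---------------------------------------------------------------------------
# waveform-level operations


def add_white_noise(clip: AudioClip, snr_db: float, seed: int = 0,
                    variant_tag: str | None = None) -> AudioClip:
    """Add zero-mean Gaussian white noise at the requested clip-to-noise SNR.

    The noise is scaled so clip-RMS / noise-RMS equals ``10**(snr_db/20)``;
    the sum is re-clipped to [-1, 1].  ``snr_db = inf`` is the identity.
    """
    if np.isnan(snr_db):
        raise ValueError("snr_db must not be NaN")
    x = clip.samples
    tag = variant_tag if variant_tag is not None else f"noise_snr{snr_db:g}"
    if np.isinf(snr_db) and snr_db > 0:
        return clip.replace(x.copy(), tag)
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        raise ValueError("cannot set a finite SNR on an all-zero clip")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(x.size) * (rms / 10.0 ** (snr_db / 20.0))
    return clip.replace(np.clip(x + noise, -1.0, 1.0), tag)


def time_shift(clip: AudioClip, shift_s: float, mode: str = "wrap",
               variant_tag: str | None = None) -> AudioClip:
    """Delay the clip by ``shift_s`` seconds at constant length.

    ``mode="wrap"`` (default) rotates circularly, conserving energy exactly;
    ``mode="pad"`` discards the tail and zero-fills the head.
    """
    if not 0.0 <= shift_s < clip.duration:
        raise ValueError("shift must lie in [0, clip duration)")
    k = int(round(shift_s * clip.sample_rate))
    tag = variant_tag if variant_tag is not None else f"shift_{float(shift_s)}"
    if mode == "wrap":
        y = np.roll(clip.samples, k)
    elif mode == "pad":
        y = np.zeros_like(clip.samples)
        if k < y.size:
            y[k:] = clip.samples[: y.size - k]
    else:
        raise ValueError(f"unknown shift mode {mode!r}")
    return clip.replace(y, tag)


def dynamic_compress(clip: AudioClip, amount: float, frame_s: float = 0.05,
                     fade_s: float = 0.01, allow_any_amount: bool = False,
                     variant_tag: str | None = None) -> AudioClip:
    """Frame-RMS dynamic-range compression.

    The clip is divided into ``frame_s`` frames; a frame is *loud* if its
    RMS is at or above the mean frame RMS, *quiet* below.  Positive
    ``amount`` multiplies quiet frames by (1 + amount) ("amplify the
    background"); negative ``amount`` multiplies loud frames by (1 + amount)
    ("attenuate the call").  Per-frame gains are cross-faded with a
    ``fade_s`` moving average to avoid discontinuities, and the output is
    clipped to [-1, 1].
    """
    allowed = (0.20, 0.40, -0.20, -0.40, 0.0)
    if not allow_any_amount and not any(abs(amount - a) < 1e-12 for a in allowed):
        raise ValueError(
            f"amount {amount} outside the configured set {allowed[:-1]}; "
            "pass allow_any_amount=True to override")
    tag = variant_tag if variant_tag is not None else f"gain_{amount * 100:+.0f}"
    x = clip.samples
    if amount == 0.0 or x.size == 0:
        return clip.replace(x.copy(), tag)

    frame = max(1, int(round(frame_s * clip.sample_rate)))
    n_frames = int(np.ceil(x.size / frame))
    padded = np.zeros(n_frames * frame)
    padded[: x.size] = x**2
    frame_rms = np.sqrt(padded.reshape(n_frames, frame).mean(axis=1))
    thr = frame_rms.mean() * (1.0 - _THRESHOLD_GUARD)

    gains = np.ones(n_frames)
    if amount > 0:
        gains[frame_rms < thr] = 1.0 + amount
    else:
        gains[frame_rms >= thr] = 1.0 + amount

    g = np.repeat(gains, frame)[: x.size]
    fade = int(round(fade_s * clip.sample_rate))
    if fade > 1:
        kernel = np.full(fade, 1.0 / fade)
        g = np.convolve(np.pad(g, (fade // 2, fade - 1 - fade // 2),
                               mode="edge"), kernel, mode="valid")
    return clip.replace(np.clip(x * g, -1.0, 1.0), tag)


def apply_variant(clip: AudioClip, variant_tag: str, param: float,
                  seed: int) -> AudioClip:
    """Apply the recipe encoded by a manifest row's tag/param/seed."""
    if variant_tag.startswith("noise"):
        return add_white_noise(clip, param, seed=seed, variant_tag=variant_tag)
    if variant_tag.startswith("shift"):
        return time_shift(clip, param, variant_tag=variant_tag)
    if variant_tag.startswith("gain"):
        return dynamic_compress(clip, param, variant_tag=variant_tag)
    raise ValueError(f"unknown variant tag {variant_tag!r}")


def _origin_key(origin_id: str) -> int:
    return zlib.crc32(origin_id.encode("utf-8"))


def augment_clip(clip: AudioClip, plan: AugmentationPlan) -> list[AudioClip]:
    """Produce the 10 augmented variants of one original clip."""
    if clip.variant_tag != "original":
        raise ValueError("refusing to augment an already-augmented clip")
    out = []
    okey = _origin_key(clip.origin_id)
    for vi, (tag, kind, param) in enumerate(plan.recipes()):
        seed = _derive_seed(plan.rng_seed, okey, vi)
        out.append(apply_variant(clip, tag, param, seed))
    return out


def augment_dataset(manifest: DatasetManifest,
                    plan: AugmentationPlan) -> DatasetManifest:
    """Expand a manifest of originals elevenfold (lazily, metadata only).

    Each origin keeps its original row and gains 10 recipe rows; per-variant
    noise seeds are derived from (plan seed, origin id, variant index), so
    the expansion is reproducible and identical to calling
    :func:`augment_clip` on the rendered originals.
    """
    if not manifest.is_original_only():
        raise ValueError("augment_dataset expects a manifest of originals only")
    ids = manifest.df["origin_id"]
    if ids.duplicated().any():
        raise ValueError("duplicate origin_ids in manifest")

    recipes = plan.recipes()
    blocks = []
    for _, row in manifest.df.iterrows():
        block = [row]
        okey = _origin_key(row.origin_id)
        for vi, (tag, kind, param) in enumerate(recipes):
            r = row.copy()
            r["variant_tag"] = tag
            r["aug_param"] = param
            r["aug_seed"] = _derive_seed(plan.rng_seed, okey, vi)
            block.append(r)
        blocks.append(pd.DataFrame(block))
    if not blocks:
        return DatasetManifest(manifest.df.copy())
    return DatasetManifest(pd.concat(blocks, ignore_index=True))
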