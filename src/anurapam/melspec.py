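"""Log-mel spectrogram front end: 5-s clips -> 128-band x 435-frame matrices.

A 220500-sample clip is framed with centered 2048-point Hann windows at a
hop of 507 samples, giving exactly 1 + floor(220500/507) = 435 frames; the
power spectrum is pooled through 128 triangular filters on the HTK mel scale
(fmin 0, fmax 22050 Hz) and expressed in dB with an absolute -80 dB floor.
The (128, 435) shape is the hard contract every downstream stage relies on.
The dB scale is absolute (no per-clip reference), so amplifying a clip never
lowers any cell.

Images are exported as 435x128-pixel JPEGs (time left to right, low
frequencies at the bottom, amplitude through a blue-to-red colormap) for
human inspection and for the optional train-from-image dataflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calls import CLIP_SAMPLES, SAMPLE_RATE, AudioClip


@dataclass(frozen=True)
class MelFrontEndConfig:
    """Front-end parameters; defaults honour the (128, 435) shape contract."""

    n_mels: int = 128
    n_fft: int = 2048
    hop: int = 507
    window: str = "hann"
    fmin: float = 0.0
    fmax: float = SAMPLE_RATE / 2
    log_floor_db: float = -80.0
    sample_rate: int = SAMPLE_RATE

    def n_frames(self, n_samples: int = CLIP_SAMPLES) -> int:
        """Frame count for centered framing: 1 + floor(n/hop)."""
        return 1 + n_samples // self.hop


@dataclass
class MelSpec:
    """A (n_mels, n_frames) log-mel matrix in dB with its provenance."""

    matrix: np.ndarray
    config: MelFrontEndConfig
    label: str = ""
    origin_id: str = ""
    variant_tag: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def hz_to_mel(f):
    """HTK mel scale: 2595 * log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_band_centers(config: MelFrontEndConfig) -> np.ndarray:
    """Center frequency (Hz) of each triangular mel filter."""
    edges = mel_to_hz(np.linspace(hz_to_mel(config.fmin), hz_to_mel(config.fmax),
                                  config.n_mels + 2))
    return edges[1:-1]


def mel_filterbank(config: MelFrontEndConfig) -> np.ndarray:
    """(n_mels, n_fft//2 + 1) matrix of unit-peak triangular filters."""
    n_bins = config.n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, config.sample_rate / 2, n_bins)
    edges = mel_to_hz(np.linspace(hz_to_mel(config.fmin), hz_to_mel(config.fmax),
                                  config.n_mels + 2))
    fb = np.zeros((config.n_mels, n_bins))
    for m in range(config.n_mels):
        lo, ctr, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _frames(x: np.ndarray, config: MelFrontEndConfig) -> np.ndarray:
    """Centered frames: zero-pad n_fft//2 on both sides, stride by hop."""
    pad = config.n_fft // 2
    xp = np.pad(x, (pad, pad))
    n_frames = config.n_frames(x.size)
    stride = xp.strides[0]
    return np.lib.stride_tricks.as_strided(
        xp, shape=(n_frames, config.n_fft),
        strides=(config.hop * stride, stride), writeable=False)


def compute_melspec(clip: AudioClip,
                    config: MelFrontEndConfig | None = None) -> MelSpec:
    """Log-mel power spectrogram of a 5-second clip.

    Raises if the clip is not 220500 samples at 44.1 kHz: the shape contract
    downstream (and the CNN input layer) depends on it.
    """
    cfg = config if config is not None else MelFrontEndConfig()
    if clip.sample_rate != cfg.sample_rate:
        raise ValueError(
            f"clip sample rate {clip.sample_rate} != expected {cfg.sample_rate}")
    if clip.samples.size != CLIP_SAMPLES:
        raise ValueError(
            f"clip length {clip.samples.size} != expected {CLIP_SAMPLES} "
            "samples (5 s at 44.1 kHz)")

    frames = _frames(clip.samples, cfg)
    window = np.hanning(cfg.n_fft)
    spec = np.fft.rfft(frames * window, axis=1)
    power = np.abs(spec) ** 2                       # (n_frames, n_bins)
    mel_power = mel_filterbank(cfg) @ power.T       # (n_mels, n_frames)
    floor = 10.0 ** (cfg.log_floor_db / 10.0)
    db = 10.0 * np.log10(np.maximum(mel_power, floor))
    return MelSpec(matrix=db, config=cfg, label=clip.label,
                   origin_id=clip.origin_id, variant_tag=clip.variant_tag)


def normalize_spec(spec: MelSpec | np.ndarray) -> np.ndarray:
    """Min-max scale a spectrogram matrix to [0, 1]; constants map to zeros."""
    mat = spec.matrix if isinstance(spec, MelSpec) else np.asarray(spec, float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("spectrogram contains non-finite values")
    lo, hi = mat.min(), mat.max()
    if hi == lo:
        return np.zeros_like(mat)
    return (mat - lo) / (hi - lo)


def downsample_mean(mat: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Block-average ``mat`` down to ``out_shape``, cropping remainders."""
    h, w = out_shape
    fh, fw = mat.shape[0] // h, mat.shape[1] // w
    if fh < 1 or fw < 1:
        raise ValueError("output shape larger than input")
    cropped = mat[: h * fh, : w * fw]
    return cropped.reshape(h, fh, w, fw).mean(axis=(1, 3))


def export_image(spec: MelSpec, path, cmap: str = "jet",
                 quality: int = 95) -> None:
    """Write the spectrogram as a 435x128-pixel JPEG.

    Time runs left to right, low frequencies sit at the bottom, and
    amplitude maps through a blue-to-red colormap (default ``jet``).
    """
    import matplotlib
    from PIL import Image

    norm = normalize_spec(spec)
    rgba = matplotlib.colormaps[cmap](norm)
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb = rgb[::-1]  # matrix row 0 is the lowest band; image row 0 is the top
    Image.fromarray(rgb, mode="RGB").save(path, format="JPEG", quality=quality)


def read_image(path, gray: bool = False) -> np.ndarray:
    """Decode an exported JPEG back to an array.

    With ``gray=True`` returns a (n_mels, n_frames) luminance matrix in
    [0, 1] with the original row order (low band first), usable as CNN input
    for the strict train-from-image dataflow.
    """
    from PIL import Image

    img = Image.open(path)
    if not gray:
        return np.asarray(img.convert("RGB"))
    arr = np.asarray(img.convert("L"), dtype=np.float64) / 255.0
    return arr[::-1].copy()
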