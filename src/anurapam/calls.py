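"""Synthetic anuran-like vocalizations and dataset manifests.

The classification pipeline was designed around a corpus of 865 field
recordings of *Epidalea calamita* (natterjack toad; standard, chorus and
amplexus vocalizations) and *Alytes obstetricans* (midwife toad; standard and
distress vocalizations), sampled at 44.1 kHz in 5-second segments.  That
archive has no public accession, so this module synthesises seeded,
parametric stand-ins with the same class structure: each class gets a
distinct time-frequency signature (pulsed trill, superposed chorus, quiet
slow trill, repeated whistle, rising FM sweep) over a pink-noise background.
The signatures only need to be mutually distinguishable, not biologically
faithful.

Everything is deterministic given a seed; a :class:`DatasetManifest` stores
enough per-row metadata (class, signature, seeds, augmentation recipe) that
any clip can be re-rendered bit-exactly from the manifest alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

SAMPLE_RATE = 44_100
CLIP_SECONDS = 5.0
CLIP_SAMPLES = 220_500  # round(44100 * 5.0)

#: Fixed RMS of the pink-noise background floor; the call is scaled relative
#: to this to realise a requested SNR.
NOISE_FLOOR_RMS = 0.02

CLASS_NAMES: tuple[str, ...] = (
    "ec_standard",
    "ec_chorus",
    "ec_amplexus",
    "ao_standard",
    "ao_distress",
)

#: 5-class -> 4-class merge: the two *E. calamita* advertisement-type classes
#: (standard and chorus) collapse to a single "ec_st&ch" label.
MERGED_LABEL: dict[str, str] = {
    "ec_standard": "ec_st&ch",
    "ec_chorus": "ec_st&ch",
    "ec_amplexus": "ec_amplexus",
    "ao_standard": "ao_standard",
    "ao_distress": "ao_distress",
}

MERGED_CLASS_NAMES: tuple[str, ...] = (
    "ec_st&ch",
    "ec_amplexus",
    "ao_standard",
    "ao_distress",
)

_CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


def merge_label(label: str) -> str:
    """Map a fine (5-class) label to its merged (4-class) label."""
    return MERGED_LABEL[label]


# ---------------------------------------------------------------------------
# signatures


@dataclass(frozen=True)
class CallSignature:
    """Parametric description of one vocalization class.

    Parameters
    ----------
    carrier_freq : float
        Fundamental frequency in Hz; must lie in (0, Nyquist).
    am_rate : float
        Amplitude-modulation (pulse/trill) rate in Hz; 0 disables AM.
    call_duration : float
        Duration of a single call element in seconds.
    n_repeats : int
        Sequential repeats (whistles) or superposed voices (chorus).
    fm_sweep : float
        Linear frequency sweep rate in Hz/s; 0 for constant pitch.
    harmonics : int
        Number of harmonic partials; amplitude halves per partial.
    rel_amplitude : float
        Relative call level in [0, 1]; 0 yields pure background noise.
    """

    carrier_freq: float
    am_rate: float = 0.0
    call_duration: float = 1.0
    n_repeats: int = 1
    fm_sweep: float = 0.0
    harmonics: int = 1
    rel_amplitude: float = 1.0

    def validate(self, sample_rate: int = SAMPLE_RATE,
                 clip_seconds: float = CLIP_SECONDS) -> None:
        vals = dataclasses.asdict(self)
        for k, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"signature field {k!r} must be finite, got {v!r}")
        if not 0.0 < self.carrier_freq < sample_rate / 2:
            raise ValueError("carrier_freq must lie in (0, Nyquist)")
        if self.call_duration <= 0:
            raise ValueError("call_duration must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.call_duration * self.n_repeats > clip_seconds:
            raise ValueError("call_duration * n_repeats exceeds the clip length")
        if self.harmonics < 1:
            raise ValueError("harmonics must be >= 1")
        if not 0.0 <= self.rel_amplitude <= 1.0:
            raise ValueError("rel_amplitude must lie in [0, 1]")
        if self.am_rate < 0 or self.fm_sweep < 0:
            raise ValueError("am_rate and fm_sweep must be non-negative")

    def jittered(self, rng: np.random.Generator,
                 jitter: Mapping[str, float] | None) -> "CallSignature":
        """Return a copy with multiplicative jitter on selected fields.

        ``jitter`` maps field name -> fraction f; the field is scaled by a
        factor drawn uniformly from [1-f, 1+f].
        """
        if not jitter:
            return self
        fields = dataclasses.asdict(self)
        for name, frac in jitter.items():
            fields[name] = fields[name] * rng.uniform(1.0 - frac, 1.0 + frac)
        fields["n_repeats"] = int(round(fields["n_repeats"]))
        fields["harmonics"] = int(round(fields["harmonics"]))
        return CallSignature(**fields)


def _load_signature_config() -> dict:
    path = resources.files("anurapam").joinpath("data/default_signatures.yaml")
    with path.open("r") as fh:
        return yaml.safe_load(fh)


def default_signatures() -> dict[str, CallSignature]:
    """Default per-class signatures, loaded from the packaged config file."""
    cfg = _load_signature_config()
    out = {}
    for name in CLASS_NAMES:
        fields = {k: v for k, v in cfg[name].items() if k != "jitter"}
        out[name] = CallSignature(**fields)
    return out


def signature_jitter() -> dict[str, dict[str, float]]:
    """Per-class jitter fractions from the packaged config file."""
    cfg = _load_signature_config()
    return {name: cfg[name].get("jitter", {}) for name in CLASS_NAMES}


# ---------------------------------------------------------------------------
# clips


@dataclass
class AudioClip:
    """A fixed-rate mono waveform with provenance metadata.

    ``samples`` lie in [-1, 1]; 5-second clips at 44.1 kHz have exactly
    220500 samples.  ``origin_id`` identifies the source recording a clip
    derives from (augmented variants share it), ``variant_tag`` names the
    augmentation recipe ("original" for unmodified clips).
    """

    samples: np.ndarray
    label: str
    origin_id: str = ""
    variant_tag: str = "original"
    sample_rate: int = SAMPLE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        peak = float(np.max(np.abs(self.samples))) if self.samples.size else 0.0
        if peak > 1.0 + 1e-9:
            raise ValueError(f"samples exceed [-1, 1] (peak {peak:.4f})")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def replace(self, samples: np.ndarray, variant_tag: str) -> "AudioClip":
        """New clip with modified samples and tag, same origin and label."""
        return AudioClip(samples=samples, label=self.label,
                         origin_id=self.origin_id, variant_tag=variant_tag,
                         sample_rate=self.sample_rate)


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS pink (1/f power) noise, flat below 20 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freq = np.fft.rfftfreq(n, d=1.0 / SAMPLE_RATE)
    spec *= 1.0 / np.sqrt(np.maximum(freq, 20.0))
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x**2))


def _edge_ramp(n: int, ramp_s: float = 0.01) -> np.ndarray:
    """Linear attack/release ramp to avoid onset/offset clicks."""
    env = np.ones(n)
    k = min(int(round(ramp_s * SAMPLE_RATE)), n // 2)
    if k > 0:
        ramp = np.linspace(0.0, 1.0, k, endpoint=False)
        env[:k] = ramp
        env[n - k:] = ramp[::-1]
    return env


def _element(sig: CallSignature, duration: float, rng: np.random.Generator,
             carrier_scale: float = 1.0) -> np.ndarray:
    """One call element: harmonic tone with optional AM pulsing and FM sweep."""
    n = int(round(duration * SAMPLE_RATE))
    t = np.arange(n) / SAMPLE_RATE
    f0 = sig.carrier_freq * carrier_scale
    phase = 2 * np.pi * (f0 * t + 0.5 * sig.fm_sweep * t**2)
    x = np.zeros(n)
    for h in range(1, sig.harmonics + 1):
        x += 0.5 ** (h - 1) * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    if sig.am_rate > 0:
        x *= 0.5 * (1.0 - np.cos(2 * np.pi * sig.am_rate * t
                                 + rng.uniform(0, 2 * np.pi)))
    return x * _edge_ramp(n)


def _place(buf: np.ndarray, element: np.ndarray, onset_s: float) -> None:
    i0 = int(round(onset_s * SAMPLE_RATE))
    i0 = max(0, min(i0, buf.size - 1))
    i1 = min(i0 + element.size, buf.size)
    buf[i0:i1] += element[: i1 - i0]


def _call_waveform(label: str, sig: CallSignature,
                   rng: np.random.Generator) -> np.ndarray:
    """Full-length call waveform (no noise), onset jittered in the window."""
    buf = np.zeros(CLIP_SAMPLES)
    margin = 0.1

    if label == "ec_chorus":
        # n_repeats desynchronized voices, each detuned and offset.
        span = min(sig.call_duration * 2.5, CLIP_SECONDS - 2 * margin)
        base = rng.uniform(margin, CLIP_SECONDS - margin - span)
        for _ in range(sig.n_repeats):
            dur = sig.call_duration * rng.uniform(0.8, 1.2)
            detune = rng.uniform(0.97, 1.03)
            onset = base + rng.uniform(0.0, max(span - dur, 0.0))
            _place(buf, _element(sig, dur, rng, carrier_scale=detune), onset)
    elif label == "ao_standard":
        # short whistles repeated with ~50% duty cycle
        spacing = 2.0 * sig.call_duration
        span = spacing * sig.n_repeats
        base = rng.uniform(margin, max(CLIP_SECONDS - margin - span, margin))
        for k in range(sig.n_repeats):
            _place(buf, _element(sig, sig.call_duration, rng), base + k * spacing)
    else:
        # single element (ec_standard / ec_amplexus trills, ao_distress sweep)
        span = sig.call_duration * sig.n_repeats
        base = rng.uniform(margin, max(CLIP_SECONDS - margin - span, margin))
        for k in range(sig.n_repeats):
            _place(buf, _element(sig, sig.call_duration, rng),
                   base + k * sig.call_duration)
    return buf


def generate_clip(label: str, signature: CallSignature | None = None,
                  snr_db: float = 20.0, seed: int = 0,
                  origin_id: str = "") -> AudioClip:
    """Synthesise one 5-second clip of the given class over pink noise.

    The call is scaled so that its RMS over the active (non-silent) span is
    ``10**(snr_db/20)`` times the background RMS, then multiplied by the
    signature's ``rel_amplitude``.  Deterministic in (label, signature,
    snr_db, seed).
    """
    if label not in _CLASS_INDEX:
        raise ValueError(f"unknown call class {label!r}")
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    sig = signature if signature is not None else default_signatures()[label]
    sig.validate()

    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), _CLASS_INDEX[label]]))
    call = _call_waveform(label, sig, rng)
    noise = pink_noise(CLIP_SAMPLES, rng) * NOISE_FLOOR_RMS

    active = call != 0.0
    if active.any() and sig.rel_amplitude > 0:
        call_rms = np.sqrt(np.mean(call[active] ** 2))
        target = NOISE_FLOOR_RMS * 10.0 ** (snr_db / 20.0)
        call *= (target / call_rms) * sig.rel_amplitude
    else:
        call = np.zeros_like(call)

    x = call + noise
    peak = np.max(np.abs(x))
    if peak > 0.99:
        x *= 0.99 / peak
    return AudioClip(samples=x, label=label, origin_id=origin_id,
                     variant_tag="original")


# ---------------------------------------------------------------------------
# manifests

MANIFEST_COLUMNS = [
    "origin_id", "label", "variant_tag", "clip_seed", "snr_db",
    "carrier_freq", "am_rate", "call_duration", "n_repeats", "fm_sweep",
    "harmonics", "rel_amplitude", "aug_param", "aug_seed",
]

_SIGNATURE_FIELDS = ["carrier_freq", "am_rate", "call_duration", "n_repeats",
                     "fm_sweep", "harmonics", "rel_amplitude"]


@dataclass
class DatasetManifest:
    """Inventory of clips: one row per (origin, variant).

    Rows carry everything needed to re-render the clip deterministically —
    the class label, the per-origin signature and seed, and (for augmented
    variants) the recipe tag, parameter and noise seed.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> pd.Series:
        return self.df["label"]

    def class_counts(self) -> dict[str, int]:
        counts = self.df["label"].value_counts()
        return {name: int(counts.get(name, 0)) for name in CLASS_NAMES}

    def origin_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["origin_id"]))

    def is_original_only(self) -> bool:
        return bool((self.df["variant_tag"] == "original").all())

    def originals(self) -> "DatasetManifest":
        return DatasetManifest(self.df[self.df["variant_tag"] == "original"].copy())

    def signature_for(self, i: int) -> CallSignature:
        row = self.df.iloc[i]
        return CallSignature(
            carrier_freq=float(row.carrier_freq), am_rate=float(row.am_rate),
            call_duration=float(row.call_duration), n_repeats=int(row.n_repeats),
            fm_sweep=float(row.fm_sweep), harmonics=int(row.harmonics),
            rel_amplitude=float(row.rel_amplitude))

    def render(self, i: int) -> AudioClip:
        """Re-synthesise the clip for row ``i`` (original or variant)."""
        row = self.df.iloc[i]
        original = generate_clip(row.label, self.signature_for(i),
                                 snr_db=float(row.snr_db),
                                 seed=int(row.clip_seed),
                                 origin_id=row.origin_id)
        if row.variant_tag == "original":
            return original
        from .augment import apply_variant  # deferred: augment imports calls
        return apply_variant(original, row.variant_tag,
                             float(row.aug_param), int(row.aug_seed))

    def iter_clips(self) -> Iterator[AudioClip]:
        for i in range(len(self)):
            yield self.render(i)

    def to_csv(self, path) -> None:
        # %.17g keeps the signature floats bit-exact through the round trip
        self.df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path, float_precision="round_trip"))


def _derive_seed(*parts: int) -> int:
    """Deterministic child seed below 2**31 from integer parts."""
    state = np.random.SeedSequence([int(p) for p in parts]).generate_state(1)
    return int(state[0] % (2**31))


def generate_dataset(counts_per_class: Mapping[str, int], seed: int = 0,
                     snr_db: float = 20.0,
                     signatures: Mapping[str, CallSignature] | None = None,
                     jitter: Mapping[str, Mapping[str, float]] | None = None,
                     ) -> DatasetManifest:
    """Create a manifest of original clips, one row per requested slot.

    Per-clip seeds derive deterministically from the master seed; per-origin
    signatures are jittered within class-specific ranges so origins within a
    class are distinct recordings rather than copies.
    """
    sigs = dict(signatures) if signatures is not None else default_signatures()
    jit = dict(jitter) if jitter is not None else signature_jitter()
    rows = []
    idx = 0
    for label in CLASS_NAMES:
        count = int(counts_per_class.get(label, 0))
        if count < 0:
            raise ValueError("counts must be non-negative")
        for i in range(count):
            clip_seed = _derive_seed(seed, idx)
            jrng = np.random.default_rng(
                np.random.SeedSequence([clip_seed, 7]))
            sig = sigs[label].jittered(jrng, jit.get(label))
            sig.validate()
            row = {
                "origin_id": f"{label}-{i:04d}",
                "label": label,
                "variant_tag": "original",
                "clip_seed": clip_seed,
                "snr_db": float(snr_db),
                "aug_param": np.nan,
                "aug_seed": -1,
            }
            row.update({f: getattr(sig, f) for f in _SIGNATURE_FIELDS})
            rows.append(row)
            idx += 1
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return DatasetManifest(df)
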