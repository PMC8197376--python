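"""Edge-deployment cost model: ship audio vs ship classification results.

Remote acoustic-monitoring nodes sit behind very slow radio links (order
1 kbps).  Two paradigms compete: *centralized* (the node transmits the raw
5-s WAV to the server, which classifies it) and *distributed* (the node
computes the mel-spectrogram and runs the CNN locally, transmitting only a
~70-byte result).  This module does the raw-payload arithmetic for both —
media sizes, link transmission times, end-to-end latency, the one-off cost
of pushing new model weights to a node — and flags whether each paradigm
can keep up with real time (latency not exceeding the clip duration).

Backbone (fiber) time is treated as negligible against the radio link.  A
configurable overhead multiplier (default 1.0, i.e. raw payload) stands in
for framing/protocol overhead.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MediaSpec:
    """Uncompressed PCM recording parameters."""

    duration_s: float = 5.0
    sample_rate_hz: int = 44_100
    bits_per_sample: int = 16
    channels: int = 1

    def __post_init__(self) -> None:
        if (self.duration_s < 0 or self.sample_rate_hz <= 0
                or self.bits_per_sample <= 0 or self.channels <= 0):
            raise ValueError("media parameters must be positive")


@dataclass(frozen=True)
class LinkSpec:
    """A radio link characterised by its data rate in bits per second."""

    data_rate_bps: float = 1000.0
    overhead: float = 1.0  # multiplier on payload bits (1.0 = raw)

    def __post_init__(self) -> None:
        if self.data_rate_bps <= 0:
            raise ValueError("data rate must be positive")
        if self.overhead < 1.0:
            raise ValueError("overhead multiplier must be >= 1")


@dataclass(frozen=True)
class NodeTiming:
    """Measured on-node processing times and result payload size."""

    preprocess_s: float = 0.120   # mel-spectrogram computation
    cnn_exec_s: float = 0.160     # CNN inference
    result_bytes: int = 70        # classification result for one 5-s clip

    def __post_init__(self) -> None:
        if (self.preprocess_s < 0 or self.cnn_exec_s < 0
                or self.result_bytes < 0):
            raise ValueError("node timing values must be non-negative")


@dataclass
class CostReport:
    """Per-paradigm latency breakdown for analysing one audio clip."""

    paradigm: str
    components: dict[str, float]
    audio_duration_s: float

    @property
    def total_s(self) -> float:
        return float(sum(self.components.values()))

    @property
    def realtime_feasible(self) -> bool:
        """Can the paradigm keep up with a continuous stream of clips?"""
        return self.total_s <= self.audio_duration_s

    def to_dict(self) -> dict:
        return {
            "paradigm": self.paradigm,
            "components_s": dict(self.components),
            "total_s": self.total_s,
            "audio_duration_s": self.audio_duration_s,
            "realtime_feasible": self.realtime_feasible,
        }

    def summary(self) -> str:
        lines = [f"Paradigm: {self.paradigm}"]
        for name, t in self.components.items():
            lines.append(f"  {name:<22} {t:12.3f} s")
        lines.append(f"  {'total':<22} {self.total_s:12.3f} s")
        verdict = "feasible" if self.realtime_feasible else "NOT feasible"
        lines.append(f"  real-time ({self.audio_duration_s:g} s audio): {verdict}")
        return "\n".join(lines)


def media_size(spec: MediaSpec) -> int:
    """Exact payload of an uncompressed PCM recording, in bytes."""
    return int(round(spec.duration_s * spec.sample_rate_hz
                     * spec.bits_per_sample * spec.channels / 8))


def tx_time(payload_bytes: float, link: LinkSpec) -> float:
    """Seconds to push ``payload_bytes`` through the link (linear in both)."""
    if payload_bytes < 0:
        raise ValueError("payload must be non-negative")
    return payload_bytes * 8 * link.overhead / link.data_rate_bps


def centralized_latency(media: MediaSpec, link: LinkSpec) -> CostReport:
    """Latency of shipping the raw recording to the server for analysis."""
    return CostReport(
        paradigm="centralized",
        components={"audio_transfer": tx_time(media_size(media), link)},
        audio_duration_s=media.duration_s)


def distributed_latency(timing: NodeTiming, link: LinkSpec,
                        audio_duration_s: float = 5.0) -> CostReport:
    """Latency of on-node analysis plus transmission of the small result."""
    return CostReport(
        paradigm="distributed",
        components={
            "preprocess": timing.preprocess_s,
            "cnn_execution": timing.cnn_exec_s,
            "result_transfer": tx_time(timing.result_bytes, link),
        },
        audio_duration_s=audio_duration_s)


def model_deploy_time(model_bytes: float, link: LinkSpec) -> float:
    """One-off cost of pushing a serialized model to a remote node."""
    return tx_time(model_bytes, link)


def format_bytes(n: float) -> str:
    """Render a byte count in both decimal (MB) and binary (MiB) units."""
    return f"{n / 1e6:.3f} MB ({n / 2**20:.3f} MiB)"
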