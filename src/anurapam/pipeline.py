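"""End-to-end orchestration: synth -> augment -> split -> train -> eval -> cost.

A single :class:`PipelineConfig` (YAML-serializable) is the sole source of
parameters; :func:`run_pipeline` executes every stage in order, logs per-
stage wall time and counts, and writes manifests, the trained model, the
confusion-matrix report and the deployment-cost reports into a run
directory.  Reruns with the same config and seed reproduce the manifests,
split and training bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cps
from .augment import AugmentationPlan, augment_dataset
from .calls import CLASS_NAMES, generate_dataset
from .classify import (DEFAULT_INPUT_SHAPE, CallClassifier,
                       features_from_manifest)
from .melspec import MelFrontEndConfig

log = logging.getLogger("anurapam")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline in one round-trippable object."""

    counts: dict[str, int] = field(
        default_factory=lambda: {name: 50 for name in CLASS_NAMES})
    seed: int = 0
    snr_db: float = 20.0
    task: str = "fine"                    # "fine" (5-class) or "merged" (4)
    epochs: int | None = None             # None -> task default (6 or 8)
    batch_size: int = 32
    learning_rate: float = 0.001
    input_shape: tuple[int, int] = DEFAULT_INPUT_SHAPE
    noise_snrs_db: tuple[float, ...] = (20.0, 10.0)
    shifts_s: tuple[float, ...] = (1.0, 1.25, 1.75, 2.0)
    gain_amounts: tuple[float, ...] = (0.20, 0.40, -0.20, -0.40)
    link_rate_bps: float = 1000.0
    write_audio: bool = False

    def plan(self) -> AugmentationPlan:
        return AugmentationPlan(noise_snrs_db=tuple(self.noise_snrs_db),
                                shifts_s=tuple(self.shifts_s),
                                gain_amounts=tuple(self.gain_amounts),
                                rng_seed=self.seed)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["input_shape"] = list(self.input_shape)
        d["noise_snrs_db"] = list(self.noise_snrs_db)
        d["shifts_s"] = list(self.shifts_s)
        d["gain_amounts"] = list(self.gain_amounts)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("input_shape", "noise_snrs_db", "shifts_s", "gain_amounts"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-8s done in %.2f s", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages; returns a dict of the key artifacts.

    Writes to ``out_dir``: config.yaml, manifest.csv (augmented),
    train/test manifests, model.npz, history.json, eval_report.json,
    confusion.csv, cost_report.json, and (optionally) the original WAVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    if sum(config.counts.values()) == 0:
        raise RuntimeError("pipeline stage 'synth' failed: all class counts are zero")

    originals = _stage("synth")(generate_dataset)(
        config.counts, seed=config.seed, snr_db=config.snr_db)
    log.info("synth: %d originals (%s)", len(originals), originals.class_counts())

    if config.write_audio:
        from .io import write_wav
        wav_dir = out / "wav"
        wav_dir.mkdir(exist_ok=True)
        for i in range(len(originals)):
            clip = originals.render(i)
            write_wav(clip, wav_dir / f"{clip.origin_id}.wav")

    manifest = _stage("augment")(augment_dataset)(originals, config.plan())
    manifest.to_csv(out / "manifest.csv")
    log.info("augment: %d clips total", len(manifest))

    features = _stage("melspec")(features_from_manifest)(
        manifest, MelFrontEndConfig(), config.input_shape)

    clf = CallClassifier(manifest, task=config.task,
                         input_shape=config.input_shape, seed=config.seed,
                         features=features)
    clf.train_manifest.to_csv(out / "train_manifest.csv")
    clf.test_manifest.to_csv(out / "test_manifest.csv")
    log.info("split: %d train / %d test clips",
             len(clf.train_manifest), len(clf.test_manifest))

    results = _stage("train")(clf.fit)(
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate)
    with open(out / "history.json", "w") as fh:
        json.dump(results.history, fh, indent=2)

    results.report.to_json(out / "eval_report.json")
    results.report.to_frame().to_csv(out / "confusion.csv")
    model_path, model_bytes = results.save(out / "model.npz")
    log.info("eval: test accuracy %.2f %%", results.report.accuracy_percent())

    link = cps.LinkSpec(data_rate_bps=config.link_rate_bps)
    media = cps.MediaSpec()
    cost = {
        "centralized": cps.centralized_latency(media, link).to_dict(),
        "distributed": cps.distributed_latency(cps.NodeTiming(), link).to_dict(),
        "model_bytes": model_bytes,
        "model_deploy_time_s": cps.model_deploy_time(model_bytes, link),
    }
    with open(out / "cost_report.json", "w") as fh:
        json.dump(cost, fh, indent=2)

    return {"manifest": manifest, "results": results, "cost": cost,
            "model_path": model_path, "out_dir": str(out)}
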