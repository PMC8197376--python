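"""Call classification: grouped splitting, CNN training, evaluation.

The modelling surface follows the statsmodels convention: build a
:class:`CallClassifier` from an augmented :class:`DatasetManifest`, call
``.fit()`` and receive a :class:`CallClassifierResults` carrying the trained
network, the training history, the held-out confusion matrix and a
``summary()`` table.  The underlying operations (:func:`split_dataset`,
:func:`build_model`, :func:`train_model`, :func:`evaluate`,
:func:`export_model`) are plain functions usable on their own.

Two tasks are supported: the fine 5-class problem (both *E. calamita*
advertisement contexts kept apart) and the merged 4-class problem in which
standard and chorus collapse to one "ec_st&ch" label.

The split is grouped by origin recording: per class, origins are sorted by
id and every 5th (offset 4) goes to the test set together with all 11 of its
variants, so no augmented copy of a training recording can leak into the
test set.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .calls import (CLASS_NAMES, MERGED_CLASS_NAMES, AudioClip,
                    DatasetManifest, merge_label)
from .melspec import MelFrontEndConfig, compute_melspec, downsample_mean, normalize_spec
from .nn import SequentialCNN

#: Default CNN input: the (128, 435) normalized log-mel block-averaged by
#: (4, 8) to (32, 54).  Full-resolution (128, 435) remains available.
DEFAULT_INPUT_SHAPE = (32, 54)

VARIANTS_PER_ORIGIN = 11  # original + 10 augmentations


@dataclass(frozen=True)
class CnnArchitecture:
    """Three 3x3 conv blocks (32/64/128 filters, 2x2 max pool), dense 512,
    K-way softmax."""

    n_classes: int
    conv_filters: tuple[int, ...] = (32, 64, 128)
    kernel: int = 3
    dense_units: int = 512


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe: Adam, lr 0.001, batch 32; 8 epochs for the 4-class
    task, 6 for the 5-class task."""

    epochs: int
    batch_size: int = 32
    learning_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def default_epochs(task: str) -> int:
    return 6 if task == "fine" else 8


# ---------------------------------------------------------------------------
# splitting


def split_dataset(manifest: DatasetManifest, every: int = 5, offset: int = 4
                  ) -> tuple[DatasetManifest, DatasetManifest]:
    """Grouped 1-in-``every`` train/test split, leakage-free by origin.

    Requires every origin to carry exactly 11 rows (original + 10 variants).
    Per class, origins are sorted lexicographically and indices
    offset, offset+every, ... are assigned to the test set with all of their
    variants.
    """
    df = manifest.df
    sizes = df.groupby("origin_id").size()
    bad = sizes[sizes != VARIANTS_PER_ORIGIN]
    if len(bad):
        raise ValueError(
            f"{len(bad)} origin(s) do not have exactly {VARIANTS_PER_ORIGIN} "
            f"variants (e.g. {bad.index[0]!r} has {int(bad.iloc[0])})")

    test_origins: set[str] = set()
    origins = df[df["variant_tag"] == "original"][["origin_id", "label"]]
    for label, group in origins.groupby("label"):
        ids = sorted(group["origin_id"])
        test_origins.update(ids[offset::every])

    in_test = df["origin_id"].isin(test_origins)
    return (DatasetManifest(df[~in_test].copy()),
            DatasetManifest(df[in_test].copy()))


# ---------------------------------------------------------------------------
# features


def clip_features(clip: AudioClip, frontend: MelFrontEndConfig,
                  input_shape: tuple[int, int]) -> np.ndarray:
    """Normalized, optionally block-averaged log-mel image for one clip."""
    spec = compute_melspec(clip, frontend)
    mat = normalize_spec(spec)
    if tuple(input_shape) != mat.shape:
        mat = downsample_mean(mat, tuple(input_shape))
    return mat.astype(np.float32)[..., None]


def features_from_manifest(manifest: DatasetManifest,
                           frontend: MelFrontEndConfig | None = None,
                           input_shape: tuple[int, int] = DEFAULT_INPUT_SHAPE,
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render every manifest row to a CNN input image.

    Returns ``(X, meta)`` where ``X`` has shape (n, h, w, 1) and ``meta``
    is the manifest frame (same row order).  The original waveform of each
    origin is synthesised once and re-used for its variants.
    """
    from .calls import generate_clip
    from .augment import apply_variant

    cfg = frontend if frontend is not None else MelFrontEndConfig()
    df = manifest.df
    feats = np.empty((len(df), *input_shape, 1), dtype=np.float32)
    for origin, idx in df.groupby("origin_id", sort=False).groups.items():
        idx = list(idx)
        first = df.loc[idx[0]]
        m_first = manifest.df.index.get_loc(idx[0])
        original = generate_clip(first.label, manifest.signature_for(m_first),
                                 snr_db=float(first.snr_db),
                                 seed=int(first.clip_seed), origin_id=origin)
        for j in idx:
            row = df.loc[j]
            if row.variant_tag == "original":
                clip = original
            else:
                clip = apply_variant(original, row.variant_tag,
                                     float(row.aug_param), int(row.aug_seed))
            feats[manifest.df.index.get_loc(j)] = clip_features(
                clip, cfg, input_shape)
    return feats, df


def encode_labels(labels, task: str) -> tuple[np.ndarray, tuple[str, ...]]:
    """Map string labels to class indices for the fine or merged task."""
    if task == "fine":
        names = CLASS_NAMES
        mapped = list(labels)
    elif task == "merged":
        names = MERGED_CLASS_NAMES
        mapped = [merge_label(l) for l in labels]
    else:
        raise ValueError("task must be 'fine' or 'merged'")
    index = {n: i for i, n in enumerate(names)}
    return np.array([index[l] for l in mapped], dtype=np.int64), names


# ---------------------------------------------------------------------------
# model construction / training / evaluation


def build_model(arch: CnnArchitecture, input_shape: tuple[int, int, int],
                seed: int = 0, allow_any_k: bool = False) -> SequentialCNN:
    """Seeded untrained CNN with the fixed layer sequence."""
    if arch.n_classes not in (4, 5) and not allow_any_k:
        raise ValueError("n_classes must be 4 or 5 (pass allow_any_k to override)")
    if arch.kernel != 3:
        raise ValueError("architecture is fixed to 3x3 kernels")
    return SequentialCNN(tuple(input_shape), arch.n_classes,
                         conv_filters=arch.conv_filters,
                         dense_units=arch.dense_units, seed=seed)


def train_model(model: SequentialCNN, x: np.ndarray, y: np.ndarray,
                config: TrainConfig, verbose: bool = False) -> dict:
    """Run exactly ``config.epochs`` seeded passes; returns the history."""
    return model.fit(x, y, epochs=config.epochs, batch_size=config.batch_size,
                     learning_rate=config.learning_rate, seed=config.seed,
                     verbose=verbose)


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    """Confusion matrix (rows actual, columns predicted) and derived rates."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be K x K")

    @classmethod
    def from_counts(cls, counts, class_names) -> "EvalReport":
        return cls(np.asarray(counts), tuple(class_names))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        """trace / total, in [0, 1]."""
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def row_percentages(self) -> np.ndarray:
        """Counts normalized by row sums, in percent (rounded half-up, 2 dp)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / sums
        pct = np.nan_to_num(pct)
        return np.vectorize(_round2)(pct)

    @property
    def per_class_error(self) -> np.ndarray:
        """1 - diagonal row fraction, in percent (2 dp, half-up)."""
        sums = self.counts.sum(axis=1)
        diag = np.diag(self.counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            err = 100.0 * (1.0 - diag / sums)
        err = np.nan_to_num(err)
        return np.vectorize(_round2)(err)

    def accuracy_percent(self, ndigits: int = 2) -> float:
        return _round2(100.0 * self.overall_accuracy)

    def merged(self, mapping: dict[str, str],
               merged_names: tuple[str, ...]) -> "EvalReport":
        """Sum rows/columns of classes that share a merged label."""
        k = len(merged_names)
        idx = {n: i for i, n in enumerate(merged_names)}
        out = np.zeros((k, k), dtype=np.int64)
        for i, ni in enumerate(self.class_names):
            for j, nj in enumerate(self.class_names):
                out[idx[mapping[ni]], idx[mapping[nj]]] += self.counts[i, j]
        return EvalReport(out, merged_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "counts": self.counts.tolist(),
            "row_percentages": self.row_percentages.tolist(),
            "per_class_error": self.per_class_error.tolist(),
            "overall_accuracy_percent": self.accuracy_percent(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(model: SequentialCNN, x: np.ndarray, y: np.ndarray,
             class_names: tuple[str, ...]) -> EvalReport:
    """Confusion matrix of the model on a held-out set."""
    if x.shape[0] == 0:
        raise ValueError("empty test set")
    pred = model.predict(x)
    k = len(class_names)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (np.asarray(y), pred), 1)
    return EvalReport(counts, tuple(class_names))


def export_model(model: SequentialCNN, path) -> tuple[str, int]:
    """Serialize the trained network; returns (path, on-disk byte size).

    The byte size feeds the deployment-cost model (how long pushing new
    weights to a remote node takes over its radio link).
    """
    path = os.fspath(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    model.save(path)
    return path, os.path.getsize(path)


def load_model(path) -> SequentialCNN:
    return SequentialCNN.load(path)


# ---------------------------------------------------------------------------
# model object


class CallClassifier:
    """Vocalization classifier built from an augmented dataset manifest.

    Parameters
    ----------
    manifest : DatasetManifest
        Augmented manifest (11 rows per origin).
    task : {"fine", "merged"}
        5-class problem or 4-class problem with standard+chorus merged.
    frontend : MelFrontEndConfig, optional
        Log-mel front-end parameters (defaults honour the 128x435 contract).
    input_shape : (int, int)
        CNN input resolution; the normalized spectrogram is block-averaged
        down to it (use (128, 435) for full resolution).
    seed : int
        Controls weight initialization and batch shuffling.
    features : (ndarray, DataFrame), optional
        Precomputed output of :func:`features_from_manifest` for this
        manifest, to share rendering across tasks.
    """

    def __init__(self, manifest: DatasetManifest, task: str = "fine",
                 frontend: MelFrontEndConfig | None = None,
                 input_shape: tuple[int, int] = DEFAULT_INPUT_SHAPE,
                 seed: int = 0, every: int = 5, offset: int = 4,
                 features: tuple[np.ndarray, pd.DataFrame] | None = None):
        if task not in ("fine", "merged"):
            raise ValueError("task must be 'fine' or 'merged'")
        self.manifest = manifest
        self.task = task
        self.frontend = frontend if frontend is not None else MelFrontEndConfig()
        self.input_shape = tuple(input_shape)
        self.seed = int(seed)
        self.train_manifest, self.test_manifest = split_dataset(
            manifest, every=every, offset=offset)
        self._features = features
        _, self.class_names = encode_labels([], task)
        self.arch = CnnArchitecture(n_classes=len(self.class_names))

    def _ensure_features(self):
        if self._features is None:
            self._features = features_from_manifest(
                self.manifest, self.frontend, self.input_shape)
        return self._features

    def _task_arrays(self):
        x_all, meta = self._ensure_features()
        in_test = meta["origin_id"].isin(
            set(self.test_manifest.df["origin_id"])).to_numpy()
        y_all, names = encode_labels(meta["label"], self.task)
        return (x_all[~in_test], y_all[~in_test],
                x_all[in_test], y_all[in_test], names)

    def fit(self, epochs: int | None = None, batch_size: int = 32,
            learning_rate: float = 0.001, verbose: bool = False
            ) -> "CallClassifierResults":
        """Train the CNN and evaluate it on the held-out origins."""
        cfg = TrainConfig(
            epochs=epochs if epochs is not None else default_epochs(self.task),
            batch_size=batch_size, learning_rate=learning_rate, seed=self.seed)
        x_tr, y_tr, x_te, y_te, names = self._task_arrays()
        net = build_model(self.arch, (*self.input_shape, 1), seed=self.seed)
        history = train_model(net, x_tr, y_tr, cfg, verbose=verbose)
        report = evaluate(net, x_te, y_te, names)
        return CallClassifierResults(model=self, net=net, config=cfg,
                                     history=history, report=report,
                                     n_train=len(y_tr), n_test=len(y_te))


@dataclass
class CallClassifierResults:
    """Fit results: trained network, history, held-out confusion matrix."""

    model: CallClassifier
    net: SequentialCNN
    config: TrainConfig
    history: dict
    report: EvalReport
    n_train: int
    n_test: int

    @property
    def test_accuracy(self) -> float:
        return self.report.overall_accuracy

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict(x)

    def predict_clip(self, clip: AudioClip) -> str:
        feat = clip_features(clip, self.model.frontend, self.model.input_shape)
        return self.model.class_names[int(self.net.predict(feat[None])[0])]

    def save(self, path) -> tuple[str, int]:
        return export_model(self.net, path)

    def summary(self) -> str:
        lines = []
        task = "5-class (fine)" if self.model.task == "fine" else \
            "4-class (standard+chorus merged)"
        lines.append("Anuran call classifier — compact CNN")
        lines.append("=" * 54)
        lines.append(f"Task:            {task}")
        lines.append(f"Input:           {self.model.input_shape} log-mel image")
        lines.append(f"Parameters:      {self.net.n_params:,}")
        lines.append(f"Train / test:    {self.n_train} / {self.n_test} clips "
                     "(origin-grouped split)")
        lines.append(f"Epochs x batch:  {self.config.epochs} x "
                     f"{self.config.batch_size}, Adam lr "
                     f"{self.config.learning_rate}")
        lines.append(f"Final train acc: {self.history['accuracy'][-1]:.4f}")
        lines.append(f"Test accuracy:   {self.report.accuracy_percent():.2f} %")
        lines.append("")
        lines.append("Confusion matrix (rows actual, columns predicted):")
        lines.append(self.report.to_frame().to_string())
        lines.append("")
        err = self.report.per_class_error
        for name, e in zip(self.report.class_names, err):
            lines.append(f"  {name:<14} error {e:6.2f} %")
        return "\n".join(lines)
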