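"""Training and inference for the CNN ensemble.

Each ensemble member is an independently seeded classifier trained with
cross-entropy on class-balanced, augmented draws of per-cell crop tensors.
Diversity between members comes only from initialization and augmentation
randomness.  At inference the per-model class-probability vectors are
averaged uniformly; the predicted class is the argmax of the average (ties
broken by the lowest class index) and the confidence is its maximum.  The
default ensemble size is ten; a confidence cutoff of 0.7 is the conventional
operating point for filtering uncertain cells.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .augmentation import AugmentationConfig, SamplerConfig, balanced_sampler, compose_augmentations
from .data_io import CellRecord, DatasetBundle, Prediction
from .nn import Adam, SmallCNN, softmax_cross_entropy
from .tensorization import CropSpec, CropTensor, build_input_tensor

logger = logging.getLogger("celltyper")

__all__ = [
    "ConfigurationError",
    "ModelConfig",
    "TrainedModel",
    "build_tensors",
    "ensemble_predict",
    "filter_by_confidence",
    "load_model",
    "predict_bundle",
    "save_model",
    "train_ensemble",
    "train_model",
]

DEFAULT_ENSEMBLE_SIZE = 10
DEFAULT_CONFIDENCE_CUTOFF = 0.7


class ConfigurationError(ValueError):
    """Inconsistent training or ensemble configuration."""


@dataclass
class ModelConfig:
    """Hyperparameters for one ensemble member.

    ``small_cnn`` is the CPU-scale backbone of this package's NumPy engine;
    ``resnet50`` is accepted in the enum for config compatibility but has no
    implementation here.  10-40 epochs is the usual range depending on the
    dataset.
    """

    backbone: str = "small_cnn"
    n_classes: int = 2
    input_channels: int = 3
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    base_seed: int = 0
    draws_per_epoch: int | None = None
    val_fraction: float = 0.1
    cnn_widths: tuple[int, int, int] = (16, 32, 64)

    def __post_init__(self) -> None:
        if self.backbone not in {"small_cnn", "resnet50"}:
            raise ConfigurationError(f"unknown backbone {self.backbone!r}")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is implemented")

    def make_net(self, rng: np.random.Generator) -> SmallCNN:
        if self.backbone != "small_cnn":
            raise ConfigurationError(
                "the resnet50 backbone is not implemented in this NumPy engine; "
                "use backbone='small_cnn'"
            )
        return SmallCNN(self.input_channels, self.n_classes, rng, self.cnn_widths)


@dataclass
class TrainedModel:
    """A fitted ensemble member with its vocabulary and provenance."""

    net: SmallCNN
    config: ModelConfig
    vocabulary: list[str]
    seed: int
    log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict_proba(self, tensors: Sequence[CropTensor]) -> np.ndarray:
        x = np.stack([t.values for t in tensors]).astype(np.float64)
        return self.net.predict_proba(x)


# ---------------------------------------------------------------------------
# Tensor preparation
# ---------------------------------------------------------------------------

def build_tensors(
    bundle: DatasetBundle,
    cells: Sequence[CellRecord],
    spec: CropSpec,
) -> list[CropTensor]:
    """Crop tensors for ``cells``, grouped internally by FOV for locality."""
    out: dict[tuple[str, int], CropTensor] = {}
    by_fov: dict[str, list[CellRecord]] = {}
    for rec in cells:
        by_fov.setdefault(rec.fov_id, []).append(rec)
    for fov_id, recs in by_fov.items():
        stack, mask = bundle.fovs[fov_id]
        for rec in recs:
            out[(fov_id, rec.cell_id)] = build_input_tensor(stack, mask, rec, spec)
    return [out[(r.fov_id, r.cell_id)] for r in cells]


def _stratified_split(
    records: list[CellRecord], val_fraction: float, rng: np.random.Generator
) -> tuple[list[CellRecord], list[CellRecord]]:
    by_class: dict[str, list[CellRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    train: list[CellRecord] = []
    val: list[CellRecord] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        order = rng.permutation(len(members))
        n_val = int(round(val_fraction * len(members)))
        if len(members) > 1:
            n_val = min(max(n_val, 1), len(members) - 1)
        else:
            n_val = 0
        val.extend(members[i] for i in order[:n_val])
        train.extend(members[i] for i in order[n_val:])
    return train, val


def _macro_recall(truth: np.ndarray, pred: np.ndarray, n_classes: int) -> float:
    recalls = []
    for c in range(n_classes):
        sel = truth == c
        if sel.any():
            recalls.append(float((pred[sel] == c).mean()))
    return float(np.mean(recalls)) if recalls else float("nan")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_model(
    bundle: DatasetBundle,
    crop: CropSpec,
    aug: AugmentationConfig,
    sampler: SamplerConfig,
    cfg: ModelConfig,
    seed: int,
    tensors: dict[tuple[str, int], CropTensor] | None = None,
) -> TrainedModel:
    """Train one ensemble member; fully deterministic given (data, config, seed).

    Cells are drawn per epoch by the class-balanced sampler and augmented on
    the fly; the loss is unweighted cross-entropy (class balance is the
    sampler's job).  A stratified 90/10 train/validation split of the labeled
    cells monitors per-epoch loss and macro recall.
    """
    vocab = bundle.vocabulary
    labeled = bundle.cells.labeled()
    present = {r.label for r in labeled}
    missing = [c for c in vocab if c not in present]
    if missing:
        raise ConfigurationError(f"classes absent from training labels: {missing}")
    if cfg.n_classes != len(vocab):
        raise ConfigurationError(
            f"cfg.n_classes={cfg.n_classes} but vocabulary has {len(vocab)} classes"
        )

    rng = np.random.default_rng(seed)
    net = cfg.make_net(rng)
    if cfg.input_channels != net.in_channels:
        raise ConfigurationError("input_channels mismatch")
    opt = Adam(net, lr=cfg.learning_rate)

    train_recs, val_recs = _stratified_split(labeled, cfg.val_fraction, rng)
    if tensors is None:
        all_tensors = build_tensors(bundle, labeled, crop)
        tensors = {(t.fov_id, t.cell_id): t for t in all_tensors}
    cls_index = {c: i for i, c in enumerate(vocab)}
    val_x = np.stack([tensors[(r.fov_id, r.cell_id)].values for r in val_recs]) \
        if val_recs else None
    val_y = np.array([cls_index[r.label] for r in val_recs]) if val_recs else None

    n_draws = cfg.draws_per_epoch or len(train_recs)
    log_rows = []
    for epoch in range(cfg.epochs):
        draws = balanced_sampler(bundle.cells, sampler, n_draws, rng, records=train_recs)
        batch_losses = []
        for start in range(0, len(draws), cfg.batch_size):
            chunk = draws[start : start + cfg.batch_size]
            xs = np.stack(
                [
                    compose_augmentations(tensors[(r.fov_id, r.cell_id)], aug, rng).values
                    for r in chunk
                ]
            ).astype(np.float64)
            ys = np.array([cls_index[r.label] for r in chunk])
            logits = net.forward(xs)
            loss, dlogits = softmax_cross_entropy(logits, ys)
            net.zero_grad()
            net.backward(dlogits)
            opt.step()
            batch_losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(batch_losses))}
        if val_x is not None:
            probs = net.predict_proba(val_x)
            val_loss, _ = softmax_cross_entropy(np.log(np.maximum(probs, 1e-12)), val_y)
            row["val_loss"] = val_loss
            row["val_recall"] = _macro_recall(val_y, probs.argmax(axis=1), len(vocab))
        log_rows.append(row)
        logger.info("seed %d epoch %d: %s", seed, epoch, row)
    return TrainedModel(net, cfg, list(vocab), seed, pd.DataFrame(log_rows))


def train_ensemble(
    bundle: DatasetBundle,
    crop: CropSpec,
    aug: AugmentationConfig,
    sampler: SamplerConfig,
    cfg: ModelConfig,
    n_members: int = DEFAULT_ENSEMBLE_SIZE,
) -> list[TrainedModel]:
    """Train ``n_members`` models seeded ``base_seed + i``; crops are built once."""
    labeled = bundle.cells.labeled()
    tensors = {
        (t.fov_id, t.cell_id): t for t in build_tensors(bundle, labeled, crop)
    }
    return [
        train_model(bundle, crop, aug, sampler, cfg, cfg.base_seed + i, tensors=tensors)
        for i in range(n_members)
    ]


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def ensemble_predict(
    models: Sequence[TrainedModel], tensors: Sequence[CropTensor]
) -> list[Prediction]:
    """Average per-model probabilities uniformly into one prediction per cell."""
    if not models:
        raise ConfigurationError("need at least one model")
    vocab = models[0].vocabulary
    channels = models[0].config.input_channels
    for m in models:
        if m.vocabulary != vocab or m.config.input_channels != channels:
            raise ConfigurationError("models must share vocabulary and input channels")
    if not tensors:
        return []
    probs = [m.predict_proba(tensors) for m in models]
    # average as base + mean deviation: exactly the uniform mean, but bitwise
    # equal to the single model when all members agree
    avg = probs[0] + np.mean([p - probs[0] for p in probs], axis=0)
    avg /= avg.sum(axis=1, keepdims=True)
    return [
        Prediction(t.fov_id, t.cell_id, avg[i], list(vocab))
        for i, t in enumerate(tensors)
    ]


def predict_bundle(
    models: Sequence[TrainedModel],
    bundle: DatasetBundle,
    crop: CropSpec,
    cells: Sequence[CellRecord] | None = None,
) -> list[Prediction]:
    cells = list(bundle.cells) if cells is None else list(cells)
    return ensemble_predict(models, build_tensors(bundle, cells, crop))


def filter_by_confidence(
    preds: Sequence[Prediction], cutoff: float = DEFAULT_CONFIDENCE_CUTOFF
) -> tuple[list[Prediction], float]:
    """Keep predictions with confidence >= cutoff; also return the coverage."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    if not preds:
        warnings.warn("filter_by_confidence on empty input; coverage undefined")
        return [], float("nan")
    kept = [p for p in preds if p.confidence >= cutoff]
    return kept, len(kept) / len(preds)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, directory: str | Path) -> None:
    """NumPy checkpoint plus a sidecar JSON (vocabulary, config, seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.net.state_dict())
    cfg = asdict(model.config)
    cfg["cnn_widths"] = list(cfg["cnn_widths"])
    (directory / "model.json").write_text(
        json.dumps({"config": cfg, "vocabulary": model.vocabulary, "seed": model.seed})
    )
    if len(model.log):
        model.log.to_csv(directory / "training_log.csv", index=False)


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    cfg_dict = meta["config"]
    cfg_dict["cnn_widths"] = tuple(cfg_dict["cnn_widths"])
    cfg = ModelConfig(**cfg_dict)
    net = cfg.make_net(np.random.default_rng(0))
    with np.load(directory / "weights.npz") as z:
        net.load_state_dict({k: z[k] for k in z.files})
    log_path = directory / "training_log.csv"
    log = pd.read_csv(log_path) if log_path.exists() else pd.DataFrame()
    return TrainedModel(net, cfg, list(meta["vocabulary"]), int(meta["seed"]), log)
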