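"""Augmentation, training with validation-loss checkpointing, and k-fold CV.

Augmentation draws, per output sample, a random composition of horizontal and
vertical flips, rotation (+-25 deg), zoom (0.85-1.15), brightness scaling
(0.8-1.2) and gamma correction (0.7-1.4).  Geometric transforms are applied
identically to image and mask (mask via nearest-neighbour, re-binarized);
photometric transforms touch the image only.

``train`` keeps the checkpoint with the lowest validation loss, updating on
every strict decrease; validation loss is computed with dropout disabled so
checkpoint selection is deterministic.  ``cross_validate`` partitions the
dataset into k seeded folds, augments each fold's training portion only, and
aggregates per-fold pooled metrics as mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import warp, AffineTransform

from .errors import ConfigurationError
from .evaluation import MetricReport, pooled_segmentation_metrics
from .inference import MCPrediction, predict
from .model import Adam, ModelConfig, SegmentationModel, build_model
from .synthetic import ImageSample

__all__ = ["TrainConfig", "FoldReport", "augment", "train", "cross_validate"]

ROTATION_RANGE = (-25.0, 25.0)  # degrees
ZOOM_RANGE = (0.85, 1.15)
BRIGHTNESS_RANGE = (0.8, 1.2)
GAMMA_RANGE = (0.7, 1.4)


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    augment_factor: int = 6
    k_folds: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs", "must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size", "must be >= 1")
        if self.k_folds < 2:
            raise ConfigurationError("k_folds", "must be >= 2")
        if self.augment_factor < 0:
            raise ConfigurationError("augment_factor", "must be >= 0")
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigurationError("val_fraction", "must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate", "must be > 0")


@dataclass
class FoldReport:
    fold_index: int
    metrics: MetricReport
    history: dict[str, list[float]]
    test_indices: np.ndarray
    model: SegmentationModel | None = field(default=None, repr=False)
    predictions: list[tuple[int, MCPrediction]] | None = field(default=None, repr=False)


def _geometric(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator):
    if rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        image, mask = image[::-1, :], mask[::-1, :]
    angle = np.deg2rad(rng.uniform(*ROTATION_RANGE))
    zoom = rng.uniform(*ZOOM_RANGE)
    h, w = mask.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    # output -> input map for warp: rotate by -angle, scale by 1/zoom, about center
    tform = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=-angle, scale=(1.0 / zoom, 1.0 / zoom))
        + AffineTransform(translation=center)
    )
    image = warp(np.ascontiguousarray(image), tform, order=1, mode="reflect", preserve_range=True)
    mask = warp(np.ascontiguousarray(mask).astype(np.float64), tform, order=0,
                mode="reflect", preserve_range=True)
    return image, (mask > 0.5).astype(np.int64)


def _photometric(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    image = image * rng.uniform(*BRIGHTNESS_RANGE)
    image = np.clip(image, 0.0, 1.0) ** rng.uniform(*GAMMA_RANGE)
    return np.clip(image, 0.0, 1.0)


def augment(sample: ImageSample, n: int, seed: int | None = None) -> list[ImageSample]:
    """``n`` independently perturbed copies of one sample (seeded)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        image, mask = _geometric(sample.image.astype(np.float64), sample.mask, rng)
        image = _photometric(image, rng)
        out.append(
            ImageSample(image=image.astype(np.float32), mask=mask, is_positive=bool(mask.any()))
        )
    return out


def _to_arrays(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples]).astype(np.float32)
    y = np.stack([s.mask for s in samples]).astype(np.int64)
    return x, y


def train(
    model: SegmentationModel,
    train_samples: list[ImageSample],
    val_samples: list[ImageSample],
    config: TrainConfig,
) -> tuple[SegmentationModel, dict[str, list[float]]]:
    """Train with Adam and keep the minimum-validation-loss checkpoint.

    Returns the best model (weights restored) and a history dict with
    per-epoch ``train_loss`` and ``val_loss``.
    """
    if not train_samples:
        raise ConfigurationError("train_samples", "training set is empty")
    if not val_samples:
        raise ConfigurationError("val_samples", "validation set is empty")
    x_tr, y_tr = _to_arrays(train_samples)
    x_val, y_val = _to_arrays(val_samples)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    stochastic = model.config.dropout_placement != "none"
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_state = model.state_dict()
    n = len(train_samples)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grad()
            loss = model.loss_and_grad(x_tr[idx], y_tr[idx], stochastic=stochastic, rng=rng)
            opt.step()
            losses.append(loss)
        val_loss = _batched_loss(model, x_val, y_val, config.batch_size)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:  # save only on a strict decrease
            best_loss = val_loss
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, history


def _batched_loss(model: SegmentationModel, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total = 0.0
    for start in range(0, len(x), batch):
        xb, yb = x[start:start + batch], y[start:start + batch]
        total += model.loss(xb, yb) * len(xb)
    return total / len(x)


def cross_validate(
    dataset: list[ImageSample],
    config: TrainConfig,
    model_config: ModelConfig,
    sigma: int = 25,
    keep_models: bool = False,
    keep_predictions: bool = False,
) -> tuple[list[FoldReport], dict[str, tuple[float, float]]]:
    """k-fold CV; test folds partition the dataset and are never augmented.

    Per fold, a seeded ``val_fraction`` of the training portion is held out
    for checkpoint selection, the rest is augmented ``augment_factor`` times,
    and test metrics are pooled over the fold's MC-dropout predictions.
    Returns the fold reports plus ``{metric: (mean, sd)}`` across folds.
    """
    n = len(dataset)
    if config.k_folds > n:
        raise ConfigurationError("k_folds", f"k_folds={config.k_folds} exceeds dataset size {n}")
    rng = np.random.default_rng(config.seed)
    folds = np.array_split(rng.permutation(n), config.k_folds)
    reports: list[FoldReport] = []
    for j, test_idx in enumerate(folds):
        rest = np.setdiff1d(np.arange(n), test_idx)
        rest = rest[rng.permutation(len(rest))]
        n_val = max(1, int(round(config.val_fraction * len(rest))))
        val_idx, tr_idx = rest[:n_val], rest[n_val:]
        train_samples = [dataset[i] for i in tr_idx]
        augmented = list(train_samples)
        for k, s in zip(tr_idx, train_samples):
            augmented.extend(augment(s, config.augment_factor, seed=config.seed * 100003 + int(k)))
        model = build_model(model_config, seed=config.seed + 1000 * j)
        model, history = train(model, augmented, [dataset[i] for i in val_idx], config)
        pairs = []
        predictions: list[tuple[int, MCPrediction]] = []
        for i in test_idx:
            pred = predict(model, dataset[i].image, sigma=sigma, seed=config.seed + int(i))
            pairs.append((pred.label_mask, dataset[i].mask))
            if keep_predictions:
                pred.samples = np.empty((0,) + pred.mean_probs.shape)  # free the stack
                predictions.append((int(i), pred))
        metrics = pooled_segmentation_metrics(pairs, n_classes=model_config.n_classes)
        reports.append(
            FoldReport(
                fold_index=j,
                metrics=metrics,
                history=history,
                test_indices=np.sort(test_idx),
                model=model if keep_models else None,
                predictions=predictions if keep_predictions else None,
            )
        )
    aggregate: dict[str, tuple[float, float]] = {}
    for key in ("pixel_accuracy", "mean_iou", "weighted_iou", "dice"):
        vals = np.array([getattr(r.metrics, key) for r in reports], dtype=np.float64)
        aggregate[key] = (float(vals.mean()), float(vals.std(ddof=1)))
    return reports, aggregate
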