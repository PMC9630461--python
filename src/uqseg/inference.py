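"""Monte-Carlo-dropout sampling and per-pixel uncertainty maps.

The predictive posterior mean is the arithmetic mean of ``sigma`` stochastic
softmax forward passes; uncertainty is the per-class population variance of
those samples around the mean, averaged over classes, then min-max normalized
to [0, 1] (a constant variance map normalizes to all zeros).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .model import SegmentationModel

__all__ = [
    "MCPrediction",
    "mc_sample",
    "posterior_mean",
    "variance_map",
    "normalize_uncertainty",
    "predict_labels",
    "predict",
    "export_maps",
]


@dataclass
class MCPrediction:
    samples: np.ndarray  # sigma x H x W x C softmax outputs
    mean_probs: np.ndarray  # H x W x C posterior mean
    label_mask: np.ndarray  # H x W argmax labels
    variance_map: np.ndarray  # H x W, >= 0
    uncertainty_map: np.ndarray  # H x W in [0, 1]


def mc_sample(
    model: SegmentationModel,
    image: np.ndarray,
    sigma: int,
    seed: int | None = None,
) -> np.ndarray:
    """Stack of ``sigma`` stochastic softmax passes (dropout active), seeded."""
    if sigma < 1:
        raise ValueError("sigma must be >= 1")
    if model.config.dropout_placement == "none":
        warnings.warn(
            "model has no dropout layers; MC samples will be identical", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    batch = image[None, ...]
    return np.stack(
        [model.forward(batch, stochastic=True, rng=rng)[0] for _ in range(sigma)], axis=0
    )


def posterior_mean(samples: np.ndarray) -> np.ndarray:
    """Per-pixel, per-class arithmetic mean over the sample stack."""
    samples = np.asarray(samples)
    if samples.ndim != 4 or samples.shape[0] < 1:
        raise ValueError("expected a nonempty sigma x H x W x C sample stack")
    return samples.astype(np.float64).mean(axis=0)


def variance_map(samples: np.ndarray, mean_probs: np.ndarray) -> np.ndarray:
    """Population variance (divide by sigma) per class, averaged over classes."""
    samples = np.asarray(samples)
    mean_probs = np.asarray(mean_probs)
    if samples.shape[1:] != mean_probs.shape:
        raise ValueError(
            f"sample stack {samples.shape} inconsistent with mean {mean_probs.shape}"
        )
    if samples.shape[0] == 1 or not np.any(samples != samples[0]):
        # identical samples carry no spread; make the degenerate case exact
        return np.zeros(samples.shape[1:3], dtype=np.float64)
    diff = samples.astype(np.float64) - mean_probs.astype(np.float64)[None]
    return (diff ** 2).mean(axis=0).mean(axis=-1)


def normalize_uncertainty(
    variance: np.ndarray,
    vmin: float | None = None,
    vmax: float | None = None,
) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant map becomes all zeros.

    ``vmin``/``vmax`` allow normalizing against an external (e.g. dataset-wide)
    range instead of the per-image one.
    """
    variance = np.asarray(variance, dtype=np.float64)
    lo = float(variance.min()) if vmin is None else float(vmin)
    hi = float(variance.max()) if vmax is None else float(vmax)
    if hi <= lo:
        return np.zeros_like(variance)
    return np.clip((variance - lo) / (hi - lo), 0.0, 1.0)


def predict_labels(mean_probs: np.ndarray) -> np.ndarray:
    """Per-pixel argmax; ties break toward the lower class index."""
    return np.argmax(np.asarray(mean_probs), axis=-1)


def predict(
    model: SegmentationModel,
    image: np.ndarray,
    sigma: int,
    seed: int | None = None,
    vmin: float | None = None,
    vmax: float | None = None,
) -> MCPrediction:
    """Full MC-dropout prediction for one HWC image."""
    samples = mc_sample(model, image, sigma, seed)
    mean = posterior_mean(samples)
    var = variance_map(samples, mean)
    return MCPrediction(
        samples=samples,
        mean_probs=mean,
        label_mask=predict_labels(mean),
        variance_map=var,
        uncertainty_map=normalize_uncertainty(var, vmin=vmin, vmax=vmax),
    )


def _heatmap(label_mask: np.ndarray, uncertainty: np.ndarray) -> np.ndarray:
    """Red = certain lesion, dark blue = certain background, green = uncertain."""
    h, w = label_mask.shape
    rgb = np.zeros((h, w, 3))
    certain = 1.0 - uncertainty
    rgb[..., 0] = certain * (label_mask == 1)
    rgb[..., 2] = certain * (label_mask == 0) * 0.6
    rgb[..., 1] = uncertainty
    return rgb


def export_maps(prediction: MCPrediction, out_dir: str | Path, stem: str = "prediction") -> dict[str, Path]:
    """Write label/uncertainty/heatmap PNGs plus a lossless ``.npz`` archive."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "label": out_dir / f"{stem}_label.png",
        "uncertainty": out_dir / f"{stem}_uncertainty.png",
        "heatmap": out_dir / f"{stem}_heatmap.png",
        "arrays": out_dir / f"{stem}_maps.npz",
    }
    Image.fromarray((prediction.label_mask * 255).astype(np.uint8), mode="L").save(paths["label"])
    unc8 = np.clip(np.rint(prediction.uncertainty_map * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(unc8, mode="L").save(paths["uncertainty"])
    heat8 = np.clip(np.rint(_heatmap(prediction.label_mask, prediction.uncertainty_map) * 255), 0, 255)
    Image.fromarray(heat8.astype(np.uint8), mode="RGB").save(paths["heatmap"])
    np.savez(
        paths["arrays"],
        mean_probs=prediction.mean_probs,
        label_mask=prediction.label_mask,
        variance_map=prediction.variance_map,
        uncertainty_map=prediction.uncertainty_map,
    )
    return paths
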