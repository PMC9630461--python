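"""Segmentation and uncertainty-quality metrics.

Segmentation metrics: pixel accuracy, per-class IoU, mean IoU (unweighted
mean over classes present), weighted IoU (ground-truth pixel-share weights)
and the Dice coefficient of the lesion class, all restrictable to a validity
mask.

Uncertainty-quality metrics traverse non-overlapping 2x2 patches of the
predicted labels, ground-truth labels and normalized uncertainty map.  A patch
is *accurate* iff its pixel accuracy is strictly greater than the accuracy
threshold (0.5 by default — a 2x2 patch with exactly two correct pixels is
inaccurate), and *uncertain* iff its mean uncertainty is strictly greater than
the uncertainty threshold.  From the four tallies nac/nau/nic/niu:

    p(accurate | certain)   = nac / (nac + nic)
    p(uncertain | inaccurate) = niu / (nic + niu)
    PAvPU = (nac + niu) / (nac + nau + nic + niu)

Undefined quotients (zero denominator) are reported as NaN, never raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricReport",
    "PatchCounts",
    "UncertaintyEval",
    "RemovalCurve",
    "segmentation_metrics",
    "patch_counts",
    "uncertainty_eval",
    "threshold_sweep",
    "removal_analysis",
    "find_threshold_for_remaining_ratio",
    "pooled_segmentation_metrics",
]

UNDEFINED = float("nan")  # sentinel for quotients with an empty denominator


@dataclass
class MetricReport:
    pixel_accuracy: float
    per_class_iou: dict[int, float]
    mean_iou: float
    weighted_iou: float
    dice: float
    valid_pixel_ratio: float = 1.0

    def as_dict(self) -> dict[str, float]:
        out = {
            "pixel_accuracy": self.pixel_accuracy,
            "mean_iou": self.mean_iou,
            "weighted_iou": self.weighted_iou,
            "dice": self.dice,
            "valid_pixel_ratio": self.valid_pixel_ratio,
        }
        for c, v in self.per_class_iou.items():
            out[f"iou_class_{c}"] = v
        return out


@dataclass
class PatchCounts:
    nac: int = 0  # accurate and certain
    nau: int = 0  # accurate and uncertain
    nic: int = 0  # inaccurate and certain
    niu: int = 0  # inaccurate and uncertain

    @property
    def total(self) -> int:
        return self.nac + self.nau + self.nic + self.niu

    def __add__(self, other: "PatchCounts") -> "PatchCounts":
        return PatchCounts(
            self.nac + other.nac, self.nau + other.nau,
            self.nic + other.nic, self.niu + other.niu,
        )


@dataclass
class UncertaintyEval:
    p_accurate_given_certain: float
    p_uncertain_given_inaccurate: float
    pavpu: float
    uncertainty_threshold: float


@dataclass
class RemovalCurve:
    thresholds: np.ndarray
    remaining_pixel_ratio: np.ndarray
    reports: list[MetricReport | None] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, r, rep in zip(self.thresholds, self.remaining_pixel_ratio, self.reports):
            row = {"threshold": t, "remaining_pixel_ratio": r}
            if rep is not None:
                row.update(rep.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def _class_counts(
    pred: np.ndarray, gt: np.ndarray, valid: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """(tp, fp, fn) per class plus (n_correct, n_valid) over valid pixels."""
    p, g = pred[valid], gt[valid]
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    for c in range(n_classes):
        tp[c] = int(np.sum((p == c) & (g == c)))
        fp[c] = int(np.sum((p == c) & (g != c)))
        fn[c] = int(np.sum((p != c) & (g == c)))
    return tp, fp, fn, int(np.sum(p == g)), int(p.size)


def _report_from_counts(
    tp: np.ndarray, fp: np.ndarray, fn: np.ndarray, n_correct: int, n_valid: int,
    lesion_class: int,
) -> MetricReport:
    n_classes = tp.shape[0]
    per_class: dict[int, float] = {}
    present = []
    for c in range(n_classes):
        union = tp[c] + fp[c] + fn[c]
        per_class[c] = tp[c] / union if union > 0 else UNDEFINED
        if union > 0:
            present.append(c)
    mean_iou = float(np.mean([per_class[c] for c in present])) if present else UNDEFINED
    gt_counts = tp + fn
    weighted_iou = float(
        sum((gt_counts[c] / n_valid) * per_class[c] for c in present if gt_counts[c] > 0)
    )
    denom = 2 * tp[lesion_class] + fp[lesion_class] + fn[lesion_class]
    dice = 2 * tp[lesion_class] / denom if denom > 0 else UNDEFINED
    return MetricReport(
        pixel_accuracy=n_correct / n_valid,
        per_class_iou=per_class,
        mean_iou=mean_iou,
        weighted_iou=weighted_iou,
        dice=float(dice),
        valid_pixel_ratio=1.0,
    )


def segmentation_metrics(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    valid_mask: np.ndarray | None = None,
    n_classes: int = 2,
    lesion_class: int = 1,
) -> MetricReport:
    """All segmentation metrics over the valid pixels of one mask pair.

    Classes absent from both prediction and ground truth (within the valid
    region) are skipped in mean IoU rather than scored 0 or 1.
    """
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"shape mismatch: pred {pred_mask.shape} vs gt {gt_mask.shape}")
    if valid_mask is None:
        valid = np.ones(pred_mask.shape, dtype=bool)
    else:
        valid = np.asarray(valid_mask, dtype=bool)
        if valid.shape != pred_mask.shape:
            raise ValueError(f"valid_mask shape {valid.shape} does not match {pred_mask.shape}")
    total = pred_mask.size
    if not valid.any():
        raise ValueError("valid_mask removes every pixel")
    report = _report_from_counts(
        *_class_counts(pred_mask, gt_mask, valid, n_classes), lesion_class
    )
    report.valid_pixel_ratio = float(valid.sum() / total)
    return report


def pooled_segmentation_metrics(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    valid_masks: list[np.ndarray] | None = None,
    n_classes: int = 2,
    lesion_class: int = 1,
) -> MetricReport:
    """Micro-averaged metrics from pooled pixel counts over many images."""
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    n_correct = n_valid = n_total = 0
    for i, (pred, gt) in enumerate(pairs):
        valid = (
            np.ones(np.asarray(pred).shape, dtype=bool)
            if valid_masks is None
            else np.asarray(valid_masks[i], dtype=bool)
        )
        t, f, n, c, v = _class_counts(np.asarray(pred), np.asarray(gt), valid, n_classes)
        tp += t
        fp += f
        fn += n
        n_correct += c
        n_valid += v
        n_total += np.asarray(pred).size
    if n_valid == 0:
        raise ValueError("no valid pixels across the pooled images")
    report = _report_from_counts(tp, fp, fn, n_correct, n_valid, lesion_class)
    report.valid_pixel_ratio = n_valid / n_total
    return report


def _patchify(arr: np.ndarray, patch: int) -> np.ndarray:
    """(n_patches, patch*patch) tiling with stride=patch; truncates remainders."""
    h, w = arr.shape
    if h % patch or w % patch:
        warnings.warn(
            f"image size ({h}, {w}) not divisible by patch size {patch}; "
            "truncating trailing rows/columns", stacklevel=3,
        )
        arr = arr[: h - h % patch, : w - w % patch]
        h, w = arr.shape
    return (
        arr.reshape(h // patch, patch, w // patch, patch)
        .transpose(0, 2, 1, 3)
        .reshape(-1, patch * patch)
    )


def patch_counts(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    uncertainty_map: np.ndarray,
    uncertainty_threshold: float,
    patch_size: int = 2,
    accuracy_threshold: float = 0.5,
) -> PatchCounts:
    """Tally accurate/inaccurate x certain/uncertain patches (strict inequalities)."""
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    uncertainty_map = np.asarray(uncertainty_map)
    if not (pred_mask.shape == gt_mask.shape == uncertainty_map.shape):
        raise ValueError("pred, gt and uncertainty maps must share a shape")
    acc = _patchify((pred_mask == gt_mask).astype(np.float64), patch_size).mean(axis=1)
    unc = _patchify(uncertainty_map.astype(np.float64), patch_size).mean(axis=1)
    accurate = acc > accuracy_threshold
    uncertain = unc > uncertainty_threshold
    return PatchCounts(
        nac=int(np.sum(accurate & ~uncertain)),
        nau=int(np.sum(accurate & uncertain)),
        nic=int(np.sum(~accurate & ~uncertain)),
        niu=int(np.sum(~accurate & uncertain)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def uncertainty_eval(counts: PatchCounts, uncertainty_threshold: float = UNDEFINED) -> UncertaintyEval:
    """The three conditional-probability metrics from the four patch tallies."""
    return UncertaintyEval(
        p_accurate_given_certain=_ratio(counts.nac, counts.nac + counts.nic),
        p_uncertain_given_inaccurate=_ratio(counts.niu, counts.nic + counts.niu),
        pavpu=_ratio(counts.nac + counts.niu, counts.total),
        uncertainty_threshold=uncertainty_threshold,
    )


def threshold_sweep(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    uncertainty_map: np.ndarray,
    thresholds: np.ndarray,
    patch_size: int = 2,
    accuracy_threshold: float = 0.5,
    csv_path=None,
) -> list[UncertaintyEval]:
    """One UncertaintyEval per threshold; optionally writes a CSV of the curve."""
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size == 0:
        raise ValueError("thresholds grid is empty")
    evals = [
        uncertainty_eval(
            patch_counts(pred_mask, gt_mask, uncertainty_map, float(t),
                         patch_size=patch_size, accuracy_threshold=accuracy_threshold),
            uncertainty_threshold=float(t),
        )
        for t in thresholds
    ]
    if csv_path is not None:
        sweep_frame(evals).to_csv(csv_path, index=False)
    return evals


def sweep_frame(evals: list[UncertaintyEval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": [e.uncertainty_threshold for e in evals],
            "p_accurate_given_certain": [e.p_accurate_given_certain for e in evals],
            "p_uncertain_given_inaccurate": [e.p_uncertain_given_inaccurate for e in evals],
            "pavpu": [e.pavpu for e in evals],
        }
    )


def removal_analysis(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    uncertainty_map: np.ndarray,
    thresholds: np.ndarray,
    n_classes: int = 2,
) -> RemovalCurve:
    """Metrics on the pixels whose uncertainty is <= each threshold.

    At threshold 1.0 this reproduces the unmasked metrics exactly.  A
    threshold that removes every pixel yields a ``None`` report for that
    point and the curve continues.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size == 0:
        raise ValueError("thresholds grid is empty")
    uncertainty_map = np.asarray(uncertainty_map)
    total = uncertainty_map.size
    remaining = np.empty(thresholds.size)
    reports: list[MetricReport | None] = []
    for i, t in enumerate(thresholds):
        valid = uncertainty_map <= t
        remaining[i] = valid.sum() / total
        if not valid.any():
            reports.append(None)
            continue
        reports.append(
            segmentation_metrics(pred_mask, gt_mask, valid_mask=valid, n_classes=n_classes)
        )
    return RemovalCurve(thresholds=thresholds, remaining_pixel_ratio=remaining, reports=reports)


def find_threshold_for_remaining_ratio(uncertainty_map: np.ndarray, target_ratio: float) -> float:
    """Smallest uncertainty value keeping at least ``target_ratio`` of pixels.

    Returns 1.0 for ``target_ratio == 1`` (normalized maps never exceed 1).
    """
    if not 0.0 < target_ratio <= 1.0:
        raise ValueError("target_ratio must be in (0, 1]")
    if target_ratio == 1.0:
        return 1.0
    values = np.sort(np.asarray(uncertainty_map).ravel())
    idx = int(np.ceil(target_ratio * values.size)) - 1
    return float(values[idx])
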