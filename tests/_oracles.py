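"""Independent brute-force oracles used to cross-check the package.

These are deliberately naive (explicit loops, per-element counting) and share
no code with the implementations they verify.
"""

from __future__ import annotations

import math

import numpy as np


def naive_conv_macs(Df: int, M: int, N: int, Dk: int, kind: str) -> int:
    """Count multiply-accumulates of a naive convolution by explicit loop nest.

    Same padding, stride 1: every output position sees the full kernel.
    """
    count = 0
    if kind == "conventional":
        for _x in range(Df):
            for _y in range(Df):
                for _n in range(N):
                    for _m in range(M):
                        for _ki in range(Dk):
                            for _kj in range(Dk):
                                count += 1
    elif kind == "separable":
        # depthwise: one spatial filter per input channel
        for _x in range(Df):
            for _y in range(Df):
                for _m in range(M):
                    for _ki in range(Dk):
                        for _kj in range(Dk):
                            count += 1
        # pointwise: 1x1 across channels
        for _x in range(Df):
            for _y in range(Df):
                for _n in range(N):
                    for _m in range(M):
                        count += 1
    else:
        raise ValueError(kind)
    return count


def pixel_metrics(pred, gt, valid=None, n_classes: int = 2, lesion_class: int = 1) -> dict:
    """Per-pixel loop computation of all segmentation metrics."""
    h, w = len(pred), len(pred[0])
    if valid is None:
        valid = [[True] * w for _ in range(h)]
    tp = [0] * n_classes
    fp = [0] * n_classes
    fn = [0] * n_classes
    gt_count = [0] * n_classes
    correct = 0
    total = 0
    for i in range(h):
        for j in range(w):
            if not valid[i][j]:
                continue
            total += 1
            p, g = int(pred[i][j]), int(gt[i][j])
            gt_count[g] += 1
            if p == g:
                correct += 1
                tp[p] += 1
            else:
                fp[p] += 1
                fn[g] += 1
    iou = {}
    present = []
    for c in range(n_classes):
        union = tp[c] + fp[c] + fn[c]
        iou[c] = tp[c] / union if union else math.nan
        if union:
            present.append(c)
    mean_iou = sum(iou[c] for c in present) / len(present) if present else math.nan
    weighted = sum((gt_count[c] / total) * iou[c] for c in present if gt_count[c])
    d_den = 2 * tp[lesion_class] + fp[lesion_class] + fn[lesion_class]
    dice = 2 * tp[lesion_class] / d_den if d_den else math.nan
    return {
        "pixel_accuracy": correct / total,
        "per_class_iou": iou,
        "mean_iou": mean_iou,
        "weighted_iou": weighted,
        "dice": dice,
    }


def patch_tallies(pred, gt, unc, u_thresh: float, patch: int = 2, a_thresh: float = 0.5):
    """Exhaustive per-patch enumeration of nac/nau/nic/niu (strict inequalities)."""
    h, w = len(pred), len(pred[0])
    nac = nau = nic = niu = 0
    for i0 in range(0, h - h % patch, patch):
        for j0 in range(0, w - w % patch, patch):
            n_correct = 0
            u_sum = 0.0
            for i in range(i0, i0 + patch):
                for j in range(j0, j0 + patch):
                    if int(pred[i][j]) == int(gt[i][j]):
                        n_correct += 1
                    u_sum += float(unc[i][j])
            accurate = (n_correct / (patch * patch)) > a_thresh
            uncertain = (u_sum / (patch * patch)) > u_thresh
            if accurate and not uncertain:
                nac += 1
            elif accurate and uncertain:
                nau += 1
            elif not accurate and not uncertain:
                nic += 1
            else:
                niu += 1
    return nac, nau, nic, niu


def two_pass_variance(samples) -> np.ndarray:
    """Two-pass per-pixel variance oracle, averaged over classes."""
    samples = np.asarray(samples, dtype=np.float64)
    s, h, w, c = samples.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for k in range(c):
                mean = sum(samples[t, i, j, k] for t in range(s)) / s
                acc += sum((samples[t, i, j, k] - mean) ** 2 for t in range(s)) / s
            out[i, j] = acc / c
    return out


def argmax_labels(probs) -> np.ndarray:
    """Per-pixel comparison argmax (first maximal index wins)."""
    probs = np.asarray(probs)
    h, w, c = probs.shape
    out = np.zeros((h, w), dtype=np.int64)
    for i in range(h):
        for j in range(w):
            best, best_v = 0, probs[i, j, 0]
            for k in range(1, c):
                if probs[i, j, k] > best_v:
                    best, best_v = k, probs[i, j, k]
            out[i, j] = best
    return out
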