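"""Overlap and boundary-distance metrics for binary segmentations.

DSC and IoU measure region overlap; HD95 is the 95th percentile of the
pooled symmetric boundary-to-boundary nearest distances and is the more
shape-sensitive of the three.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["dice", "iou", "hd95", "evaluate_masks"]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(pred).astype(bool)
    b = np.asarray(truth).astype(bool)
    if a.shape != b.shape:
        raise ValueError("pred and truth must have the same shape")
    return a, b


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); both empty -> 1."""
    a, b = _check_pair(pred, truth)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union |A∩B| / |A∪B|; both empty -> 1."""
    a, b = _check_pair(pred, truth)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one background 4-neighbor (border counts)."""
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~eroded


def hd95(pred: np.ndarray, truth: np.ndarray, spacing: float = 1.0) -> float:
    """95th percentile of symmetric boundary nearest distances, scaled by spacing.

    Distances from every boundary pixel of each mask to the nearest boundary
    pixel of the other are pooled from both directions before taking the
    percentile (linear interpolation between order statistics). An empty
    mask has no boundary; the distance is then undefined and infinity is
    returned with a warning.
    """
    a, b = _check_pair(pred, truth)
    if not a.any() or not b.any():
        warnings.warn("hd95 of an empty mask is undefined; returning inf", stacklevel=2)
        return float("inf")
    ba = _boundary(a)
    bb = _boundary(b)
    # distance map to the nearest boundary pixel of the other mask
    dist_to_bb = ndimage.distance_transform_edt(~bb)
    dist_to_ba = ndimage.distance_transform_edt(~ba)
    pooled = np.concatenate([dist_to_bb[ba], dist_to_ba[bb]])
    return float(np.percentile(pooled, 95)) * spacing


def evaluate_masks(
    preds: list[np.ndarray], truths: list[np.ndarray], spacing: float = 1.0
) -> pd.DataFrame:
    """Per-frame DSC/IoU/HD95 table with a trailing mean +/- SD aggregate row."""
    if len(preds) != len(truths):
        raise ValueError("pred/truth counts differ")
    rows = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        rows.append(
            {"frame": str(i), "dsc": dice(p, t), "iou": iou(p, t), "hd95": hd95(p, t, spacing)}
        )
    df = pd.DataFrame(rows)
    agg = {
        "frame": "mean±sd",
        "dsc": df["dsc"].mean(),
        "iou": df["iou"].mean(),
        "hd95": df["hd95"].mean(),
    }
    sd = {
        "frame": "sd",
        "dsc": df["dsc"].std(ddof=1) if len(df) > 1 else 0.0,
        "iou": df["iou"].std(ddof=1) if len(df) > 1 else 0.0,
        "hd95": df["hd95"].std(ddof=1) if len(df) > 1 else 0.0,
    }
    return pd.concat([df, pd.DataFrame([agg, sd])], ignore_index=True)
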