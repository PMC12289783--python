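"""Pixelwise confusion counting and overlap metrics.

The ``standard`` formula set is the field's usual definitions.  The
``verbatim`` set reproduces the source text's printed expressions, in which
the IoU and DSC formulas are interchanged (printed IoU = 2TP/(2TP+FP+FN),
printed DSC = TP/(TP+FP+FN)); it is kept for auditability only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_mask, gt_mask, threshold: float = 0.5) -> ConfusionCounts:
    """Count pixels after thresholding ``pred_mask`` at ``threshold``."""
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if not np.all(np.isin(gt, (0, 1))):
        raise ValueError("ground truth must be binary")
    p = pred >= threshold
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
    )


def _ratio(num: float, den: float, counts: ConfusionCounts) -> float:
    if den == 0:
        # no relevant pixels: perfect agreement scores 1, anything else 0
        val = 1.0 if counts.fp == 0 and counts.fn == 0 else 0.0
        logger.warning("metric denominator is 0; defined as %.0f", val)
        return val
    return num / den


def metrics(counts: ConfusionCounts, formula_set: str = "standard") -> dict:
    """Precision, recall, IoU and DSC from pixel counts.

    ``formula_set='verbatim'`` swaps the IoU/DSC expressions as printed in
    the source text.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    out = {
        "precision": _ratio(tp, tp + fp, counts),
        "recall": _ratio(tp, tp + fn, counts),
    }
    if formula_set == "standard":
        out["iou"] = _ratio(tp, tp + fp + fn, counts)
        out["dsc"] = _ratio(2 * tp, 2 * tp + fp + fn, counts)
    elif formula_set == "verbatim":
        out["iou"] = _ratio(2 * tp, 2 * tp + fp + fn, counts)
        out["dsc"] = _ratio(tp, tp + fp + fn, counts)
    else:
        raise ValueError(f"unknown formula_set {formula_set!r}")
    return out
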