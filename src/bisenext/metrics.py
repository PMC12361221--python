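"""Segmentation metrics via confusion-matrix accumulation.

Per-class IoU, precision, recall and Dice are computed from a (k+1)x(k+1)
pixel-count matrix (true class i, predicted class j); mIoU and mF1 average
over all k+1 classes including background.  Classes absent from both truth
and prediction have undefined metrics; they are excluded from the means
with a warning instead of propagating NaN.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_CLASSES = ("background", "leaf", "disease")


class ConfusionMatrix:
    """Accumulated pixel counts over a dataset."""

    def __init__(self, num_classes: int = 3, class_names=None):
        if num_classes < 2:
            raise ValueError("need at least 2 classes")
        self.num_classes = num_classes
        self.class_names = list(class_names or
                                (DEFAULT_CLASSES if num_classes == 3
                                 else [f"class{i}" for i in range(num_classes)]))
        self.counts = np.zeros((num_classes, num_classes), dtype=np.int64)

    def accumulate(self, truth_mask, pred_mask) -> "ConfusionMatrix":
        truth = np.asarray(truth_mask).ravel()
        pred = np.asarray(pred_mask).ravel()
        if truth.shape != pred.shape:
            raise ValueError("truth and prediction masks must have the same shape")
        for name, arr in (("truth", truth), ("prediction", pred)):
            bad = (arr < 0) | (arr >= self.num_classes)
            if bad.any():
                raise ValueError(
                    f"{name} mask contains out-of-range label {int(arr[bad][0])} "
                    f"(valid: 0..{self.num_classes - 1})")
        k = self.num_classes
        self.counts += np.bincount(truth * k + pred, minlength=k * k).reshape(k, k)
        return self

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        out = ConfusionMatrix(self.num_classes, self.class_names)
        out.counts = self.counts + other.counts
        return out

    @property
    def total_pixels(self) -> int:
        return int(self.counts.sum())

    # -- per-class quantities ----------------------------------------------
    def tp(self) -> np.ndarray:
        return np.diag(self.counts).astype(float)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1).astype(float) - self.tp()

    def _safe(self, num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
        out = np.full(self.num_classes, np.nan)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        if not ok.all():
            missing = [self.class_names[i] for i in np.flatnonzero(~ok)]
            warnings.warn(f"{what} undefined for absent class(es) {missing}; "
                          "excluded from means", stacklevel=3)
        return out

    def per_class_iou(self) -> np.ndarray:
        tp, fp, fn = self.tp(), self.fp(), self.fn()
        return self._safe(tp, tp + fp + fn, "IoU")

    def miou(self) -> float:
        return float(np.nanmean(self.per_class_iou()))

    def precision(self) -> np.ndarray:
        tp = self.tp()
        return self._safe(tp, tp + self.fp(), "precision")

    def recall(self) -> np.ndarray:
        tp = self.tp()
        return self._safe(tp, tp + self.fn(), "recall")

    def dice(self) -> np.ndarray:
        tp, fp, fn = self.tp(), self.fp(), self.fn()
        return self._safe(2 * tp, 2 * tp + fp + fn, "Dice")

    def mf1(self) -> float:
        return float(np.nanmean(self.dice()))

    def precision_recall_dice(self, class_index: int) -> tuple[float, float, float]:
        return (float(self.precision()[class_index]),
                float(self.recall()[class_index]),
                float(self.dice()[class_index]))

    # -- reporting ----------------------------------------------------------
    def report(self) -> pd.DataFrame:
        """Per-class IoU/Precision/Recall/Dice table plus mIoU/mF1 summary row."""
        df = pd.DataFrame({
            "class": self.class_names,
            "IoU": self.per_class_iou(),
            "Precision": self.precision(),
            "Recall": self.recall(),
            "Dice": self.dice(),
        })
        return df

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "classes": self.class_names,
            "iou": self.per_class_iou().tolist(),
            "precision": self.precision().tolist(),
            "recall": self.recall().tolist(),
            "dice": self.dice().tolist(),
            "miou": self.miou(),
            "mf1": self.mf1(),
            "pixels": self.total_pixels,
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=2))
        return d

    def to_csv(self, path: str | Path) -> None:
        self.report().to_csv(path, index=False)
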