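"""Mask quantification and evaluation against gold-standard masks.

Area of an annotated polygon comes from the shoelace (Gaussian area)
formula; a mask's percent-cells is its foreground fraction of the image;
predicted masks are scored against gold standards with pixel accuracy
(TP + TN) / n and the Dice score 2·TP / (2·TP + FP + FN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts with cell as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def shoelace_area(vertices: Sequence[tuple[float, float]]) -> float:
    """Area of a simple polygon from its ordered vertices.

    A = ½ |Σ x_i·y_{i+1} − Σ x_{i+1}·y_i| (indices cyclic). The absolute
    value makes the result independent of vertex orientation; concave
    polygons are handled.
    """
    if len(vertices) < 3:
        raise ValidationError("polygon area needs >= 3 vertices")
    xs = np.asarray([v[0] for v in vertices], dtype=np.float64)
    ys = np.asarray([v[1] for v in vertices], dtype=np.float64)
    return 0.5 * abs(float(np.dot(xs, np.roll(ys, -1)) - np.dot(np.roll(xs, -1), ys)))


def percent_cells(mask: np.ndarray) -> float:
    """Percent of image area covered by cells: 100 · A_cells / A_img."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValidationError("mask must be a non-empty 2D array")
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def confusion_counts(predicted: np.ndarray, gold: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts between a predicted and a gold mask."""
    predicted = np.asarray(predicted) > 0
    gold = np.asarray(gold) > 0
    if predicted.shape != gold.shape:
        raise ValidationError(
            f"shape mismatch: predicted {predicted.shape} vs gold {gold.shape}"
        )
    tp = int(np.count_nonzero(predicted & gold))
    tn = int(np.count_nonzero(~predicted & ~gold))
    fp = int(np.count_nonzero(predicted & ~gold))
    fn = int(np.count_nonzero(~predicted & gold))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / n."""
    if c.n == 0:
        raise ValidationError("accuracy undefined for empty masks (n = 0)")
    return (c.tp + c.tn) / c.n


def dice(c: ConfusionCounts) -> float:
    """2·TP / (2·TP + FP + FN); 1.0 when both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        logger.info("Dice of two empty masks: returning 1.0 by convention")
        return 1.0
    return 2 * c.tp / denom


def evaluate_masks(
    pairs: Iterable[tuple[int, np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Score (frame, predicted, gold) triples.

    Returns one row per frame with confusion counts, accuracy and Dice,
    plus a final summary row of unweighted means labelled ``mean``.
    """
    records = []
    for frame, predicted, gold in pairs:
        c = confusion_counts(predicted, gold)
        records.append(
            {
                "frame": frame,
                "tp": c.tp,
                "tn": c.tn,
                "fp": c.fp,
                "fn": c.fn,
                "accuracy": accuracy(c),
                "dice": dice(c),
            }
        )
    if not records:
        raise ValidationError("no mask pairs to evaluate")
    df = pd.DataFrame.from_records(records)
    summary = {
        "frame": "mean",
        "tp": df["tp"].mean(),
        "tn": df["tn"].mean(),
        "fp": df["fp"].mean(),
        "fn": df["fn"].mean(),
        "accuracy": df["accuracy"].mean(),
        "dice": df["dice"].mean(),
    }
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


def block_frames(n_frames: int, step: int = 100) -> list[int]:
    """Frame indices evaluated in block mode: 0, step, 2·step, ..."""
    if step < 1:
        raise ValidationError("block step must be >= 1")
    return list(range(0, n_frames, step))


def write_evaluation_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
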