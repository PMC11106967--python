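"""Voxel-wise evaluation: confusion counts, precision/recall/Dice, PSNR.

Metrics are computed on entire reassembled volumes, never on individual
sub-tiles.  Degenerate denominators surface as an explicit ``None``
("undefined"), never as a silent 0 or 1; the single documented exception is
the Dice harmonic mean, which is 0 by convention when precision and recall
are both 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volume_io import LabelVolume

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "precision",
    "recall",
    "dice_from_pr",
    "dice_from_counts",
    "psnr",
    "improvement",
    "evaluate_volumes",
    "comparison_volume",
    "round_metric",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-wise confusion counts for binary root segmentation."""

    true_positive: int
    false_positive: int
    false_negative: int
    true_negative: int

    def __post_init__(self) -> None:
        if min(
            self.true_positive,
            self.false_positive,
            self.false_negative,
            self.true_negative,
        ) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return (
            self.true_positive
            + self.false_positive
            + self.false_negative
            + self.true_negative
        )


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts with derived precision, recall and Dice."""

    counts: ConfusionCounts
    precision: float | None
    recall: float | None
    dice: float | None

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "true_positive": c.true_positive,
            "false_positive": c.false_positive,
            "false_negative": c.false_negative,
            "true_negative": c.true_negative,
            "precision": self.precision,
            "recall": self.recall,
            "dice": self.dice,
        }


def _as_bool(vol) -> np.ndarray:
    data = vol.data if isinstance(vol, LabelVolume) else np.asarray(vol)
    return data.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Count TP/FP/FN/TN voxels between a prediction and the ground truth."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def precision(c: ConfusionCounts) -> float | None:
    """TP / (TP + FP); ``None`` when nothing was predicted positive."""
    denom = c.true_positive + c.false_positive
    if denom == 0:
        return None
    return c.true_positive / denom


def recall(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN); ``None`` when the truth has no positive voxels."""
    denom = c.true_positive + c.false_negative
    if denom == 0:
        return None
    return c.true_positive / denom


def dice_from_pr(precision: float, recall: float) -> float:
    """Dice as the harmonic mean 2PR/(P+R); 0 when both inputs are 0."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def dice_from_counts(c: ConfusionCounts) -> float | None:
    """Dice directly from counts, 2TP/(2TP+FP+FN); ``None`` if undefined."""
    denom = 2 * c.true_positive + c.false_positive + c.false_negative
    if denom == 0:
        return None
    return 2 * c.true_positive / denom


def psnr(noisy, reference, max_val: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical inputs."""
    a = np.asarray(noisy, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(max_val**2 / mse)


def improvement(a: float, b: float) -> float:
    """Relative improvement of b over a, as a percentage: 100*(a-b)/a."""
    if a == 0:
        raise ValueError("improvement undefined for a = 0")
    return 100.0 * (a - b) / a


def round_metric(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, as used for metric tables."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def evaluate_volumes(pred, truth) -> MetricsReport:
    """Full report (counts + precision/recall/Dice) on reassembled volumes."""
    c = confusion(pred, truth)
    return MetricsReport(
        counts=c,
        precision=precision(c),
        recall=recall(c),
        dice=dice_from_counts(c),
    )


# colour encoding for qualitative comparison renderings
_WHITE = (255, 255, 255)
_BLUE = (0, 0, 255)
_RED = (255, 0, 0)


def comparison_volume(pred, truth) -> np.ndarray:
    """RGB overlay: white = TP, blue = FP, red = FN, black = TN.

    Returns an ``(H, W, D, 3)`` uint8 array suitable for writing as an
    RGB slice stack.
    """
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    out = np.zeros(p.shape + (3,), dtype=np.uint8)
    out[p & t] = _WHITE
    out[p & ~t] = _BLUE
    out[~p & t] = _RED
    return out
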