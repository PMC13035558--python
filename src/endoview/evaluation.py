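"""Evaluation protocol: interval recall for surgery, segment-mode confusion
matrices and per-class precision/recall for visibility.

Surgery detection is judged at interval level: a ground-truth tool interval
counts for Recall@1 when at least one of its frames is flagged, and for
Recall@50% when at least half are. Visibility is judged at segment level: a
predicted segment is compared against the *mode* of the ground-truth frame
labels over its span (projected to super classes for the binary view).
Segments predicted Uncertain carry no class claim, so they are excluded from
the confusion matrix and reported as a separate count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from endoview.discovery import ClassHierarchy
from endoview.errors import FormatError, InvalidInputError
from endoview.partition import UNCERTAIN, FrameLabels, Segmentation, SurgeryTrack

__all__ = [
    "IntervalAnnotation",
    "ConfusionMatrix",
    "surgery_recall",
    "segment_mode_eval",
    "precision_recall",
    "noninformative_fraction",
    "read_intervals",
]


@dataclass
class IntervalAnnotation:
    """Ordered, non-overlapping half-open labeled intervals (ground truth)."""

    intervals: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end, _ in self.intervals:
            if end <= start:
                raise InvalidInputError(f"empty interval ({start}, {end})")
            if start < prev_end:
                raise InvalidInputError(
                    f"intervals overlap or are unordered at ({start}, {end})"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    def to_frame_labels(self, n_frames: int, fill: str) -> FrameLabels:
        """Expand intervals to a dense per-frame label sequence; frames not
        covered by any interval get ``fill``."""
        labels = np.full(n_frames, fill, dtype=object)
        for s, e, lab in self.intervals:
            labels[s:e] = lab
        return FrameLabels(labels=labels, frame_index=np.arange(n_frames))


@dataclass
class ConfusionMatrix:
    """Rows are true labels, columns predicted; one count per evaluated
    segment. ``excluded_uncertain`` counts predicted-Uncertain segments that
    were left out."""

    counts: np.ndarray
    label_order: tuple[str, ...]
    excluded_uncertain: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.label_order)
        if self.counts.shape != (n, n):
            raise InvalidInputError(
                f"counts shape {self.counts.shape} != ({n}, {n})"
            )
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def surgery_recall(
    gt: IntervalAnnotation, track: SurgeryTrack | np.ndarray
) -> tuple[float, float]:
    """Interval-level recall of surgery detection.

    Per ground-truth interval, coverage = fraction of its frames flagged.
    Returns (Recall@1, Recall@50%): the fraction of intervals with coverage
    > 0 and with coverage >= 0.5 respectively.
    """
    if len(gt) == 0:
        raise InvalidInputError("surgery recall is undefined for empty ground truth")
    flags = track.flags if isinstance(track, SurgeryTrack) else np.asarray(track, bool)
    hit_any = 0
    hit_half = 0
    for s, e, _ in gt.intervals:
        if e > len(flags):
            raise InvalidInputError(
                f"ground-truth interval ({s}, {e}) exceeds track length {len(flags)}"
            )
        coverage = float(flags[s:e].mean())
        hit_any += coverage > 0.0
        hit_half += coverage >= 0.5
    return hit_any / len(gt), hit_half / len(gt)


def _mode_label(values: Sequence[str]) -> str:
    """Most frequent label; ties broken by first occurrence order."""
    arr = np.asarray(values, dtype=str)
    uniq, counts = np.unique(arr, return_counts=True)
    winners = uniq[counts == counts.max()]
    if len(winners) == 1:
        return str(winners[0])
    # deterministic tie-break: earliest winner in the sequence
    for v in arr:
        if v in winners:
            return str(v)
    raise AssertionError("unreachable")


def segment_mode_eval(
    pred: Segmentation,
    gt_frames: FrameLabels,
    hierarchy: ClassHierarchy,
    binary: bool = False,
) -> ConfusionMatrix:
    """One confusion-matrix increment per predicted segment: true label is
    the mode of the ground-truth frame labels inside the segment (projected
    to super classes when ``binary``); predicted-Uncertain segments are
    excluded but counted."""
    if pred.n_frames != len(gt_frames):
        raise InvalidInputError(
            f"prediction covers {pred.n_frames} frames, ground truth {len(gt_frames)}"
        )
    gt = np.asarray(gt_frames.labels, dtype=object)
    if binary:
        gt = np.asarray([hierarchy.project(str(v)) for v in gt], dtype=object)
        label_order = ("Informative", "Non-informative")
    else:
        label_order = tuple(hierarchy.fine_classes)
    index = {lab: i for i, lab in enumerate(label_order)}
    counts = np.zeros((len(label_order), len(label_order)), dtype=np.int64)
    excluded = 0
    for s, e, lab in pred.segments:
        pred_lab = hierarchy.project(lab) if binary else lab
        if pred_lab == UNCERTAIN:
            excluded += 1
            continue
        true_lab = _mode_label(gt[s:e])
        if true_lab not in index:
            raise InvalidInputError(f"ground-truth label {true_lab!r} not in hierarchy")
        if pred_lab not in index:
            raise InvalidInputError(f"predicted label {pred_lab!r} not in hierarchy")
        counts[index[true_lab], index[pred_lab]] += 1
    return ConfusionMatrix(
        counts=counts, label_order=label_order, excluded_uncertain=excluded
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def precision_recall(cm: ConfusionMatrix) -> dict[str, dict[str, int | None]]:
    """Per-class precision and recall in percent, rounded to the nearest
    integer (ties away from zero). A class with no predicted (resp. true)
    segments has undefined precision (resp. recall), reported as None."""
    if cm.total == 0:
        raise InvalidInputError("empty confusion matrix")
    col_sums = cm.counts.sum(axis=0)
    row_sums = cm.counts.sum(axis=1)
    out: dict[str, dict[str, int | None]] = {}
    for i, lab in enumerate(cm.label_order):
        tp = cm.counts[i, i]
        precision = (
            _round_half_away(100.0 * tp / col_sums[i]) if col_sums[i] > 0 else None
        )
        recall = (
            _round_half_away(100.0 * tp / row_sums[i]) if row_sums[i] > 0 else None
        )
        out[lab] = {"precision": precision, "recall": recall}
    return out


def noninformative_fraction(overview) -> float:
    """Fraction of frames labeled Non-informative in the binary track."""
    total = 0
    for s, e, lab in overview.binary.segments:
        if lab == "Non-informative":
            total += e - s
    return total / overview.n_frames


def read_intervals(path: str | Path) -> IntervalAnnotation:
    """Read a ground-truth interval CSV with columns ``start,end,label``
    (half-open, subsampled-stream positions)."""
    df = pd.read_csv(path)
    for col in ("start", "end", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation missing column '{col}'")
    return IntervalAnnotation(
        intervals=[(int(r.start), int(r.end), str(r.label)) for r in df.itertuples()]
    )
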