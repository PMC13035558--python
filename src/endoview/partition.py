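"""Video partitioning: nearest-centroid classification heads + temporal filters.

Given per-frame descriptors and a labeled centroid model, the per-class
distance of frame i to class L is

    d_L(i) = min_{n=1..N_L} || x_i - c_L^n ||^2

i.e. the squared Euclidean distance to the nearest centroid owned by L.

The *visibility head* assigns the closest class only when it wins clearly:

    class(f_i) = L        if d_1 < d_2 * R
               = Uncertain otherwise

with d_1 <= d_2 the two smallest class distances and R in (0, 1] a ratio
threshold (R = 1 rejects only exact ties; smaller R rejects more borderline
frames). Labels are then smoothed by a centered M-frame windowed mode, and
runs shorter than P frames are relabeled Uncertain.

The *surgery head* runs independently on d_Surgery alone: a centered moving
average of width W is thresholded at t, and maximal below-threshold runs
become surgery intervals.

All frame positions refer to the (subsampled) descriptor stream, 0-based;
intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from endoview.descriptors import DescriptorMatrix
from endoview.discovery import CentroidModel, ClassHierarchy
from endoview.errors import InvalidInputError

__all__ = [
    "UNCERTAIN",
    "SURGERY",
    "PartitionConfig",
    "SurgeryConfig",
    "ClassDistances",
    "FrameLabels",
    "Segmentation",
    "SurgeryTrack",
    "Overview",
    "class_distances",
    "visibility_classify",
    "temporal_mode_filter",
    "extract_segments",
    "suppress_short_segments",
    "surgery_detect",
    "build_overview",
    "run_partition",
]

UNCERTAIN = "Uncertain"
SURGERY = "Surgery"


@dataclass
class PartitionConfig:
    """Visibility-head settings.

    R: ratio threshold in (0, 1] for the rejection rule.
    M: mode-filter window in frames (centered, truncated at the boundaries).
    P: minimum segment length; shorter runs become Uncertain.
    """

    R: float = 0.95
    M: int = 40
    P: int = 80

    def __post_init__(self) -> None:
        if not (0.0 < self.R <= 1.0):
            raise InvalidInputError(f"R must be in (0, 1], got {self.R}")
        if self.M < 1:
            raise InvalidInputError(f"M must be >= 1, got {self.M}")
        if self.P < 1:
            raise InvalidInputError(f"P must be >= 1, got {self.P}")


@dataclass
class SurgeryConfig:
    """Surgery-head settings. W is the moving-average window; t the detection
    threshold in squared-distance units of the model's descriptor space, so
    it is specific to the embedding and dataset the model was built on."""

    W: int = 400
    t: float = 6.3

    def __post_init__(self) -> None:
        if self.W < 1:
            raise InvalidInputError(f"W must be >= 1, got {self.W}")
        if self.t <= 0:
            raise InvalidInputError(f"t must be > 0, got {self.t}")


@dataclass
class ClassDistances:
    """F x |classes| matrix of per-class minimum squared distances."""

    d: np.ndarray
    class_order: tuple[str, ...]
    frame_index: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.ndim != 2 or self.d.shape[1] != len(self.class_order):
            raise InvalidInputError(
                f"d shape {self.d.shape} inconsistent with "
                f"{len(self.class_order)} classes"
            )
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise InvalidInputError("distances must be finite and non-negative")
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)

    @property
    def n_frames(self) -> int:
        return self.d.shape[0]


@dataclass
class FrameLabels:
    """Per-frame labels over fine classes plus Uncertain."""

    labels: np.ndarray  # array of str
    frame_index: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        if len(self.labels) != len(self.frame_index):
            raise InvalidInputError("labels and frame_index lengths differ")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class Segmentation:
    """Maximal runs of identically labeled frames, half-open [start, end)
    positions in the subsampled stream; segments tile [0, F)."""

    segments: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, _ in self.segments:
            if start != prev_end or end <= start:
                raise InvalidInputError(
                    f"segments must tile [0, F): bad segment ({start}, {end})"
                )
            prev_end = end

    @property
    def n_frames(self) -> int:
        return self.segments[-1][1] if self.segments else 0

    def to_frame_labels(self, frame_index: np.ndarray | None = None) -> FrameLabels:
        labels = np.empty(self.n_frames, dtype=object)
        for start, end, lab in self.segments:
            labels[start:end] = lab
        if frame_index is None:
            frame_index = np.arange(self.n_frames)
        return FrameLabels(labels=labels, frame_index=frame_index)


@dataclass
class SurgeryTrack:
    """Raw and smoothed d_Surgery, the per-frame flags, and flag intervals."""

    raw: np.ndarray
    smoothed: np.ndarray
    flags: np.ndarray
    intervals: list[tuple[int, int]]
    threshold: float


@dataclass
class Overview:
    """The final multi-track summary of one procedure: fine-grained
    visibility segmentation, its informative/non-informative projection, and
    the detected surgery intervals, with per-track frame fractions."""

    fine: Segmentation
    binary: Segmentation
    surgery: SurgeryTrack
    fractions: dict[str, dict[str, float]]
    n_frames: int


def class_distances(dm: DescriptorMatrix, model: CentroidModel) -> ClassDistances:
    """Minimum squared Euclidean distance from every frame to every class."""
    if not model.is_labeled:
        raise InvalidInputError("model must be labeled")
    if dm.dim != model.descriptor_dim:
        raise InvalidInputError(
            f"descriptor dim {dm.dim} != model dim {model.descriptor_dim}"
        )
    X = dm.vectors.astype(np.float64)
    per_class = model.class_centroids()
    class_order = tuple(sorted(per_class))
    cols = []
    for lab in class_order:
        d2 = cdist(X, per_class[lab].astype(np.float64), metric="sqeuclidean")
        cols.append(d2.min(axis=1))
    return ClassDistances(
        d=np.stack(cols, axis=1), class_order=class_order, frame_index=dm.frame_index
    )


def visibility_classify(cd: ClassDistances, cfg: PartitionConfig) -> FrameLabels:
    """Ratio-rule labeling: closest class if d_1 < d_2 * R, else Uncertain."""
    if len(cd.class_order) < 2:
        raise InvalidInputError(
            "ratio rule needs at least 2 classes (second-smallest distance undefined)"
        )
    order = np.argsort(cd.d, axis=1, kind="stable")
    d1 = cd.d[np.arange(cd.n_frames), order[:, 0]]
    d2 = cd.d[np.arange(cd.n_frames), order[:, 1]]
    accept = d1 < d2 * cfg.R
    classes = np.asarray(cd.class_order, dtype=object)
    labels = np.where(accept, classes[order[:, 0]], UNCERTAIN)
    return FrameLabels(labels=labels.astype(object), frame_index=cd.frame_index)


def temporal_mode_filter(fl: FrameLabels, M: int) -> FrameLabels:
    """Replace each label by the mode of the *original* labels in the centered
    window [i - floor(M/2), i + ceil(M/2)) clipped to the video; a tied mode
    becomes Uncertain. A pure filter: no in-place cascading."""
    if M < 1:
        raise InvalidInputError(f"M must be >= 1, got {M}")
    F = len(fl)
    uniq, codes = np.unique(np.asarray(fl.labels, dtype=str), return_inverse=True)
    L = len(uniq)
    # cumulative per-label counts: cum[i, l] = count of label l in [0, i)
    onehot = np.zeros((F + 1, L), dtype=np.int64)
    onehot[np.arange(1, F + 1), codes] = 1
    cum = np.cumsum(onehot, axis=0)
    lo = np.clip(np.arange(F) - M // 2, 0, F)
    hi = np.clip(np.arange(F) + (M + 1) // 2, 0, F)
    counts = cum[hi] - cum[lo]
    best = counts.max(axis=1)
    argbest = counts.argmax(axis=1)
    tied = (counts == best[:, None]).sum(axis=1) > 1
    out = np.asarray(uniq, dtype=object)[argbest]
    out[tied] = UNCERTAIN
    return FrameLabels(labels=out, frame_index=fl.frame_index)


def extract_segments(fl: FrameLabels) -> Segmentation:
    """Maximal runs of equal labels as half-open segments."""
    labels = fl.labels
    if len(labels) == 0:
        raise InvalidInputError("cannot segment an empty label sequence")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return Segmentation(
        segments=[(int(s), int(e), str(labels[s])) for s, e in zip(starts, ends)]
    )


def suppress_short_segments(seg: Segmentation, P: int) -> Segmentation:
    """Single pass: relabel every segment shorter than P frames as Uncertain,
    then merge adjacent equal labels. Newly merged Uncertain runs are not
    re-tested (no fixpoint iteration)."""
    if P < 1:
        raise InvalidInputError(f"P must be >= 1, got {P}")
    relabeled = [
        (s, e, UNCERTAIN if (e - s) < P else lab) for s, e, lab in seg.segments
    ]
    merged: list[tuple[int, int, str]] = []
    for s, e, lab in relabeled:
        if merged and merged[-1][2] == lab:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return Segmentation(segments=merged)


def _centered_moving_average(x: np.ndarray, W: int) -> np.ndarray:
    """Mean over the centered window [i - floor(W/2), i + ceil(W/2)) clipped
    to the sequence; no padding, so boundary windows are shorter."""
    F = len(x)
    cum = np.concatenate(([0.0], np.cumsum(x, dtype=np.float64)))
    lo = np.clip(np.arange(F) - W // 2, 0, F)
    hi = np.clip(np.arange(F) + (W + 1) // 2, 0, F)
    return (cum[hi] - cum[lo]) / (hi - lo)


def surgery_detect(cd: ClassDistances, cfg: SurgeryConfig) -> SurgeryTrack:
    """Detect surgical-tool intervals from the Surgery-class distances: a
    centered W-frame moving average of d_Surgery thresholded at t."""
    if SURGERY not in cd.class_order:
        raise InvalidInputError(
            f'model has no "{SURGERY}" class (classes: {list(cd.class_order)})'
        )
    raw = cd.d[:, cd.class_order.index(SURGERY)]
    # average the threshold-centered signal: exact at the decision boundary
    # (a constant raw == t never drifts below t through summation rounding)
    delta = _centered_moving_average(raw - cfg.t, cfg.W)
    smoothed = delta + cfg.t
    flags = delta < 0.0
    return SurgeryTrack(
        raw=raw,
        smoothed=smoothed,
        flags=flags,
        intervals=_flag_runs(flags),
        threshold=cfg.t,
    )


def _flag_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open intervals."""
    padded = np.concatenate(([False], flags, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def build_overview(
    vis: Segmentation, surg: SurgeryTrack, hierarchy: ClassHierarchy
) -> Overview:
    """Assemble the three aligned tracks and per-label frame fractions."""
    n = vis.n_frames
    if n != len(surg.flags):
        raise InvalidInputError(
            f"visibility track has {n} frames, surgery track {len(surg.flags)}"
        )
    projected = [(s, e, hierarchy.project(lab)) for s, e, lab in vis.segments]
    merged: list[tuple[int, int, str]] = []
    for s, e, lab in projected:
        if merged and merged[-1][2] == lab:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    binary = Segmentation(segments=merged)

    def _fractions(seg: Segmentation) -> dict[str, float]:
        out: dict[str, float] = {}
        for s, e, lab in seg.segments:
            out[lab] = out.get(lab, 0.0) + (e - s) / n
        return out

    fractions = {
        "fine": _fractions(vis),
        "binary": _fractions(binary),
        "surgery": {"Surgery": float(surg.flags.mean())},
    }
    return Overview(
        fine=vis, binary=binary, surgery=surg, fractions=fractions, n_frames=n
    )


def run_partition(
    dm: DescriptorMatrix,
    model: CentroidModel,
    cfg: PartitionConfig | None = None,
    surgery_cfg: SurgeryConfig | None = None,
) -> Overview:
    """Full partition pipeline: distances -> ratio rule -> mode filter ->
    short-segment suppression -> surgery head -> overview."""
    cfg = cfg if cfg is not None else PartitionConfig()
    surgery_cfg = surgery_cfg if surgery_cfg is not None else SurgeryConfig()
    cd = class_distances(dm, model)
    labels = visibility_classify(cd, cfg)
    labels = temporal_mode_filter(labels, cfg.M)
    seg = suppress_short_segments(extract_segments(labels), cfg.P)
    surg = surgery_detect(cd, surgery_cfg)
    return build_overview(seg, surg, model.hierarchy)
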