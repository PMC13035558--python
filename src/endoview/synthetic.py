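"""Synthetic descriptor streams with planted cluster and temporal structure.

The generator emulates the statistical structure the pipeline assumes of real
procedure recordings: descriptors form well-separated clusters, each cluster
has one dominant semantic class, and the class signal is piecewise constant
in time (scenes persist for many consecutive frames). Concretely:

* Planted centroids are drawn in D dimensions and rejection-adjusted until
  all pairwise distances are at least ``separation * sigma``.
* Scene labels follow a Markov chain over the fine classes with geometric
  segment durations (mean ``mean_run`` frames).
* Within one segment, every frame emits isotropic Gaussian noise (scale
  ``sigma``) around a single centroid of the segment's class — one scene, one
  appearance — mirroring clusters having a dominant semantic class.
* A configurable number of long Surgery segments is planted on top of the
  chain, so interval-level detection metrics have guaranteed targets.

Ground truth (frame labels, surgery intervals, the planted centroid model) is
recorded exactly, which makes every downstream stage testable without any
clinical recordings. What this does NOT emulate: real embeddings are neither
isotropic nor equally noisy across classes, cluster overlap is common, and
real transitions (e.g. wall contact during withdrawal) are not uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from endoview.descriptors import DescriptorMatrix, FrameStream
from endoview.discovery import DEFAULT_HIERARCHY, CentroidModel, ClassHierarchy
from endoview.errors import GenerationError, InvalidInputError
from endoview.evaluation import IntervalAnnotation
from endoview.partition import SURGERY, FrameLabels

__all__ = [
    "SurgeryRuns",
    "SyntheticConfig",
    "SyntheticVideo",
    "sample_planted_model",
    "generate",
    "make_image_fixtures",
    "surgery_threshold_for",
]


@dataclass(frozen=True)
class SurgeryRuns:
    """Planted Surgery segments: ``count`` runs, lengths uniform in
    ``length_range`` (inclusive)."""

    count: int = 3
    length_range: tuple[int, int] = (500, 1200)


def _default_clusters() -> dict[str, int]:
    return {
        "Surgery": 2,
        "High quality": 4,
        "Medium quality": 3,
        "Liquids": 3,
        "Wall": 2,
    }


@dataclass
class SyntheticConfig:
    """Generator settings.

    separation is the minimum pairwise centroid distance in units of sigma;
    at the default 8 the Gaussian emissions are essentially non-overlapping,
    so classification errors downstream come from the temporal filters, not
    from descriptor ambiguity.
    """

    dim: int = 64
    hierarchy: ClassHierarchy = field(default_factory=lambda: DEFAULT_HIERARCHY)
    clusters_per_class: dict[str, int] = field(default_factory=_default_clusters)
    separation: float = 8.0
    sigma: float = 1.0
    n_frames: int = 20000
    mean_run: int = 600
    transition: dict[str, dict[str, float]] | None = None
    surgery_runs: SurgeryRuns = field(default_factory=SurgeryRuns)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise InvalidInputError(f"separation must be > 0, got {self.separation}")
        if self.mean_run < 1:
            raise InvalidInputError(f"mean_run must be >= 1, got {self.mean_run}")
        if any(c < 1 for c in self.clusters_per_class.values()):
            raise InvalidInputError("all cluster counts must be >= 1")
        unknown = set(self.clusters_per_class) - set(self.hierarchy.fine_classes)
        if unknown:
            raise InvalidInputError(f"classes not in hierarchy: {sorted(unknown)}")

    @property
    def total_clusters(self) -> int:
        return sum(self.clusters_per_class.values())


@dataclass
class SyntheticVideo:
    """Generated stream plus exact ground truth."""

    dm: DescriptorMatrix
    gt_frames: FrameLabels
    gt_surgery: IntervalAnnotation
    true_model: CentroidModel
    emitting_cluster: np.ndarray  # per-frame planted cluster id


def surgery_threshold_for(cfg: SyntheticConfig) -> float:
    """Analytic surgery-detection threshold for this generator's geometry.

    A surgery frame's squared distance to its own centroid is chi-square with
    ``dim`` degrees of freedom scaled by sigma^2 (mean dim * sigma^2), while a
    non-surgery frame is at least separation * sigma away from every Surgery
    centroid, adding >= separation^2 * sigma^2. The midpoint of that gap,
    sigma^2 * (dim + separation^2 / 2), separates the two populations.
    """
    return cfg.sigma**2 * (cfg.dim + cfg.separation**2 / 2.0)


def _sample_centroids(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw centroids at scale separation*sigma, rejecting candidates closer
    than separation*sigma to an accepted one."""
    min_dist = cfg.separation * cfg.sigma
    # placement scale uses max(sigma, 1) so the cluster geometry does not
    # collapse in the small-noise limit; the separation constraint is in
    # sigma units as configured
    scale = cfg.separation * max(cfg.sigma, 1.0)
    accepted: list[np.ndarray] = []
    attempts = 0
    max_attempts = 1000 * cfg.total_clusters
    while len(accepted) < cfg.total_clusters:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {cfg.total_clusters} centroids at pairwise "
                f"distance >= {min_dist:.3g} in {attempts} attempts; "
                f"increase dim or reduce separation"
            )
        cand = rng.normal(0.0, scale, size=cfg.dim)
        if all(np.linalg.norm(cand - a) >= min_dist for a in accepted):
            accepted.append(cand)
    return np.stack(accepted)


def _planted_model(cfg: SyntheticConfig, rng: np.random.Generator) -> CentroidModel:
    centroids = _sample_centroids(cfg, rng)
    labels: dict[int, str] = {}
    cid = 0
    for lab in cfg.hierarchy.fine_classes:
        for _ in range(cfg.clusters_per_class.get(lab, 0)):
            labels[cid] = lab
            cid += 1
    return CentroidModel(
        centroids=centroids.astype(np.float32),
        hierarchy=cfg.hierarchy,
        cluster_label=labels,
    )


def sample_planted_model(cfg: SyntheticConfig) -> CentroidModel:
    """The planted, labeled centroid model (deterministic by cfg.seed)."""
    return _planted_model(cfg, np.random.default_rng(cfg.seed))


def _transition_matrix(
    cfg: SyntheticConfig, classes: tuple[str, ...]
) -> np.ndarray:
    n = len(classes)
    if cfg.transition is None:
        T = np.full((n, n), 1.0 / (n - 1))
        np.fill_diagonal(T, 0.0)
        return T
    T = np.zeros((n, n))
    for i, a in enumerate(classes):
        row = cfg.transition.get(a, {})
        for j, b in enumerate(classes):
            T[i, j] = row.get(b, 0.0)
        s = T[i].sum()
        if s <= 0:
            raise InvalidInputError(f"transition row for {a!r} has no mass")
        T[i] /= s
    return T


def _chain_labels(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame labels from the Markov chain with geometric run lengths."""
    classes = tuple(cfg.hierarchy.fine_classes)
    T = _transition_matrix(cfg, classes)
    p = 1.0 / cfg.mean_run
    labels = np.empty(cfg.n_frames, dtype=object)
    pos = 0
    state = int(rng.integers(len(classes)))
    while pos < cfg.n_frames:
        run = int(rng.geometric(p))
        labels[pos : pos + run] = classes[state]
        pos += run
        state = int(rng.choice(len(classes), p=T[state]))
    return labels


def _plant_surgery(
    labels: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> None:
    """Overwrite ``cfg.surgery_runs.count`` non-overlapping stretches with the
    Surgery label, one per equal block of the video."""
    count = cfg.surgery_runs.count
    if count == 0:
        return
    lo, hi = cfg.surgery_runs.length_range
    block = cfg.n_frames // count
    if hi > block - 3:
        raise GenerationError(
            f"surgery runs up to {hi} frames do not fit in blocks of {block}; "
            f"reduce count or lengths"
        )
    for b in range(count):
        length = int(rng.integers(lo, hi + 1))
        # keep 1 frame of margin inside the block so planted runs stay maximal
        start = b * block + int(rng.integers(1, block - length - 1))
        labels[start : start + length] = SURGERY


def _label_runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return [(int(s), int(e), str(labels[s])) for s, e in zip(starts, ends)]


def generate(cfg: SyntheticConfig) -> SyntheticVideo:
    """Generate one synthetic procedure: descriptors + exact ground truth."""
    rng = np.random.default_rng(cfg.seed)
    model = _planted_model(cfg, rng)
    labels = _chain_labels(cfg, rng)
    _plant_surgery(labels, cfg, rng)

    clusters_of: dict[str, list[int]] = {}
    for cid, lab in model.cluster_label.items():
        clusters_of.setdefault(lab, []).append(cid)

    # One appearance (centroid) per scene. Clusters of a class are cycled in a
    # seeded random order so occupancy stays even across a class's clusters.
    cycles: dict[str, list[int]] = {}
    used: dict[str, int] = {}
    for lab, ids in clusters_of.items():
        order = list(ids)
        rng.shuffle(order)
        cycles[lab] = order
        used[lab] = 0
    emitting = np.empty(cfg.n_frames, dtype=np.int64)
    for s, e, lab in _label_runs(labels):
        emitting[s:e] = cycles[lab][used[lab] % len(cycles[lab])]
        used[lab] += 1
    vectors = (
        model.centroids[emitting].astype(np.float64)
        + cfg.sigma * rng.standard_normal((cfg.n_frames, cfg.dim))
    )

    gt_surgery = IntervalAnnotation(
        intervals=[
            (s, e, SURGERY) for s, e, lab in _label_runs(labels) if lab == SURGERY
        ]
    )
    frame_index = np.arange(cfg.n_frames)
    return SyntheticVideo(
        dm=DescriptorMatrix(
            vectors=vectors.astype(np.float32),
            frame_index=frame_index,
            source_id=f"synthetic-{cfg.seed}",
        ),
        gt_frames=FrameLabels(labels=labels, frame_index=frame_index),
        gt_surgery=gt_surgery,
        true_model=model,
        emitting_cluster=emitting,
    )


def stationary_fractions(cfg: SyntheticConfig) -> dict[str, float]:
    """Frame-weighted stationary class fractions of the configured chain
    (before surgery planting). Durations share one mean, so this is the
    stationary distribution of the segment-level chain."""
    classes = tuple(cfg.hierarchy.fine_classes)
    T = _transition_matrix(cfg, classes)
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = pi / pi.sum()
    return {lab: float(p) for lab, p in zip(classes, pi)}


# ---------------------------------------------------------------------------
# Image fixtures for the descriptors module
# ---------------------------------------------------------------------------

_BASE_COLORS: dict[str, tuple[int, int, int]] = {
    "Surgery": (40, 40, 200),
    "High quality": (200, 60, 60),
    "Medium quality": (160, 120, 60),
    "Liquids": (60, 180, 180),
    "Wall": (90, 90, 90),
}


def make_image_fixtures(
    n_per_class: int = 10,
    size: int = 64,
    hierarchy: ClassHierarchy | None = None,
    seed: int = 0,
    noise: float = 12.0,
) -> tuple[FrameStream, list[str]]:
    """Deterministic synthetic frames, one base color plus seeded texture per
    class, so the baseline featurizer can be exercised end to end. Returns
    the stream and the per-frame class labels."""
    hierarchy = hierarchy if hierarchy is not None else DEFAULT_HIERARCHY
    rng = np.random.default_rng(seed)
    classes = tuple(hierarchy.fine_classes)
    palette = np.array(
        [
            _BASE_COLORS.get(
                lab,
                tuple(int(v) for v in rng.integers(0, 256, size=3)),
            )
            for lab in classes
        ],
        dtype=np.float64,
    )
    frames: list[np.ndarray] = []
    labels: list[str] = []
    for ci, lab in enumerate(classes):
        for _ in range(n_per_class):
            img = np.tile(palette[ci], (size, size, 1))
            img = img + rng.normal(0.0, noise, size=img.shape)
            frames.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(lab)
    return FrameStream(frames=frames, source_id=f"image-fixtures-{seed}"), labels
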