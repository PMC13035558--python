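"""Scene-class discovery: K-means over descriptors plus human cluster labeling.

Descriptors from many procedures are clustered jointly with K-means; each
cluster tends to collect one kind of scene (wall contact, clear mucosa view,
tool present, ...). A human inspects a few exemplar frames per cluster and
assigns every cluster one fine-grained class inside a two-level hierarchy
(informative vs non-informative at the top). The stored model is just the
labeled centroids: classification downstream is nearest-centroid, so a class
may own many centroids and the label effort is per cluster, not per frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from endoview.descriptors import DescriptorMatrix
from endoview.errors import FormatError, InvalidInputError, ValidationError

__all__ = [
    "DiscoveryConfig",
    "ClassHierarchy",
    "CentroidModel",
    "cluster_descriptors",
    "export_exemplars",
    "apply_label_map",
    "save_model",
    "load_model",
    "lloyd_inertia_trace",
    "INFORMATIVE",
    "NON_INFORMATIVE",
    "DEFAULT_HIERARCHY",
]

INFORMATIVE = "Informative"
NON_INFORMATIVE = "Non-informative"


@dataclass
class DiscoveryConfig:
    """K-means settings. k trades annotation effort against class purity;
    n_init restarts guard against bad local minima."""

    k: int = 100
    max_iter: int = 300
    seed: int = 0
    n_init: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidInputError(f"k must be >= 1, got {self.k}")
        if self.max_iter < 1:
            raise InvalidInputError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.n_init < 1:
            raise InvalidInputError(f"n_init must be >= 1, got {self.n_init}")


@dataclass(frozen=True)
class ClassHierarchy:
    """Two-level class structure: fine-grained classes, each under exactly one
    super class. "Uncertain" is a reserved output label for frames that fail
    the confidence tests; it is never attached to a cluster."""

    super_of: Mapping[str, str]

    RESERVED = "Uncertain"

    def __post_init__(self) -> None:
        if self.RESERVED in self.super_of:
            raise ValidationError(f'"{self.RESERVED}" cannot be a fine class')
        supers = set(self.super_of.values())
        if not supers <= {INFORMATIVE, NON_INFORMATIVE}:
            bad = sorted(supers - {INFORMATIVE, NON_INFORMATIVE})
            raise ValidationError(f"unknown super classes: {bad}")

    @property
    def fine_classes(self) -> tuple[str, ...]:
        return tuple(self.super_of.keys())

    def project(self, fine: str) -> str:
        """Map a fine label to its super class; Uncertain stays Uncertain."""
        if fine == self.RESERVED:
            return self.RESERVED
        return self.super_of[fine]


#: Classes that emerge from colonoscopy frame clusters: tool visible, clear
#: view, partly occluded view (informative); water/debris, lens-on-wall
#: (non-informative).
DEFAULT_HIERARCHY = ClassHierarchy(
    super_of={
        "Surgery": INFORMATIVE,
        "High quality": INFORMATIVE,
        "Medium quality": INFORMATIVE,
        "Liquids": NON_INFORMATIVE,
        "Wall": NON_INFORMATIVE,
    }
)


@dataclass
class CentroidModel:
    """k labeled cluster centroids plus the class hierarchy.

    ``cluster_label`` maps cluster id -> fine class; it is None until
    :func:`apply_label_map` runs. ``assignments`` (optional) caches the
    training-set cluster assignment for exemplar export.
    """

    centroids: np.ndarray
    hierarchy: ClassHierarchy = DEFAULT_HIERARCHY
    cluster_label: dict[int, str] | None = None
    assignments: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float32)
        if self.centroids.ndim != 2:
            raise InvalidInputError("centroids must be a k x D matrix")
        if not np.all(np.isfinite(self.centroids)):
            raise InvalidInputError("centroids contain non-finite values")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def descriptor_dim(self) -> int:
        return self.centroids.shape[1]

    @property
    def is_labeled(self) -> bool:
        return self.cluster_label is not None

    def class_centroids(self) -> dict[str, np.ndarray]:
        """Group centroid rows by fine class (the N_L centroids of class L)."""
        if not self.is_labeled:
            raise InvalidInputError("model is unlabeled; apply a label map first")
        out: dict[str, list[int]] = {}
        for cid, lab in self.cluster_label.items():
            out.setdefault(lab, []).append(cid)
        return {lab: self.centroids[sorted(ids)] for lab, ids in out.items()}


def cluster_descriptors(dm: DescriptorMatrix, cfg: DiscoveryConfig) -> CentroidModel:
    """Run K-means (k-means++ init, best of n_init restarts) on the
    descriptor matrix and return the unlabeled centroid model."""
    if dm.n_frames < cfg.k:
        raise InvalidInputError(
            f"need at least k={cfg.k} descriptors, got {dm.n_frames}"
        )
    km = KMeans(
        n_clusters=cfg.k,
        init="k-means++",
        n_init=cfg.n_init,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    assignments = km.fit_predict(dm.vectors.astype(np.float64))
    return CentroidModel(
        centroids=km.cluster_centers_.astype(np.float32),
        assignments=assignments.astype(np.int64),
    )


def lloyd_inertia_trace(
    vectors: np.ndarray, init_centroids: np.ndarray, n_iter: int
) -> list[float]:
    """Explicit Lloyd iterations returning the inertia after each assignment
    step. Diagnostic helper: inertia must be non-increasing."""
    X = np.asarray(vectors, dtype=np.float64)
    C = np.asarray(init_centroids, dtype=np.float64).copy()
    trace: list[float] = []
    for _ in range(n_iter):
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(len(X)), assign].sum()))
        for j in range(C.shape[0]):
            members = X[assign == j]
            if len(members):
                C[j] = members.mean(axis=0)
    return trace


def export_exemplars(
    model: CentroidModel, dm: DescriptorMatrix, m: int = 5
) -> dict[int, list[int]]:
    """For each cluster, the m assigned frames nearest its centroid (native
    frame indices), ties broken toward the lower frame index. Clusters with
    fewer than m members return all members."""
    if m < 1:
        raise InvalidInputError(f"m must be >= 1, got {m}")
    if model.assignments is None:
        # recompute assignments against this matrix
        d2 = _sq_dists(dm.vectors.astype(np.float64), model.centroids.astype(np.float64))
        assignments = d2.argmin(axis=1)
    else:
        if len(model.assignments) != dm.n_frames:
            raise InvalidInputError(
                "cached assignments do not match this descriptor matrix"
            )
        assignments = model.assignments
    X = dm.vectors.astype(np.float64)
    out: dict[int, list[int]] = {}
    for cid in range(model.k):
        members = np.flatnonzero(assignments == cid)
        if len(members) == 0:
            out[cid] = []
            continue
        d = ((X[members] - model.centroids[cid].astype(np.float64)) ** 2).sum(axis=1)
        # stable sort on distance keeps lower frame index first on ties
        order = np.argsort(d, kind="stable")[:m]
        out[cid] = dm.frame_index[members[order]].tolist()
    return out


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import cdist

    return cdist(X, C, metric="sqeuclidean")


def apply_label_map(
    model: CentroidModel,
    label_map: Mapping[int, str],
    hierarchy: ClassHierarchy | None = None,
) -> CentroidModel:
    """Attach the human cluster labels to the model, validating coverage."""
    hierarchy = hierarchy if hierarchy is not None else model.hierarchy
    missing = [cid for cid in range(model.k) if cid not in label_map]
    if missing:
        raise ValidationError(f"label map missing cluster ids: {missing}")
    extra = sorted(set(label_map) - set(range(model.k)))
    if extra:
        raise ValidationError(f"label map has unknown cluster ids: {extra}")
    unknown = sorted(
        {lab for lab in label_map.values() if lab not in hierarchy.fine_classes}
    )
    if unknown:
        raise ValidationError(f"labels not in hierarchy: {unknown}")
    return CentroidModel(
        centroids=model.centroids,
        hierarchy=hierarchy,
        cluster_label={int(c): str(l) for c, l in label_map.items()},
        assignments=model.assignments,
    )


# ---------------------------------------------------------------------------
# Model persistence: model.json (k, D, hierarchy, cluster_label) +
# centroids.bin (row-major float32) inside a directory.
# ---------------------------------------------------------------------------


def save_model(model: CentroidModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "k": int(model.k),
        "dim": int(model.descriptor_dim),
        "hierarchy": dict(model.hierarchy.super_of),
        "cluster_label": (
            {str(c): l for c, l in model.cluster_label.items()}
            if model.is_labeled
            else None
        ),
    }
    (path / "model.json").write_text(json.dumps(meta, indent=1))
    model.centroids.astype(np.float32).tofile(path / "centroids.bin")


def load_model(path: str | Path) -> CentroidModel:
    path = Path(path)
    try:
        meta = json.loads((path / "model.json").read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}/model.json: invalid JSON: {exc}") from exc
    for key in ("k", "dim", "hierarchy"):
        if key not in meta:
            raise FormatError(f"{path}/model.json: missing field '{key}'")
    k, dim = int(meta["k"]), int(meta["dim"])
    raw = np.fromfile(path / "centroids.bin", dtype=np.float32)
    if raw.size != k * dim:
        raise FormatError(
            f"{path}/centroids.bin: payload has {raw.size} floats, "
            f"header requires k={k} x dim={dim} = {k * dim}"
        )
    labels = meta.get("cluster_label")
    return CentroidModel(
        centroids=raw.reshape(k, dim),
        hierarchy=ClassHierarchy(super_of=dict(meta["hierarchy"])),
        cluster_label=(
            {int(c): str(l) for c, l in labels.items()} if labels is not None else None
        ),
    )


def read_label_map(path: str | Path) -> dict[int, str]:
    """Read a cluster label map CSV with columns ``cluster_id,fine_class``."""
    df = pd.read_csv(path)
    for col in ("cluster_id", "fine_class"):
        if col not in df.columns:
            raise FormatError(f"{path}: label map missing column '{col}'")
    return {int(r.cluster_id): str(r.fine_class) for r in df.itertuples()}


def read_hierarchy(path: str | Path) -> ClassHierarchy:
    """Read a hierarchy CSV with columns ``fine_class,super_class``."""
    df = pd.read_csv(path)
    for col in ("fine_class", "super_class"):
        if col not in df.columns:
            raise FormatError(f"{path}: hierarchy missing column '{col}'")
    return ClassHierarchy(
        super_of={str(r.fine_class): str(r.super_class) for r in df.itertuples()}
    )
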