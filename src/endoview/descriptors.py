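"""Frame preprocessing, subsampling, baseline featurization and descriptor I/O.

A *descriptor* is one fixed-dimension real vector per video frame. The
pipeline is agnostic to where descriptors come from: a contrastively trained
network typically emits 2048-d vectors, while :func:`featurize_baseline`
provides a deterministic 96-d color-histogram/grid featurizer so the whole
system can run and be tested without any trained model. Any producer of a
valid :class:`DescriptorMatrix` satisfies the contract; descriptors are used
raw (no normalization), since the classification heads operate on squared
Euclidean distances in whatever space the descriptors live in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from endoview.errors import FormatError, InvalidInputError

__all__ = [
    "FrameStream",
    "DescriptorMatrix",
    "PreprocessSpec",
    "preprocess_frame",
    "subsample",
    "featurize_baseline",
    "save_descriptors",
    "load_descriptors",
    "load_frame_stream",
]

#: Baseline featurizer output dimension: 3 channels x (16 hist bins + 16 grid cells).
BASELINE_DIM = 96


@dataclass
class FrameStream:
    """An ordered sequence of RGB frames with their original frame numbers."""

    frames: list[np.ndarray]
    source_id: str = ""
    native_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise InvalidInputError("FrameStream requires at least one frame")
        if self.native_index is None:
            self.native_index = np.arange(len(self.frames), dtype=np.int64)
        else:
            self.native_index = np.asarray(self.native_index, dtype=np.int64)
        if len(self.native_index) != len(self.frames):
            raise InvalidInputError(
                f"native_index length {len(self.native_index)} != "
                f"frame count {len(self.frames)}"
            )
        if len(self.native_index) > 1 and not np.all(np.diff(self.native_index) > 0):
            raise InvalidInputError("native_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DescriptorMatrix:
    """F x D matrix of per-frame descriptors for one video.

    ``vectors`` is stored as float32 (the on-disk dtype) so that save/load
    round-trips are bit-exact. ``frame_index`` holds the native frame number
    of each row and is strictly increasing.
    """

    vectors: np.ndarray
    frame_index: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise InvalidInputError(
                f"vectors must be a non-empty 2-D matrix, got shape {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise InvalidInputError("vectors contain non-finite values")
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        if len(self.frame_index) != self.vectors.shape[0]:
            raise InvalidInputError(
                f"frame_index length {len(self.frame_index)} != "
                f"row count {self.vectors.shape[0]}"
            )
        if len(self.frame_index) > 1 and not np.all(np.diff(self.frame_index) > 0):
            raise InvalidInputError("frame_index must be strictly increasing")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]


@dataclass
class PreprocessSpec:
    """How raw frames are normalized before featurization.

    ``crop`` center-crops to a square on the shorter dimension, ``side`` is
    the output resolution, and ``stride`` keeps one frame in every ``stride``
    from the original stream (full procedures are long; 1-in-10 subsampling
    preserves the temporal structure the downstream filters need).
    """

    crop: bool = True
    side: int = 224
    stride: int = 10

    def __post_init__(self) -> None:
        if self.side < 8:
            raise InvalidInputError(f"side must be >= 8, got {self.side}")
        if self.stride < 1:
            raise InvalidInputError(f"stride must be >= 1, got {self.stride}")


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError(
            f"expected an RGB HxWx3 image, got shape {image.shape}"
        )
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise InvalidInputError("image has an empty dimension")
    return image


def preprocess_frame(image: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Center-crop an RGB frame to a square and resize to ``spec.side``.

    The crop is centered on the longer dimension; when the margin is odd the
    extra pixel goes to the trailing side (offset = floor(diff / 2)). Resizing
    uses fixed bilinear interpolation so repeated runs are identical.
    """
    image = _check_rgb(image)
    h, w = image.shape[:2]
    if spec.crop and h != w:
        side = min(h, w)
        off_r = (h - side) // 2
        off_c = (w - side) // 2
        image = image[off_r : off_r + side, off_c : off_c + side]
    if image.shape[0] != spec.side:
        pil = Image.fromarray(np.ascontiguousarray(image.astype(np.uint8)))
        pil = pil.resize((spec.side, spec.side), resample=Image.BILINEAR)
        image = np.asarray(pil)
    return image


def subsample(stream: FrameStream, stride: int) -> FrameStream:
    """Keep frames at positions 0, stride, 2*stride, ... of the stream."""
    if stride < 1:
        raise InvalidInputError(f"stride must be >= 1, got {stride}")
    keep = range(0, len(stream), stride)
    return FrameStream(
        frames=[stream.frames[i] for i in keep],
        source_id=stream.source_id,
        native_index=stream.native_index[list(keep)],
    )


def _featurize_one(image: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    img = preprocess_frame(image, spec).astype(np.float64) / 255.0
    parts: list[np.ndarray] = []
    # 16-bin normalized intensity histogram per channel (48 values)
    for c in range(3):
        hist, _ = np.histogram(img[:, :, c], bins=16, range=(0.0, 1.0))
        parts.append(hist / img.shape[0] / img.shape[1])
    # 4x4 grid of mean intensities per channel (48 values)
    rows = np.array_split(np.arange(img.shape[0]), 4)
    cols = np.array_split(np.arange(img.shape[1]), 4)
    for c in range(3):
        grid = np.empty((4, 4))
        for i, rs in enumerate(rows):
            for j, cs in enumerate(cols):
                grid[i, j] = img[rs[0] : rs[-1] + 1, cs[0] : cs[-1] + 1, c].mean()
        parts.append(grid.ravel())
    return np.concatenate(parts)


def featurize_baseline(stream: FrameStream, spec: PreprocessSpec | None = None) -> DescriptorMatrix:
    """Deterministic 96-d color descriptor: per-channel histograms + grid means.

    Not a learned embedding — a fixed featurizer that separates scenes by
    global color distribution and coarse spatial layout, sufficient to
    exercise clustering and partitioning end to end. All outputs lie in
    [0, 1]; each channel histogram sums to 1.
    """
    spec = spec if spec is not None else PreprocessSpec()
    vecs = np.stack([_featurize_one(f, spec) for f in stream.frames])
    return DescriptorMatrix(
        vectors=vecs.astype(np.float32),
        frame_index=stream.native_index,
        source_id=stream.source_id,
    )


# ---------------------------------------------------------------------------
# Descriptor I/O
#
# Two formats: a JSON sidecar (source_id, dim, frame_index, dtype) next to a
# row-major float32 binary payload, or a plain CSV (header
# "frame_index,f0,...,f{D-1}") for tiny fixtures.
# ---------------------------------------------------------------------------


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    if path.suffix == ".json":
        return path, path.with_suffix(".bin")
    return path.with_suffix(path.suffix + ".json"), path.with_suffix(path.suffix + ".bin")


def save_descriptors(dm: DescriptorMatrix, path: str | Path) -> None:
    """Write a DescriptorMatrix to ``path`` (CSV if it ends in .csv, else
    JSON sidecar + .bin payload). Round-trips are bit-exact."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.DataFrame(
            dm.vectors.astype(np.float64),
            columns=[f"f{i}" for i in range(dm.dim)],
        )
        df.insert(0, "frame_index", dm.frame_index)
        df.to_csv(path, index=False)
        return
    meta_path, bin_path = _sidecar_paths(path)
    meta = {
        "source_id": dm.source_id,
        "dim": int(dm.dim),
        "n_frames": int(dm.n_frames),
        "frame_index": dm.frame_index.tolist(),
        "dtype": "float32",
    }
    meta_path.write_text(json.dumps(meta))
    dm.vectors.astype(np.float32).tofile(bin_path)


def load_descriptors(path: str | Path) -> DescriptorMatrix:
    """Read a DescriptorMatrix written by :func:`save_descriptors`."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        if "frame_index" not in df.columns:
            raise FormatError(f"{path}: missing 'frame_index' column")
        if df.shape[0] < 1:
            raise InvalidInputError(f"{path}: descriptor file has no rows")
        vectors = df.drop(columns=["frame_index"]).to_numpy(dtype=np.float64)
        return DescriptorMatrix(
            vectors=vectors.astype(np.float32),
            frame_index=df["frame_index"].to_numpy(),
            source_id=path.stem,
        )
    meta_path, bin_path = _sidecar_paths(path)
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{meta_path}: invalid JSON sidecar: {exc}") from exc
    for key in ("dim", "n_frames", "frame_index", "dtype"):
        if key not in meta:
            raise FormatError(f"{meta_path}: sidecar missing field '{key}'")
    if meta["dtype"] != "float32":
        raise FormatError(f"{meta_path}: unsupported dtype '{meta['dtype']}'")
    dim, n = int(meta["dim"]), int(meta["n_frames"])
    if n < 1:
        raise InvalidInputError(f"{meta_path}: n_frames must be >= 1")
    raw = np.fromfile(bin_path, dtype=np.float32)
    if raw.size != n * dim:
        raise FormatError(
            f"{bin_path}: payload has {raw.size} floats, header 'dim'={dim} x "
            f"'n_frames'={n} requires {n * dim}"
        )
    if len(meta["frame_index"]) != n:
        raise FormatError(
            f"{meta_path}: field 'frame_index' has {len(meta['frame_index'])} "
            f"entries, expected {n}"
        )
    return DescriptorMatrix(
        vectors=raw.reshape(n, dim),
        frame_index=np.asarray(meta["frame_index"]),
        source_id=meta.get("source_id", ""),
    )


def load_frame_stream(path: str | Path, source_id: str | None = None) -> FrameStream:
    """Load frames from a directory of PNG/JPEG named by frame number, or
    from a manifest CSV with columns ``native_index,path``."""
    path = Path(path)
    if path.is_dir():
        entries: list[tuple[int, Path]] = []
        for p in sorted(path.iterdir()):
            if p.suffix.lower() in (".png", ".jpg", ".jpeg"):
                try:
                    idx = int(p.stem)
                except ValueError as exc:
                    raise FormatError(
                        f"{p}: filename stem must be the integer frame number"
                    ) from exc
                entries.append((idx, p))
        if not entries:
            raise InvalidInputError(f"{path}: no PNG/JPEG frames found")
        entries.sort()
        frames = [np.asarray(Image.open(p).convert("RGB")) for _, p in entries]
        index = np.array([i for i, _ in entries])
    else:
        df = pd.read_csv(path)
        for col in ("native_index", "path"):
            if col not in df.columns:
                raise FormatError(f"{path}: manifest missing column '{col}'")
        frames = [
            np.asarray(Image.open(Path(path).parent / p).convert("RGB"))
            for p in df["path"]
        ]
        index = df["native_index"].to_numpy()
    return FrameStream(
        frames=frames,
        source_id=source_id if source_id is not None else path.stem,
        native_index=index,
    )
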