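"""Skeleton domain types, coordinate conventions, and file I/O.

Conventions
-----------
* Frame indexing is 0-based everywhere in this package.
* 2D coordinates are normalized camera units; 3D coordinates are
  millimetres for real data and abstract units for synthetic data.
  Metrics always report in input units.
* Missing 2D keypoints are zero-filled with ``observed=False`` and
  ``confidence=0``; downstream code must consult the mask.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "JointLayout",
    "PoseSequence2D",
    "PoseSequence3D",
    "PaddedSequence",
    "LabeledDataset",
    "ModelConfig",
    "h36m_layout",
    "write_sequence",
    "read_sequence",
    "load_config",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


# --------------------------------------------------------------------------
# layout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class JointLayout:
    """Named joints with a parent tree defining the static skeleton graph.

    ``parents[i]`` is the index of joint *i*'s parent; the single root has
    parent ``-1``. The tree must be connected and acyclic.
    """

    joint_names: tuple[str, ...]
    parents: tuple[int, ...]

    def __post_init__(self):
        j = len(self.joint_names)
        if len(self.parents) != j:
            raise ValidationError("joint_names and parents lengths differ")
        roots = [i for i, p in enumerate(self.parents) if p == -1]
        if len(roots) != 1:
            raise ValidationError(f"expected exactly one root, found {len(roots)}")
        for i, p in enumerate(self.parents):
            if p != -1 and not (0 <= p < j):
                raise ValidationError(f"parent index {p} of joint {i} out of range")
        # connectivity / acyclicity: every joint must reach the root
        for i in range(j):
            seen = set()
            cur = i
            while cur != -1:
                if cur in seen:
                    raise ValidationError("cycle detected in parent tree")
                seen.add(cur)
                cur = self.parents[cur]

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    @property
    def root_index(self) -> int:
        return self.parents.index(-1)

    @property
    def edges(self) -> list[tuple[int, int]]:
        """(child, parent) pairs, excluding the root's virtual parent."""
        return [(i, p) for i, p in enumerate(self.parents) if p != -1]


#: 17-joint Human3.6M-style tree: pelvis root; right/left legs; spine,
#: thorax, neck, head chain; left/right arms.
_H36M_NAMES = (
    "pelvis", "right_hip", "right_knee", "right_ankle",
    "left_hip", "left_knee", "left_ankle",
    "spine", "thorax", "neck", "head",
    "left_shoulder", "left_elbow", "left_wrist",
    "right_shoulder", "right_elbow", "right_wrist",
)
_H36M_PARENTS = (-1, 0, 1, 2, 0, 4, 5, 0, 7, 8, 9, 8, 11, 12, 8, 14, 15)

#: left/right joint index pairs for horizontal-flip augmentation
H36M_FLIP_PAIRS = ((1, 4), (2, 5), (3, 6), (11, 14), (12, 15), (13, 16))


def h36m_layout() -> JointLayout:
    """The default 17-joint layout."""
    return JointLayout(_H36M_NAMES, _H36M_PARENTS)


# --------------------------------------------------------------------------
# sequences
# --------------------------------------------------------------------------

@dataclass
class PoseSequence2D:
    """F x J x 2 keypoints with per-joint confidences and an observed mask."""

    coords: np.ndarray
    confidence: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValidationError(f"coords must be F x J x 2, got {self.coords.shape}")
        f, j, _ = self.coords.shape
        if f < 1:
            raise ValidationError("no frames")
        self.confidence = np.asarray(self.confidence, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.confidence.shape != (f, j) or self.observed.shape != (f, j):
            raise ValidationError("confidence/observed shape mismatch")
        if np.any(self.confidence < 0) or np.any(self.confidence > 1):
            raise ValidationError("confidence outside [0, 1]")
        if np.any(self.confidence[~self.observed] != 0):
            raise ValidationError("unobserved entries must have confidence 0")
        if not np.all(np.isfinite(self.coords[self.observed])):
            raise ValidationError("NaN/inf in observed coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "PoseSequence2D":
        return PoseSequence2D(self.coords.copy(), self.confidence.copy(), self.observed.copy())

    @classmethod
    def fully_observed(cls, coords: np.ndarray) -> "PoseSequence2D":
        coords = np.asarray(coords, dtype=np.float64)
        f, j = coords.shape[:2]
        return cls(coords, np.ones((f, j)), np.ones((f, j), dtype=bool))


@dataclass
class PoseSequence3D:
    """F x J x 3 joint positions."""

    coords: np.ndarray
    root_relative: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(f"coords must be F x J x 3, got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValidationError("no frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite 3D coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "PoseSequence3D":
        return PoseSequence3D(self.coords.copy(), self.root_relative)


@dataclass
class PaddedSequence:
    """A sequence extended by `pad` synthesized frames at each end."""

    coords: np.ndarray
    original_length: int
    pad: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape[0] != self.original_length + 2 * self.pad:
            raise ValidationError("total length must equal original_length + 2*pad")

    @property
    def core(self) -> np.ndarray:
        """The central original frames."""
        return self.coords[self.pad:self.pad + self.original_length]


@dataclass
class LabeledDataset:
    """Sequences with binary labels for one classification task."""

    sequences: list
    labels: list[int]
    task_name: str = "task"

    def __post_init__(self):
        if len(self.sequences) != len(self.labels):
            raise ValidationError("one label per sequence required")
        if any(l not in (0, 1) for l in self.labels):
            raise ValidationError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sequences)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """All architecture and optimisation hyperparameters.

    Defaults follow the reference configuration: input feature dim 25,
    hidden dim 512, 2 encoder layers, 5 temporal scales. The printed head
    count (9) does not divide either feature dim; the default resolves to
    8 heads on the 512-dim space, and ``faithful_heads=True`` switches to
    9 heads on a 522-dim space instead.
    """

    dm: int = 25
    df: int = 512
    encoder_layers: int = 2
    attention_heads: int = 8
    faithful_heads: bool = False
    n_scales: int = 5
    segment_lengths: tuple[int, ...] | None = None
    pad: int = 5
    trend_window: int = 3
    tlsi_window: int = 5
    lambda_t: float = 0.5
    adjacency_mix: float = 0.5
    conv_kernel: int = 3
    learning_rate: float = 1e-3
    lr_decay: float = 0.95
    epochs: int = 10
    seed: int = 0
    positional_embedding: bool = True
    horizontal_flip: bool = False

    def __post_init__(self):
        if self.faithful_heads:
            self.attention_heads = 9
        for name in ("dm", "df", "encoder_layers", "attention_heads", "n_scales",
                     "trend_window", "tlsi_window", "conv_kernel", "epochs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.pad < 0:
            raise ValidationError("pad must be >= 0")
        if self.trend_window < 2:
            raise ValidationError("trend_window must be >= 2")
        if self.lambda_t < 0:
            raise ValidationError("lambda_t must be >= 0")
        if not (0.0 <= self.adjacency_mix <= 1.0):
            raise ValidationError("adjacency_mix must lie in [0, 1]")
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be >= 0")
        if self.segment_lengths is not None:
            self.segment_lengths = tuple(int(s) for s in self.segment_lengths)
            if len(self.segment_lengths) != self.n_scales:
                raise ValidationError("segment_lengths length must equal n_scales")
            if any(s <= 0 for s in self.segment_lengths):
                raise ValidationError("segment lengths must be positive")

    @property
    def unified_dim(self) -> int:
        """Dimension of the fused feature space; ``df`` by default. In
        faithful-heads mode the dim is rounded up to 9 heads of even width
        (522 = 9 * 58 for df=512)."""
        if self.faithful_heads:
            per_head = int(math.ceil(self.df / 9))
            if per_head % 2:
                per_head += 1
            return 9 * per_head
        return self.df


def load_config(path: str | Path) -> ModelConfig:
    """Load a YAML/JSON config, applying defaults for missing keys."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return ModelConfig(**data)


# --------------------------------------------------------------------------
# sequence I/O
# --------------------------------------------------------------------------

def write_sequence(seq, path: str | Path, fmt: str = "hdf5",
                   layout: JointLayout | None = None, fps: float | None = None) -> None:
    """Write a 2D or 3D pose sequence to HDF5 or long-format CSV."""
    path = Path(path)
    if fmt == "hdf5":
        _write_hdf5(seq, path, layout, fps)
    elif fmt == "csv":
        _write_csv(seq, path)
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def _write_hdf5(seq, path, layout, fps):
    with h5py.File(path, "w") as h5:
        h5.create_dataset("coords", data=seq.coords)
        if isinstance(seq, PoseSequence2D):
            h5.create_dataset("confidence", data=seq.confidence)
            h5.create_dataset("observed", data=seq.observed)
            h5.attrs["kind"] = "2d"
        else:
            h5.attrs["kind"] = "3d"
            h5.attrs["root_relative"] = seq.root_relative
        h5.attrs["n_frames"] = seq.n_frames
        h5.attrs["n_joints"] = seq.n_joints
        if layout is not None:
            h5.attrs["joint_names"] = list(layout.joint_names)
            h5.attrs["parents"] = list(layout.parents)
        if fps is not None:
            h5.attrs["fps"] = fps


def _write_csv(seq, path):
    f, j = seq.n_frames, seq.n_joints
    frames = np.repeat(np.arange(f), j)
    joints = np.tile(np.arange(j), f)
    if isinstance(seq, PoseSequence2D):
        df = pd.DataFrame({
            "frame": frames,
            "joint": joints,
            "x": seq.coords[:, :, 0].ravel(),
            "y": seq.coords[:, :, 1].ravel(),
            "confidence": seq.confidence.ravel(),
            "observed": seq.observed.ravel().astype(int),
        })
    else:
        df = pd.DataFrame({
            "frame": frames,
            "joint": joints,
            "x": seq.coords[:, :, 0].ravel(),
            "y": seq.coords[:, :, 1].ravel(),
            "z": seq.coords[:, :, 2].ravel(),
        })
    df.to_csv(path, index=False, float_format="%.17g")


def read_sequence(path: str | Path, fmt: str = "hdf5", kind: str | None = None):
    """Read a pose sequence; `kind` in {'2d','3d'} is required for CSV only
    when the column set is ambiguous (it never is: 'z' implies 3d)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "hdf5":
        return _read_hdf5(path, kind)
    if fmt == "csv":
        return _read_csv(path, kind)
    raise ValueError(f"unknown format: {fmt!r}")


def _read_hdf5(path, kind):
    with h5py.File(path, "r") as h5:
        if "coords" not in h5:
            raise ValidationError("missing dataset: coords")
        coords = np.asarray(h5["coords"])
        stored_kind = h5.attrs.get("kind")
        if coords.ndim != 3:
            raise ValidationError("coords must be 3-dimensional")
        actual = "2d" if coords.shape[2] == 2 else "3d"
        if stored_kind is not None and stored_kind != actual:
            raise ValidationError("dimension mismatch between kind attr and coords")
        if kind is not None and kind != actual:
            raise ValidationError(f"dimension mismatch: requested {kind}, file holds {actual}")
        if actual == "3d":
            return PoseSequence3D(coords, bool(h5.attrs.get("root_relative", False)))
        if "confidence" in h5:
            confidence = np.asarray(h5["confidence"])
        else:
            confidence = np.ones(coords.shape[:2])
        if "observed" in h5:
            observed = np.asarray(h5["observed"]).astype(bool)
        else:
            observed = confidence > 0
        return PoseSequence2D(coords, confidence, observed)


def _read_csv(path, kind):
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValidationError("no frames")
    required = {"frame", "joint", "x", "y"}
    if not required <= set(df.columns):
        raise ValidationError(f"missing columns: {sorted(required - set(df.columns))}")
    actual = "3d" if "z" in df.columns else "2d"
    if kind is not None and kind != actual:
        raise ValidationError(f"dimension mismatch: requested {kind}, file holds {actual}")
    f = int(df["frame"].max()) + 1
    j = int(df["joint"].max()) + 1
    if len(df) != f * j:
        raise ValidationError("incomplete frame/joint grid")
    df = df.sort_values(["frame", "joint"])
    if actual == "3d":
        coords = df[["x", "y", "z"]].to_numpy().reshape(f, j, 3)
        return PoseSequence3D(coords)
    coords = df[["x", "y"]].to_numpy().reshape(f, j, 2)
    if "confidence" in df.columns:
        confidence = df["confidence"].to_numpy().reshape(f, j)
    else:
        confidence = np.ones((f, j))
    if "observed" in df.columns:
        observed = df["observed"].to_numpy().reshape(f, j).astype(bool)
    else:
        observed = confidence > 0
    return PoseSequence2D(coords, confidence, observed)


def write_label_manifest(entries: list[dict], path: str | Path) -> None:
    """JSON manifest: list of {sequence_path, label, task}."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2)


def read_label_manifest(path: str | Path) -> list[dict]:
    with open(path) as fh:
        entries = json.load(fh)
    for e in entries:
        if not {"sequence_path", "label", "task"} <= set(e):
            raise ValidationError("manifest entries need sequence_path, label, task")
    return entries
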