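"""Synthetic skeleton motion: smooth 3D trajectories, 2D projections,
per-frame random joint occlusion, and two-class datasets.

Every generator is a pure function of its parameters and seed, so tests
and benchmarks are reproducible without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton_io import (
    JointLayout,
    LabeledDataset,
    PoseSequence2D,
    PoseSequence3D,
    ValidationError,
)

__all__ = [
    "MotionParams",
    "ClassEffect",
    "rest_pose",
    "gen_pose_sequence",
    "apply_occlusion",
    "gen_classification_dataset",
]

_REST_POSE_SEED = 1234567  # fixed: rest geometry is part of the layout, not the draw


@dataclass(frozen=True)
class MotionParams:
    """Parameters of the sinusoid + drift + noise trajectory model.

    Frequencies are in cycles per sequence; drift is units per frame.
    """

    n_frames: int = 81
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    frequency_range: tuple[float, float] = (0.5, 2.0)
    drift_range: tuple[float, float] = (-0.02, 0.02)
    noise_sd: float = 0.01
    seed: int = 0
    #: When True, each joint moves along a fixed per-joint 3D direction
    #: (drawn once from a frozen stream), so depth is a deterministic
    #: function of the 2D projection and lifting is learnable. When False
    #: (default), the three coordinates oscillate independently.
    coupled_axes: bool = False

    def __post_init__(self):
        if self.n_frames < 4:
            raise ValidationError("n_frames must be >= 4")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for name in ("amplitude_range", "frequency_range", "drift_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValidationError(f"{name} must be (lo, hi) with hi >= lo")


@dataclass(frozen=True)
class ClassEffect:
    """Two-class contrast: class 1 scales the motion amplitude of the
    discriminative joints by `effect_size`."""

    discriminative_joints: tuple[int, ...]
    effect_size: float = 2.0
    n_per_class: int = 20

    def __post_init__(self):
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if len(self.discriminative_joints) == 0 and self.effect_size != 1.0:
            raise ValidationError("effect_size != 1 requires discriminative joints")


def rest_pose(layout: JointLayout) -> np.ndarray:
    """Deterministic J x 3 rest geometry for any tree layout: each joint is
    offset from its parent by a unit vector drawn from a fixed stream."""
    rng = np.random.default_rng(_REST_POSE_SEED)
    j = layout.n_joints
    offsets = rng.normal(size=(j, 3))
    offsets /= np.linalg.norm(offsets, axis=1, keepdims=True)
    pose = np.zeros((j, 3))
    # parents always precede children once sorted by tree depth
    depth = [0] * j
    for i, p in enumerate(layout.parents):
        d, cur = 0, p
        while cur != -1:
            d += 1
            cur = layout.parents[cur]
        depth[i] = d
    for i in sorted(range(j), key=lambda i: depth[i]):
        p = layout.parents[i]
        if p != -1:
            pose[i] = pose[p] + offsets[i]
    return pose


def _motion_directions(n_joints: int) -> np.ndarray:
    """Frozen per-joint unit directions for coupled-axes motion."""
    rng = np.random.default_rng(_REST_POSE_SEED + 1)
    u = rng.normal(size=(n_joints, 3))
    # keep a healthy in-plane component so the 2D projection carries signal
    u[:, :2] += np.sign(u[:, :2]) * 0.5
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def _sample_motion(layout: JointLayout, params: MotionParams,
                   rng: np.random.Generator,
                   amplitude_scale: np.ndarray | None = None) -> np.ndarray:
    f, j = params.n_frames, layout.n_joints
    t = np.arange(f, dtype=np.float64)[:, None, None]
    if params.coupled_axes:
        amp = rng.uniform(*params.amplitude_range, size=j)
        if amplitude_scale is not None:
            amp = amp * amplitude_scale
        freq = rng.uniform(*params.frequency_range, size=j)
        phase = rng.uniform(0, 2 * np.pi, size=j)
        v = rng.uniform(*params.drift_range)
        scalar = (amp[None] * np.sin(2 * np.pi * freq[None] * t[:, :, 0] / f
                                     + phase[None])
                  + v * t[:, :, 0])
        coords = rest_pose(layout)[None] \
            + scalar[:, :, None] * _motion_directions(j)[None]
    else:
        amp = rng.uniform(*params.amplitude_range, size=(j, 3))
        if amplitude_scale is not None:
            amp = amp * amplitude_scale[:, None]
        freq = rng.uniform(*params.frequency_range, size=(j, 3))
        phase = rng.uniform(0, 2 * np.pi, size=(j, 3))
        drift = rng.uniform(*params.drift_range, size=3)
        coords = (rest_pose(layout)[None]
                  + amp[None] * np.sin(2 * np.pi * freq[None] * t / f + phase[None])
                  + drift[None, None, :] * t)
    if params.noise_sd > 0:
        coords = coords + rng.normal(scale=params.noise_sd, size=(f, j, 3))
    return coords


def gen_pose_sequence(layout: JointLayout, params: MotionParams,
                      amplitude_scale: np.ndarray | None = None,
                      ) -> tuple[PoseSequence3D, PoseSequence2D]:
    """Generate a paired (3D, 2D) sequence.

    3D trajectories are per-joint sinusoids plus a shared linear drift plus
    Gaussian noise; the 2D view is the orthographic x-y projection with all
    confidences 1.
    """
    rng = np.random.default_rng(params.seed)
    coords3d = _sample_motion(layout, params, rng, amplitude_scale)
    seq3d = PoseSequence3D(coords3d)
    seq2d = PoseSequence2D.fully_observed(coords3d[:, :, :2].copy())
    return seq3d, seq2d


def apply_occlusion(seq: PoseSequence2D, n_missing: int, seed: int = 0,
                    mode: str = "iid") -> PoseSequence2D:
    """Mark joints unobserved: coords zeroed, confidence 0, observed False.

    ``iid`` (default): exactly `n_missing` uniformly random joints per
    frame, independently across frames. ``block``: the same `n_missing`
    joints are occluded over one contiguous window spanning half the
    sequence (stress-test mode; per-frame counts then vary between 0 and
    `n_missing`).
    """
    f, j = seq.n_frames, seq.n_joints
    if not (0 <= n_missing <= j):
        raise ValidationError(f"n_missing must lie in [0, {j}]")
    out = seq.copy()
    if n_missing == 0:
        return out
    rng = np.random.default_rng(seed)
    if mode == "iid":
        for fr in range(f):
            idx = rng.choice(j, size=n_missing, replace=False)
            out.coords[fr, idx] = 0.0
            out.confidence[fr, idx] = 0.0
            out.observed[fr, idx] = False
    elif mode == "block":
        joints = rng.choice(j, size=n_missing, replace=False)
        span = max(1, f // 2)
        start = int(rng.integers(0, f - span + 1))
        sl = slice(start, start + span)
        for jo in joints:
            out.coords[sl, jo] = 0.0
            out.confidence[sl, jo] = 0.0
            out.observed[sl, jo] = False
    else:
        raise ValueError(f"unknown occlusion mode: {mode!r}")
    return out


def gen_classification_dataset(layout: JointLayout, effect: ClassEffect,
                               params: MotionParams) -> LabeledDataset:
    """Balanced two-class dataset of 3D sequences.

    Class 0 draws from the base motion model; class 1 multiplies the
    sinusoid amplitude (hence also velocity) of the discriminative joints
    by ``effect.effect_size``. Non-discriminative joints are identically
    distributed across classes.
    """
    for jt in effect.discriminative_joints:
        if not (0 <= jt < layout.n_joints):
            raise ValidationError(f"discriminative joint {jt} outside layout")
    scale = np.ones(layout.n_joints)
    scale[list(effect.discriminative_joints)] = effect.effect_size
    ss = np.random.SeedSequence(params.seed)
    child_seeds = ss.generate_state(2 * effect.n_per_class)
    sequences, labels = [], []
    for i in range(2 * effect.n_per_class):
        label = i % 2
        rng = np.random.default_rng(child_seeds[i])
        coords = _sample_motion(layout, params, rng,
                                amplitude_scale=scale if label == 1 else None)
        sequences.append(PoseSequence3D(coords))
        labels.append(label)
    return LabeledDataset(sequences, labels, task_name="synthetic_effect")
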