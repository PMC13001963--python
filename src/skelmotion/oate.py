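"""Occlusion-aware and trend-enhanced input stage.

Two mechanisms operate before any learned model sees the data:

* TLSI — temporally local, confidence-weighted interpolation of missing
  keypoints from observed frames of the same joint.
* TTEP — boundary padding that extrapolates the mean consecutive-frame
  difference at each end of the sequence instead of repeating frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton_io import PaddedSequence, PoseSequence2D, ValidationError

__all__ = [
    "TlsiConfig",
    "TtepConfig",
    "tlsi_weight",
    "tlsi_impute",
    "ttep_trend",
    "ttep_pad",
]


@dataclass(frozen=True)
class TlsiConfig:
    window_halfwidth: int = 5
    lambda_t: float = 0.5
    #: "widen" expands the search window to the whole sequence when a joint
    #: has no observed neighbour locally; "error" raises instead.
    fallback: str = "widen"

    def __post_init__(self):
        if self.window_halfwidth < 1:
            raise ValidationError("window_halfwidth must be >= 1")
        if self.lambda_t < 0:
            raise ValidationError("lambda_t must be >= 0")
        if self.fallback not in ("widen", "error"):
            raise ValidationError("fallback must be 'widen' or 'error'")


@dataclass(frozen=True)
class TtepConfig:
    k: int = 3
    pad: int = 5
    #: "continuity" (default) extends the head trend backwards
    #: (X_{-p} = X_1 - p*Δhead); "as_printed" adds it instead.
    head_mode: str = "continuity"

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.pad < 0:
            raise ValidationError("pad must be >= 0")
        if self.head_mode not in ("continuity", "as_printed"):
            raise ValidationError("head_mode must be 'continuity' or 'as_printed'")


def tlsi_weight(f: int, f_prime: int, c: float, lambda_t: float) -> float:
    """Neighbour weight: exp(-lambda_t * |f - f'|) * c."""
    if lambda_t < 0:
        raise ValidationError("lambda_t must be >= 0")
    if not (0.0 <= c <= 1.0):
        raise ValidationError("confidence must lie in [0, 1]")
    return float(np.exp(-lambda_t * abs(f - f_prime)) * c)


def _impute_one(seq: PoseSequence2D, f: int, j: int, cfg: TlsiConfig) -> np.ndarray | None:
    frames = np.arange(seq.n_frames)
    obs = seq.observed[:, j].copy()
    obs[f] = False  # never use the target frame itself
    lo, hi = f - cfg.window_halfwidth, f + cfg.window_halfwidth
    in_window = (frames >= lo) & (frames <= hi) & obs
    neighbours = frames[in_window]
    if neighbours.size == 0:
        if cfg.fallback == "error":
            raise ValidationError(f"uninterpolatable joint {j} at frame {f}")
        neighbours = frames[obs]
        if neighbours.size == 0:
            raise ValidationError(f"uninterpolatable joint {j}: never observed")
    w = np.exp(-cfg.lambda_t * np.abs(f - neighbours)) * seq.confidence[neighbours, j]
    total = w.sum()
    if total == 0.0:
        # all confidences zero in window: treat as unobserved, widen once
        if cfg.fallback == "error":
            raise ValidationError(f"uninterpolatable joint {j} at frame {f}: zero weights")
        neighbours = frames[obs]
        w = np.exp(-cfg.lambda_t * np.abs(f - neighbours)) * seq.confidence[neighbours, j]
        total = w.sum()
        if total == 0.0:
            raise ValidationError(f"uninterpolatable joint {j}: zero weights everywhere")
    return (w[:, None] * seq.coords[neighbours, j]).sum(axis=0) / total


def tlsi_impute(seq: PoseSequence2D, cfg: TlsiConfig | None = None) -> PoseSequence2D:
    """Fill every unobserved keypoint with the confidence- and
    distance-weighted mean of observed frames of the same joint.

    Observed entries pass through unchanged. Imputed entries are marked
    observed with confidence 1.
    """
    cfg = cfg or TlsiConfig()
    out = seq.copy()
    missing = ~seq.observed
    for f, j in zip(*np.nonzero(missing)):
        value = _impute_one(seq, int(f), int(j), cfg)
        out.coords[f, j] = value
        out.observed[f, j] = True
        out.confidence[f, j] = 1.0
    return out


def ttep_trend(boundary_frames: np.ndarray) -> np.ndarray:
    """Mean consecutive-frame difference over a k-frame window.

    Equals (X_k - X_1) / (k - 1) by telescoping.
    """
    boundary_frames = np.asarray(boundary_frames, dtype=np.float64)
    k = boundary_frames.shape[0]
    if k < 2:
        raise ValidationError("trend window needs at least 2 frames")
    return np.diff(boundary_frames, axis=0).mean(axis=0)


def ttep_pad(coords: np.ndarray, cfg: TtepConfig | None = None) -> PaddedSequence:
    """Extend a (F, ...) array by `pad` extrapolated frames at each end.

    Tail pads are X_F + p * Δtail. Head pads follow ``head_mode``:
    continuity gives X_1 - p * Δhead (backwards extension of the head
    trend); as_printed gives X_1 + p * Δhead, prepended for p = P..1.
    """
    cfg = cfg or TtepConfig()
    coords = np.asarray(coords, dtype=np.float64)
    f = coords.shape[0]
    if cfg.pad == 0:
        return PaddedSequence(coords.copy(), f, 0)
    if f < cfg.k:
        raise ValidationError(f"need at least k={cfg.k} frames to pad, got {f}")
    d_head = ttep_trend(coords[:cfg.k])
    d_tail = ttep_trend(coords[-cfg.k:])
    sign = -1.0 if cfg.head_mode == "continuity" else 1.0
    ps = np.arange(cfg.pad, 0, -1).reshape((-1,) + (1,) * d_head.ndim)
    head = coords[0] + sign * ps * d_head
    ps_tail = np.arange(1, cfg.pad + 1).reshape((-1,) + (1,) * d_tail.ndim)
    tail = coords[-1] + ps_tail * d_tail
    return PaddedSequence(np.concatenate([head, coords, tail], axis=0), f, cfg.pad)
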