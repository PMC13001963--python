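"""Pose-estimation evaluation: MPJPE, PCK and threshold-integrated AUC.

Threshold comparisons are strict (<): a joint whose error equals the
threshold exactly does not count as correct. The AUC discretization is
the mean PCK over an increasing threshold grid (default 5..150 in steps
of 5), i.e. the normalized integral of the PCK curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PoseErrorSummary", "mpjpe", "pck", "auc_pck", "summarize"]

DEFAULT_PCK_THRESHOLD = 150.0
DEFAULT_AUC_GRID = tuple(np.arange(5.0, 151.0, 5.0))


def _coords(x) -> np.ndarray:
    return np.asarray(getattr(x, "coords", x), dtype=np.float64)


def _joint_errors(pred, truth) -> np.ndarray:
    p, t = _coords(pred), _coords(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return np.linalg.norm(p - t, axis=-1)


def mpjpe(pred, truth) -> float:
    """Mean per-joint position error: average Euclidean distance between
    predicted and ground-truth joint positions over all frames and joints."""
    return float(_joint_errors(pred, truth).mean())


def pck(pred, truth, threshold: float = DEFAULT_PCK_THRESHOLD) -> float:
    """Fraction of joints with error strictly below `threshold`."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return float((_joint_errors(pred, truth) < threshold).mean())


def auc_pck(pred, truth, grid=DEFAULT_AUC_GRID) -> float:
    """Mean PCK over the positive thresholds of an increasing grid."""
    grid = [float(t) for t in grid if t > 0]
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly increasing")
    errors = _joint_errors(pred, truth)
    return float(np.mean([(errors < t).mean() for t in grid]))


@dataclass(frozen=True)
class PoseErrorSummary:
    mpjpe: float
    pck: float
    auc: float
    threshold: float = DEFAULT_PCK_THRESHOLD
    thresholds_grid: tuple = DEFAULT_AUC_GRID

    def __post_init__(self):
        if not (0.0 <= self.pck <= 1.0 and 0.0 <= self.auc <= 1.0):
            raise ValueError("pck/auc must lie in [0, 1]")
        if self.mpjpe < 0:
            raise ValueError("mpjpe must be >= 0")


def summarize(pred, truth, threshold: float = DEFAULT_PCK_THRESHOLD,
              grid=DEFAULT_AUC_GRID) -> PoseErrorSummary:
    return PoseErrorSummary(
        mpjpe=mpjpe(pred, truth),
        pck=pck(pred, truth, threshold),
        auc=auc_pck(pred, truth, grid),
        threshold=threshold,
        thresholds_grid=tuple(grid),
    )
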