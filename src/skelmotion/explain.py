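"""Joint-level saliency for a trained skeleton classifier.

Two complementary views of per-joint importance:

* gradient — mean absolute gradient of the pre-sigmoid class logit with
  respect to each joint's input coordinates (the logit rather than the
  probability, to avoid vanishing signal near saturation);
* perturbation — mean absolute change in the class score when a joint's
  coordinates are zeroed or jittered with Gaussian noise.

Both operate on the normalized coordinates the model actually consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .skeleton_io import ValidationError

__all__ = [
    "SaliencyMap",
    "gradient_saliency",
    "perturbation_importance",
    "top_joints",
]


@dataclass(frozen=True)
class SaliencyMap:
    scores: tuple[float, ...]
    method: str
    normalization: str = "none"

    def __post_init__(self):
        if any(s < 0 for s in self.scores):
            raise ValidationError("saliency scores must be nonnegative")
        if self.method not in ("gradient", "perturbation"):
            raise ValidationError("method must be 'gradient' or 'perturbation'")
        if self.normalization not in ("none", "max1", "sum1"):
            raise ValidationError("unknown normalization")

    @property
    def n_joints(self) -> int:
        return len(self.scores)

    def normalized(self, how: str) -> "SaliencyMap":
        scores = np.asarray(self.scores, dtype=np.float64)
        if how == "max1":
            peak = scores.max()
            if peak > 0:
                scores = scores / peak
        elif how == "sum1":
            total = scores.sum()
            if total > 0:
                scores = scores / total
        elif how != "none":
            raise ValidationError("unknown normalization")
        return SaliencyMap(tuple(scores), self.method, how)


def _reduce(values: np.ndarray, reduction: str) -> np.ndarray:
    """(T, J, C) absolute values -> per-joint scores."""
    if reduction == "mean":
        return values.mean(axis=(0, 2))
    if reduction == "max":
        return values.max(axis=(0, 2))
    raise ValidationError("reduction must be 'mean' or 'max'")


def gradient_saliency(model, coords: np.ndarray, target_class: int = 1,
                      reduction: str = "mean") -> SaliencyMap:
    """|d logit / d input| aggregated over frames and coordinate channels.

    `model` must expose ``logit(coords) -> Tensor``; gradients flow
    through the autograd graph back to the input tensor.
    """
    x = nn.Tensor(np.asarray(coords, dtype=np.float64), requires_grad=True)
    logit = model.logit(x)
    sign = 1.0 if int(target_class) == 1 else -1.0
    (logit * sign).sum().backward()
    if x.grad is None:
        raise ValidationError("model produced no gradient for the input")
    scores = _reduce(np.abs(x.grad), reduction)
    return SaliencyMap(tuple(float(s) for s in scores), "gradient")


def perturbation_importance(model, coords: np.ndarray, scheme: str = "zero",
                            sigma: float = 0.1, n_repeats: int = 1,
                            seed: int = 0, reduction: str = "mean") -> SaliencyMap:
    """Mean absolute change of the class score when one joint is perturbed.

    ``zero`` replaces the joint's coordinates by 0; ``gaussian`` adds
    N(0, sigma^2) noise, averaged over `n_repeats` draws.
    """
    coords = np.asarray(coords, dtype=np.float64)
    t, j, c = coords.shape
    if scheme not in ("zero", "gaussian"):
        raise ValidationError("scheme must be 'zero' or 'gaussian'")
    if scheme == "gaussian" and sigma <= 0:
        raise ValidationError("sigma must be > 0 for gaussian perturbation")
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    base = float(model.forward(coords).numpy().reshape(-1)[0])
    rng = np.random.default_rng(seed)
    scores = []
    for joint in range(j):
        deltas = []
        reps = 1 if scheme == "zero" else n_repeats
        for _ in range(reps):
            perturbed = coords.copy()
            if scheme == "zero":
                perturbed[:, joint, :] = 0.0
            else:
                perturbed[:, joint, :] += rng.normal(scale=sigma, size=(t, c))
            out = float(model.forward(perturbed).numpy().reshape(-1)[0])
            deltas.append(abs(out - base))
        scores.append(float(np.mean(deltas)))
    return SaliencyMap(tuple(scores), "perturbation")


def top_joints(saliency: SaliencyMap, k: int) -> list[int]:
    """Indices of the k largest scores; ties break by ascending index."""
    j = saliency.n_joints
    if not (1 <= k <= j):
        raise ValidationError(f"k must lie in [1, {j}]")
    scores = np.asarray(saliency.scores)
    # stable sort on (-score, index)
    order = sorted(range(j), key=lambda i: (-scores[i], i))
    return order[:k]
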