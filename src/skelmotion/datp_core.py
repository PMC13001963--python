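"""Occlusion-robust 2D-to-3D pose lifting network.

Pipeline: TLSI imputation -> TTEP padding -> two-stage residual channel
encoding -> per-stage temporal convolution to a unified feature space ->
cross-attention fusion of the two streams -> temporal crop back to the
original length -> per-scale (spatial transformer -> segmentation ->
local temporal transformer -> recomposition) -> sigmoid scale weighting
-> weighted fusion -> convolutional 3D regression head.

The functional primitives at the top of this module are numpy-only and
exist so each formula can be tested against brute-force oracles; the
Module classes below implement the same math inside the autograd graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .oate import TlsiConfig, TtepConfig, tlsi_impute, ttep_pad
from .skeleton_io import (
    JointLayout,
    ModelConfig,
    PoseSequence2D,
    PoseSequence3D,
    ValidationError,
)

__all__ = [
    "ScaleSpec",
    "default_scale_spec",
    "cross_attention_fuse",
    "crop_to_original",
    "temporal_segment",
    "inverse_recompose",
    "asw_fuse",
    "ResidualFFN",
    "TransformerBlock",
    "DATPModel",
    "preprocess_sequence",
    "datp_forward",
    "train_datp",
]


# --------------------------------------------------------------------------
# functional primitives (numpy)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleSpec:
    """Multi-scale temporal segmentation scheme: one segment length per
    scale; a length that does not divide the working sequence is handled
    by edge-replication padding up to the next multiple."""

    segment_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.segment_lengths) < 1:
            raise ValidationError("need at least one scale")
        if any(s < 1 for s in self.segment_lengths):
            raise ValidationError("segment lengths must be positive")

    @property
    def n_scales(self) -> int:
        return len(self.segment_lengths)

    def n_segments(self, length: int, d: int) -> int:
        s = self.segment_lengths[d]
        if length % s != 0:
            raise ValidationError(f"length {length} not divisible by segment {s}")
        return length // s


def default_scale_spec(n_scales: int, length: int | None = None) -> ScaleSpec:
    """Powers-of-three segment lengths (…, 9, 3, 1), capped at `length`.

    For length 81 and 5 scales this is (81, 27, 9, 3, 1)."""
    lengths = tuple(3 ** (n_scales - 1 - d) for d in range(n_scales))
    if length is not None:
        lengths = tuple(min(s, length) for s in lengths)
    return ScaleSpec(lengths)


def cross_attention_fuse(e1: np.ndarray, e2: np.ndarray,
                         return_attention: bool = False):
    """softmax(E1 E2^T / sqrt(d)) @ E2 with E1 as query, E2 as key/value."""
    e1 = np.asarray(e1, dtype=np.float64)
    e2 = np.asarray(e2, dtype=np.float64)
    if e1.ndim != 2 or e2.ndim != 2 or e1.shape[1] != e2.shape[1]:
        raise ValidationError("E1 and E2 must be (tokens, d) with equal d")
    scores = e1 @ e2.T / np.sqrt(e1.shape[1])
    scores -= scores.max(axis=1, keepdims=True)
    attn = np.exp(scores)
    attn /= attn.sum(axis=1, keepdims=True)
    fused = attn @ e2
    return (fused, attn) if return_attention else fused


def crop_to_original(x, pad: int):
    """Drop `pad` tokens from each end along the leading axis."""
    n = x.shape[0]
    if n < 2 * pad + 1:
        raise ValidationError(f"cannot crop {pad} from each end of {n} tokens")
    if pad == 0:
        return x
    return x[pad:n - pad]


def temporal_segment(x: np.ndarray, s: int) -> np.ndarray:
    """(F, C) -> (F/s, s, C); segment i holds frames i*s .. (i+1)*s - 1."""
    x = np.asarray(x)
    f = x.shape[0]
    if f % s != 0:
        raise ValidationError(f"length {f} not divisible by segment {s}")
    return x.reshape((f // s, s) + x.shape[1:])


def inverse_recompose(segments: np.ndarray) -> np.ndarray:
    """Inverse of temporal_segment: (n, s, C) -> (n*s, C)."""
    segments = np.asarray(segments)
    return segments.reshape((segments.shape[0] * segments.shape[1],) + segments.shape[2:])


def asw_fuse(features: list[np.ndarray], alphas) -> np.ndarray:
    """Elementwise weighted sum of equally-shaped scale features; the
    weights are sigmoid outputs and are not renormalized."""
    if len(features) == 0:
        raise ValidationError("empty scale list")
    alphas = np.asarray(alphas, dtype=np.float64)
    if alphas.shape[0] != len(features):
        raise ValidationError("one weight per scale required")
    shape = features[0].shape
    if any(f.shape != shape for f in features):
        raise ValidationError("scale feature shapes differ")
    out = np.zeros(shape)
    for a, f in zip(alphas, features):
        out = out + a * np.asarray(f, dtype=np.float64)
    return out


# --------------------------------------------------------------------------
# network modules
# --------------------------------------------------------------------------

class ResidualFFN(nn.Module):
    """Z = X + FFN(LayerNorm(X)); identity when the FFN output path is 0."""

    def __init__(self, dim: int, hidden: int, rng, zero_init: bool = False):
        self.norm = nn.LayerNorm(dim)
        self.ffn = nn.FeedForward(dim, hidden, rng, zero_init=zero_init)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return x + self.ffn(self.norm(x))


class TransformerBlock(nn.Module):
    """Pre-norm block as used by both the spatial and the segment-local
    temporal encoders: X + MLP(LN(X + Attn(LN(X))))."""

    def __init__(self, dim: int, heads: int, hidden: int, rng, zero_init: bool = False):
        self.norm1 = nn.LayerNorm(dim)
        self.attn = nn.MultiheadAttention(dim, heads, rng, zero_init=zero_init)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.FeedForward(dim, hidden, rng, zero_init=zero_init)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        inner = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(inner))


class ASWHead(nn.Module):
    """Per-scale weight head: sigmoid(MLP(time-pooled features))."""

    def __init__(self, dim: int, rng):
        # tanh: a tiny ReLU hidden layer can die and freeze the scale weight
        self.mlp = nn.FeedForward(dim, max(1, dim // 4), rng, out_dim=1,
                                  activation="tanh")

    def forward(self, pooled: nn.Tensor) -> nn.Tensor:
        return self.mlp(pooled).sigmoid()


class DATPModel(nn.Module):
    """The lifting network proper (expects already imputed+padded input)."""

    def __init__(self, layout: JointLayout, config: ModelConfig,
                 max_len: int = 512, in_coords: int = 2):
        self.layout = layout
        self.config = config
        self.in_coords = in_coords
        rng = np.random.default_rng(config.seed)
        j = layout.n_joints
        dm, cu = config.dm, config.unified_dim
        heads = config.attention_heads
        if cu % heads != 0:
            raise ValidationError(f"unified dim {cu} not divisible by heads {heads}")
        if config.segment_lengths is not None:
            self.scales = ScaleSpec(config.segment_lengths)
        else:
            self.scales = default_scale_spec(config.n_scales)

        self.embed = nn.Linear(j * in_coords, dm, rng)
        if config.positional_embedding:
            self.pos = nn.Parameter(rng.normal(scale=0.02, size=(max_len, dm)))
        else:
            self.pos = None
        self.stage1 = [ResidualFFN(dm, config.df, rng) for _ in range(config.encoder_layers)]
        self.stage2 = [ResidualFFN(dm, config.df, rng) for _ in range(config.encoder_layers)]
        self.proj1 = nn.Conv1d(dm, cu, config.conv_kernel, rng)
        self.proj2 = nn.Conv1d(dm, cu, config.conv_kernel, rng)
        # residual fusion with a small-scale output projection: plain soft
        # attention over time would replace each frame by a convex mix of
        # other frames and destroy frame-local detail before the crop;
        # exact zero init would leave the second stream without gradient
        self.fuse_attn = nn.MultiheadAttention(cu, heads, rng)
        self.fuse_attn.wo.weight.data *= 0.05
        hidden = 2 * cu
        self.spatial = [TransformerBlock(cu, heads, hidden, rng)
                        for _ in range(self.scales.n_scales)]
        self.local = [TransformerBlock(cu, heads, hidden, rng)
                      for _ in range(self.scales.n_scales)]
        self.asw = [ASWHead(cu, rng) for _ in range(self.scales.n_scales)]
        self.head = nn.Conv1d(cu, j * 3, 1, rng)

    # -- stages ----------------------------------------------------------
    def encode(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        z = x
        for block in self.stage1:
            z = block(z)
        z1 = z
        for block in self.stage2:
            z = block(z)
        return z1, z

    def multi_scale(self, f_tilde: nn.Tensor, ablate_asw: bool = False) -> nn.Tensor:
        length = f_tilde.shape[0]
        outputs: list[nn.Tensor] = []
        alphas: list[nn.Tensor] = []
        for d in range(self.scales.n_scales):
            s = self.scales.segment_lengths[d]
            feat = self.spatial[d](f_tilde)
            work = feat
            extra = (-length) % s
            if extra:
                # edge-replicate up to the next multiple of s
                last = work[length - 1:length]
                reps = nn.Tensor(np.ones((extra, 1)))
                work = _concat_time(work, reps @ last)
            n_seg = work.shape[0] // s
            segs = work.reshape(n_seg, s, work.shape[-1])
            segs = self.local[d](segs)
            out = segs.reshape(n_seg * s, work.shape[-1])
            if extra:
                out = out[:length]
            outputs.append(out)
            pooled = out.mean(axis=0)
            alphas.append(self.asw[d](pooled))
        fused = None
        for out, alpha in zip(outputs, alphas):
            term = out if ablate_asw else out * alpha
            fused = term if fused is None else fused + term
        return fused

    def forward(self, padded_coords: np.ndarray | nn.Tensor, pad: int,
                ablate_asw: bool = False) -> nn.Tensor:
        """(F+2P, J, in_coords) -> (F, J, 3)."""
        x = nn.as_tensor(padded_coords)
        total = x.shape[0]
        j = self.layout.n_joints
        x = x.reshape(total, j * self.in_coords)
        x = self.embed(x)
        if self.pos is not None:
            if total > self.pos.shape[0]:
                raise ValidationError(f"sequence length {total} exceeds positional table")
            x = x + self.pos[:total]
        z1, z2 = self.encode(x)
        e1 = self.proj1(z1)
        e2 = self.proj2(z2)
        fused = e1 + self.fuse_attn(e1, kv=e2)
        cropped = crop_to_original(fused, pad)
        multi = self.multi_scale(cropped, ablate_asw=ablate_asw)
        out = self.head(multi)
        f = out.shape[0]
        return out.reshape(f, j, 3)


def _concat_time(a: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
    return nn.stack([a[i] for i in range(a.shape[0])]
                    + [b[i] for i in range(b.shape[0])], axis=0)


# --------------------------------------------------------------------------
# preprocessing + end-to-end forward
# --------------------------------------------------------------------------

def preprocess_sequence(seq: PoseSequence2D, config: ModelConfig,
                        ablate: frozenset | set = frozenset()) -> tuple[np.ndarray, int]:
    """TLSI imputation then TTEP padding; returns (padded coords, pad).

    Ablations: 'tlsi' replaces imputation by zero-fill, 'confidence' sets
    all confidences to 1 inside the interpolation weights, 'ttep' disables
    boundary padding.
    """
    work = seq
    if "tlsi" in ablate:
        filled = work.copy()
        filled.coords[~filled.observed] = 0.0
        coords = filled.coords
    else:
        if "confidence" in ablate:
            work = work.copy()
            work.confidence[work.observed] = 1.0
        cfg = TlsiConfig(window_halfwidth=config.tlsi_window, lambda_t=config.lambda_t)
        coords = tlsi_impute(work, cfg).coords
    pad = 0 if "ttep" in ablate else config.pad
    padded = ttep_pad(coords, TtepConfig(k=config.trend_window, pad=pad))
    return padded.coords, pad


def datp_forward(model: DATPModel, seq: PoseSequence2D, config: ModelConfig,
                 ablate: frozenset | set = frozenset()) -> PoseSequence3D:
    coords, pad = preprocess_sequence(seq, config, ablate)
    out = model.forward(coords, pad, ablate_asw="asw" in ablate)
    return PoseSequence3D(out.numpy())


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _flip_pair(seq2d: PoseSequence2D, seq3d: PoseSequence3D,
               flip_pairs) -> tuple[PoseSequence2D, PoseSequence3D]:
    """Mirror the x axis and swap left/right joints."""
    s2, s3 = seq2d.copy(), seq3d.copy()
    s2.coords[:, :, 0] *= -1
    s3.coords[:, :, 0] *= -1
    for a, b in flip_pairs:
        for arr in (s2.coords, s2.confidence, s2.observed, s3.coords):
            arr[:, [a, b]] = arr[:, [b, a]]
    return s2, s3


def _pose_loss(pred: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    """Mean per-joint Euclidean distance (differentiable MPJPE)."""
    diff = pred - nn.Tensor(target)
    sq = (diff * diff).sum(axis=-1)
    return ((sq + 1e-12) ** 0.5).mean()


def train_datp(pairs: list[tuple[PoseSequence2D, PoseSequence3D]],
               layout: JointLayout, config: ModelConfig,
               ablate: frozenset | set = frozenset(),
               flip_pairs=None, model: DATPModel | None = None,
               ) -> tuple[DATPModel, list[dict]]:
    """Train the lifting network with Adam and per-epoch lr decay.

    Returns the model and a history of {'epoch', 'loss', 'lr'} records;
    the loss is the mean differentiable MPJPE over the training pairs.
    """
    if len(pairs) == 0:
        raise ValidationError("empty training set")
    if model is None:
        max_f = max(p[0].n_frames for p in pairs)
        model = DATPModel(layout, config, max_len=max_f + 2 * config.pad + 8)
    # preprocessing has no trainable parameters: cache it
    cache = [preprocess_sequence(s2, config, ablate) for s2, _ in pairs]
    targets = [s3.coords for _, s3 in pairs]
    if config.horizontal_flip:
        if flip_pairs is None:
            raise ValidationError("horizontal_flip requires flip_pairs")
        flipped = [_flip_pair(s2, s3, flip_pairs) for s2, s3 in pairs]
        cache += [preprocess_sequence(s2, config, ablate) for s2, _ in flipped]
        targets += [s3.coords for _, s3 in flipped]
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    sched = nn.ExponentialDecay(opt, config.lr_decay)
    history: list[dict] = []
    for epoch in range(config.epochs):
        total = 0.0
        for (coords, pad), target in zip(cache, targets):
            opt.zero_grad()
            pred = model.forward(coords, pad, ablate_asw="asw" in ablate)
            loss = _pose_loss(pred, target)
            value = float(loss.numpy())
            if not np.isfinite(value):
                raise ValidationError(
                    f"non-finite loss at epoch {epoch}: {value}")
            loss.backward()
            opt.step()
            total += value
        history.append({"epoch": epoch, "loss": total / len(cache), "lr": opt.lr})
        sched.step()
    return model, history


def evaluate_datp(model: DATPModel, pairs, config: ModelConfig,
                  ablate: frozenset | set = frozenset()) -> float:
    """Mean MPJPE of the model over (2D, 3D) pairs."""
    from .pose_metrics import mpjpe

    errs = [mpjpe(datp_forward(model, s2, config, ablate), s3) for s2, s3 in pairs]
    return float(np.mean(errs))
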