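"""Adaptive-graph skeleton classifier.

A static binary adjacency from the skeleton tree is fused with a
per-frame attention-derived row-stochastic adjacency; graph convolution,
a residual per-node channel MLP, temporal stacking and global pooling
produce a sequence embedding for a two-layer binary head.

Functional numpy primitives (for oracle tests) live alongside the
autograd Modules that the trained network uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .skeleton_io import JointLayout, LabeledDataset, ValidationError

__all__ = [
    "AdjacencyPair",
    "ClassificationReport",
    "AgtmConfig",
    "build_static_adjacency",
    "dynamic_adjacency",
    "fuse_adjacency",
    "graph_conv",
    "stack_temporal",
    "global_pool",
    "normalize_skeleton",
    "AGTMNet",
    "train_agtm",
    "predict_proba",
    "classification_metrics",
]


# --------------------------------------------------------------------------
# functional primitives
# --------------------------------------------------------------------------

def build_static_adjacency(layout: JointLayout, self_loops: bool = True) -> np.ndarray:
    """Symmetric binary adjacency of the skeleton tree."""
    j = layout.n_joints
    a0 = np.zeros((j, j))
    for child, parent in layout.edges:
        a0[child, parent] = 1.0
        a0[parent, child] = 1.0
    if self_loops:
        np.fill_diagonal(a0, 1.0)
    return a0


def dynamic_adjacency(xt: np.ndarray, wq: np.ndarray, wk: np.ndarray) -> np.ndarray:
    """Row-wise softmax of (Xt Wq)(Xt Wk)^T / sqrt(dk)."""
    xt = np.asarray(xt, dtype=np.float64)
    wq = np.asarray(wq, dtype=np.float64)
    wk = np.asarray(wk, dtype=np.float64)
    dk = wq.shape[1]
    if dk <= 0 or wk.shape[1] != dk:
        raise ValidationError("Wq and Wk must share a positive key dimension")
    scores = (xt @ wq) @ (xt @ wk).T / np.sqrt(dk)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def fuse_adjacency(a0: np.ndarray, ad: np.ndarray, lam: float) -> np.ndarray:
    """Convex combination lam*A0 + (1-lam)*Ad."""
    if not (0.0 <= lam <= 1.0):
        raise ValidationError("lambda must lie in [0, 1]")
    a0 = np.asarray(a0, dtype=np.float64)
    ad = np.asarray(ad, dtype=np.float64)
    if a0.shape != ad.shape:
        raise ValidationError("adjacency shapes differ")
    return lam * a0 + (1.0 - lam) * ad


@dataclass
class AdjacencyPair:
    a0: np.ndarray
    ad: np.ndarray
    lam: float

    def __post_init__(self):
        self.a0 = np.asarray(self.a0, dtype=np.float64)
        self.ad = np.asarray(self.ad, dtype=np.float64)
        if self.a0.shape != self.ad.shape or self.a0.ndim != 2:
            raise ValidationError("A0/Ad must be equal square matrices")
        if not np.array_equal(self.a0, self.a0.T):
            raise ValidationError("A0 must be symmetric")
        if not np.isin(self.a0, (0.0, 1.0)).all():
            raise ValidationError("A0 entries must be 0 or 1")
        if not np.allclose(self.ad.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("Ad rows must sum to 1")
        if not (0.0 <= self.lam <= 1.0):
            raise ValidationError("lambda must lie in [0, 1]")

    @property
    def a_final(self) -> np.ndarray:
        return fuse_adjacency(self.a0, self.ad, self.lam)


def graph_conv(a_final: np.ndarray, xt: np.ndarray, wf: np.ndarray,
               activation="relu") -> np.ndarray:
    """Ht = activation(A_final @ Xt @ Wf)."""
    z = np.asarray(a_final) @ np.asarray(xt) @ np.asarray(wf)
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "identity" or activation is None:
        return z
    if callable(activation):
        return activation(z)
    raise ValidationError(f"unknown activation: {activation!r}")


def stack_temporal(frames: list[np.ndarray]) -> np.ndarray:
    """Stack T per-frame (J, C') feature matrices into (T, J, C')."""
    if len(frames) == 0:
        raise ValidationError("empty frame list")
    shape = np.asarray(frames[0]).shape
    if any(np.asarray(f).shape != shape for f in frames):
        raise ValidationError("frame feature shapes differ")
    return np.stack([np.asarray(f, dtype=np.float64) for f in frames], axis=0)


def global_pool(h: np.ndarray) -> np.ndarray:
    """Channelwise mean over all time steps and joints: (T, J, C') -> (C',)."""
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 3 or h.size == 0:
        raise ValidationError("expected nonempty (T, J, C') tensor")
    return h.mean(axis=(0, 1))


# --------------------------------------------------------------------------
# input normalization
# --------------------------------------------------------------------------

def normalize_skeleton(coords: np.ndarray, layout: JointLayout) -> np.ndarray:
    """Root-center each frame and divide by the sequence's mean bone length."""
    coords = np.asarray(coords, dtype=np.float64)
    centered = coords - coords[:, layout.root_index:layout.root_index + 1]
    lengths = [np.linalg.norm(centered[:, c] - centered[:, p], axis=-1)
               for c, p in layout.edges]
    scale = float(np.mean(lengths)) if lengths else 1.0
    if scale <= 0:
        scale = 1.0
    return centered / scale


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

@dataclass
class AgtmConfig:
    hidden_dim: int = 16
    key_dim: int = 8
    gc_layers: int = 2
    adjacency_mix: float = 0.5
    head_hidden: int = 16
    learning_rate: float = 1e-4
    milestones: tuple[int, ...] = (30, 40)
    lr_factor: float = 0.1
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.adjacency_mix <= 1.0):
            raise ValidationError("adjacency_mix must lie in [0, 1]")
        for name in ("hidden_dim", "key_dim", "gc_layers", "head_hidden", "epochs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


class CCIBlock(nn.Module):
    """Per-node residual channel MLP: H + MLP(LayerNorm(H))."""

    def __init__(self, dim: int, rng, zero_init: bool = False):
        self.norm = nn.LayerNorm(dim)
        self.mlp = nn.FeedForward(dim, dim, rng, zero_init=zero_init)

    def forward(self, h: nn.Tensor) -> nn.Tensor:
        return h + self.mlp(self.norm(h))


class AGTMNet(nn.Module):
    """Graph feature extractor + binary classification head.

    The dynamic adjacency is recomputed at every time step from that
    frame's input node features with one shared query/key projection;
    all graph layers at a time step share the fused adjacency.
    """

    def __init__(self, layout: JointLayout, config: AgtmConfig, in_dim: int = 3):
        self.layout = layout
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.a0 = build_static_adjacency(layout)  # fixed, not trained
        self.wq = nn.Parameter(rng.normal(scale=0.3, size=(in_dim, config.key_dim)))
        self.wk = nn.Parameter(rng.normal(scale=0.3, size=(in_dim, config.key_dim)))
        dims = [in_dim] + [config.hidden_dim] * config.gc_layers
        self.wf = [nn.Parameter(rng.normal(scale=np.sqrt(2.0 / dims[i]),
                                           size=(dims[i], dims[i + 1])))
                   for i in range(config.gc_layers)]
        self.cci = [CCIBlock(config.hidden_dim, rng) for _ in range(config.gc_layers)]
        self.head = nn.FeedForward(config.hidden_dim, config.head_hidden, rng, out_dim=1)

    def dynamic_adjacency(self, x: nn.Tensor) -> nn.Tensor:
        """(T, J, C) -> (T, J, J) row-stochastic."""
        q = x @ self.wq
        k = x @ self.wk
        scores = q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(self.config.key_dim))
        return scores.softmax(axis=-1)

    def extract(self, coords: np.ndarray | nn.Tensor) -> nn.Tensor:
        """(T, J, C_in) -> (T, J, hidden) frame-level skeleton features."""
        x = nn.as_tensor(coords)
        ad = self.dynamic_adjacency(x)
        lam = self.config.adjacency_mix
        a_final = nn.Tensor(self.a0) * lam + ad * (1.0 - lam)
        h = x
        for wf, cci in zip(self.wf, self.cci):
            h = (a_final @ h @ wf).relu()
            h = cci(h)
        return h

    def logit(self, coords) -> nn.Tensor:
        h = self.extract(coords)
        g = h.mean(axis=(0, 1))
        return self.head(g)

    def forward(self, coords) -> nn.Tensor:
        """Probability of class 1."""
        return self.logit(coords).sigmoid()


def predict_proba(model: AGTMNet, coords: np.ndarray) -> float:
    return float(model.forward(coords).numpy()[0])


def predict_label(model: AGTMNet, coords: np.ndarray) -> int:
    # ties at exactly 0.5 classify as class 1
    return int(predict_proba(model, coords) >= 0.5)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _bce(logit: nn.Tensor, label: int) -> nn.Tensor:
    """Numerically stable binary cross-entropy on the logit:
    softplus(z) - y*z, with softplus(z) = m + log(exp(z-m) + exp(-m))
    for the constant shift m = max(z, 0)."""
    z = logit
    m = np.maximum(z.numpy(), 0.0)
    softplus = nn.Tensor(m) + ((z - m).exp() + np.exp(-m)).log()
    return (softplus - z * float(label)).sum()


def train_agtm(dataset: LabeledDataset, layout: JointLayout,
               config: AgtmConfig | None = None, in_dim: int = 3,
               model: AGTMNet | None = None) -> tuple[AGTMNet, list[dict]]:
    """Train the classifier with Adam, milestone lr decay, and BCE loss.

    Sequences are root-centered and bone-length normalized before the
    network sees them. Deterministic for a fixed config seed.
    """
    config = config or AgtmConfig()
    labels = set(dataset.labels)
    if len(labels) < 2:
        raise ValidationError("training requires samples from both classes")
    if model is None:
        model = AGTMNet(layout, config, in_dim=in_dim)
    inputs = [normalize_skeleton(s.coords, layout) for s in dataset.sequences]
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    sched = nn.MilestoneDecay(opt, list(config.milestones), config.lr_factor)
    order_rng = np.random.default_rng(config.seed + 1)
    history: list[dict] = []
    n = len(inputs)
    for epoch in range(config.epochs):
        total = 0.0
        for i in order_rng.permutation(n):
            opt.zero_grad()
            loss = _bce(model.logit(inputs[i]), dataset.labels[i])
            value = float(loss.numpy())
            if not np.isfinite(value):
                raise ValidationError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            total += value
        history.append({"epoch": epoch, "loss": total / n, "lr": opt.lr})
        sched.step()
    return model, history


def evaluate_agtm(model: AGTMNet, dataset: LabeledDataset,
                  layout: JointLayout) -> "ClassificationReport":
    preds = [predict_label(model, normalize_skeleton(s.coords, layout))
             for s in dataset.sequences]
    return classification_metrics(dataset.labels, preds)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    #: True when precision, recall, or F1 had a zero denominator and was
    #: reported as 0 by convention.
    degenerate: bool = False


def classification_metrics(labels, predictions) -> ClassificationReport:
    labels = [int(l) for l in labels]
    predictions = [int(p) for p in predictions]
    if len(labels) != len(predictions):
        raise ValidationError("labels and predictions lengths differ")
    if any(v not in (0, 1) for v in labels + predictions):
        raise ValidationError("labels and predictions must be binary")
    tp = sum(1 for l, p in zip(labels, predictions) if l == 1 and p == 1)
    fp = sum(1 for l, p in zip(labels, predictions) if l == 0 and p == 1)
    fn = sum(1 for l, p in zip(labels, predictions) if l == 1 and p == 0)
    tn = sum(1 for l, p in zip(labels, predictions) if l == 0 and p == 0)
    total = tp + fp + fn + tn
    if total == 0:
        raise ValidationError("empty input")
    accuracy = (tp + tn) / total
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationReport(tp, fp, fn, tn, accuracy, precision, recall, f1, degenerate)
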