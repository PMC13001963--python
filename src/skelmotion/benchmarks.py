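"""Desk-scale experiment protocols on synthetic motion.

These mirror, at toy scale, the experimental designs the full system is
evaluated with: occlusion-robustness curves (test error versus number of
missing joints per frame), component ablations, single-sequence overfit
capacity, classifier recovery of an injected class effect, and agreement
between gradient- and perturbation-based saliency.
"""

from __future__ import annotations

import numpy as np

from .agtm import AgtmConfig, evaluate_agtm, normalize_skeleton, train_agtm
from .datp_core import evaluate_datp, train_datp
from .explain import gradient_saliency, perturbation_importance
from .skeleton_io import JointLayout, LabeledDataset, ModelConfig, h36m_layout
from .synthetic_motion import (
    ClassEffect,
    MotionParams,
    apply_occlusion,
    gen_classification_dataset,
    gen_pose_sequence,
)

__all__ = [
    "toy_pose_config",
    "make_pose_pairs",
    "occlusion_robustness",
    "ablation_study",
    "overfit_single_sequence",
    "classifier_recovery",
    "saliency_discrimination",
]


def toy_pose_config(n_frames: int = 24, seed: int = 0, epochs: int = 40,
                    **overrides) -> ModelConfig:
    """Small lifting config that trains in seconds on one CPU."""
    base = dict(dm=8, df=16, attention_heads=4, n_scales=2,
                segment_lengths=(n_frames, max(1, n_frames // 4)),
                pad=3, trend_window=3, tlsi_window=3, lambda_t=1.0,
                # gentler decay than the full-scale default: at toy epoch
                # counts 0.95/epoch collapses the lr before convergence
                learning_rate=1e-2, lr_decay=0.99, epochs=epochs, seed=seed)
    base.update(overrides)
    return ModelConfig(**base)


def pose_benchmark_layout(n_joints: int = 12) -> JointLayout:
    """Chain layout for the pose benchmarks: small enough to train fast,
    large enough that 8 missing joints per frame leaves every joint
    observed somewhere in the sequence."""
    return JointLayout(tuple(f"j{i}" for i in range(n_joints)),
                       (-1,) + tuple(range(n_joints - 1)))


def make_pose_pairs(layout: JointLayout, n: int, n_frames: int, n_missing: int,
                    seed: int, noise_sd: float = 0.01) -> list:
    """(occluded 2D, clean 3D) pairs from the synthetic generator."""
    pairs = []
    for i in range(n):
        params = MotionParams(n_frames=n_frames, noise_sd=noise_sd,
                              frequency_range=(0.3, 1.0), coupled_axes=True,
                              seed=seed * 100_003 + i)
        seq3d, seq2d = gen_pose_sequence(layout, params)
        occ = apply_occlusion(seq2d, n_missing, seed=seed * 100_003 + 50_000 + i)
        pairs.append((occ, seq3d))
    return pairs


def occlusion_robustness(levels=(0, 2, 4, 8), seeds=(0, 1, 2), n_train: int = 12,
                         n_test: int = 8, n_frames: int = 24,
                         epochs: int = 100) -> dict[int, float]:
    """Mean test MPJPE per occlusion level, averaged over seeds.

    One model per seed is trained at a moderate occlusion level and then
    evaluated on held-out sequences with progressively more missing
    joints per frame.
    """
    layout = pose_benchmark_layout()
    results = {lvl: [] for lvl in levels}
    for seed in seeds:
        config = toy_pose_config(n_frames, seed=seed, epochs=epochs, dm=28, df=32)
        train_pairs = make_pose_pairs(layout, n_train, n_frames, 2, seed)
        model, _ = train_datp(train_pairs, layout, config)
        for lvl in levels:
            test_pairs = make_pose_pairs(layout, n_test, n_frames, lvl, seed + 777)
            results[lvl].append(evaluate_datp(model, test_pairs, config))
    return {lvl: float(np.mean(v)) for lvl, v in results.items()}


ABLATION_VARIANTS = {
    "full": frozenset(),
    "no_asw": frozenset({"asw"}),
    "no_ttep": frozenset({"ttep"}),
    "no_tlsi_ttep": frozenset({"tlsi", "ttep"}),
}


def ablation_study(seeds=(0, 1, 2), n_train: int = 12, n_test: int = 8,
                   n_frames: int = 24, n_missing: int = 4,
                   epochs: int = 80) -> dict[str, float]:
    """Mean test MPJPE per ablation variant (trained and evaluated with
    the same components removed), averaged over seeds."""
    layout = pose_benchmark_layout()
    results = {name: [] for name in ABLATION_VARIANTS}
    for seed in seeds:
        train_pairs = make_pose_pairs(layout, n_train, n_frames, n_missing, seed)
        test_pairs = make_pose_pairs(layout, n_test, n_frames, n_missing, seed + 777)
        for name, ablate in ABLATION_VARIANTS.items():
            config = toy_pose_config(n_frames, seed=seed, epochs=epochs, dm=28, df=32)
            model, _ = train_datp(train_pairs, layout, config, ablate=ablate)
            results[name].append(evaluate_datp(model, test_pairs, config, ablate))
    return {name: float(np.mean(v)) for name, v in results.items()}


def overfit_single_sequence(epochs: int = 300, n_frames: int = 24,
                            seed: int = 0) -> tuple[float, float]:
    """(initial, final) training MPJPE when fitting one sequence."""
    layout = h36m_layout()
    config = toy_pose_config(n_frames, seed=seed, epochs=epochs)
    pairs = make_pose_pairs(layout, 1, n_frames, 2, seed)
    model, history = train_datp(pairs, layout, config)
    return float(history[0]["loss"]), float(history[-1]["loss"])


def _split(dataset: LabeledDataset, n_train: int) -> tuple[LabeledDataset, LabeledDataset]:
    # labels alternate 0/1, so a prefix split stays balanced
    return (LabeledDataset(dataset.sequences[:n_train], dataset.labels[:n_train],
                           dataset.task_name),
            LabeledDataset(dataset.sequences[n_train:], dataset.labels[n_train:],
                           dataset.task_name))


#: both hips, spine, thorax in the default layout. The root (pelvis) is
#: deliberately excluded: root-centering zeroes its coordinates, which
#: makes zero-scheme perturbation blind to it.
DISCRIMINATIVE_JOINTS = (1, 4, 7, 8)

#: spine and thorax: the saliency benchmark injects only joints whose
#: signal survives root-centering and bone-length normalization cleanly
#: (hip amplitude partially leaks into the normalization scale).
SALIENCY_JOINTS = (7, 8)


def classifier_recovery(effect_size: float, n_per_class: int = 40,
                        n_frames: int = 24, seed: int = 0, epochs: int = 60,
                        train_fraction: float = 0.7,
                        joints: tuple[int, ...] = DISCRIMINATIVE_JOINTS):
    """Held-out classification report for an injected class effect."""
    layout = h36m_layout()
    effect = ClassEffect(joints, effect_size, n_per_class)
    params = MotionParams(n_frames=n_frames, noise_sd=0.02, seed=seed)
    dataset = gen_classification_dataset(layout, effect, params)
    n_train = int(round(2 * n_per_class * train_fraction))
    n_train -= n_train % 2
    train, test = _split(dataset, n_train)
    config = AgtmConfig(hidden_dim=24, epochs=epochs, learning_rate=3e-3, seed=seed)
    model, _ = train_agtm(train, layout, config)
    return evaluate_agtm(model, test, layout), model, test


def saliency_discrimination(seed: int, effect_size: float = 3.0,
                            n_per_class: int = 24, n_frames: int = 24,
                            epochs: int = 50) -> dict[str, list[float]]:
    """Dataset-averaged saliency per method for a trained classifier.

    Returns per-joint scores averaged over the held-out sequences.
    """
    layout = h36m_layout()
    _, model, test = classifier_recovery(effect_size, n_per_class, n_frames,
                                         seed, epochs, joints=SALIENCY_JOINTS)
    grad = np.zeros(layout.n_joints)
    pert = np.zeros(layout.n_joints)
    for seq in test.sequences:
        coords = normalize_skeleton(seq.coords, layout)
        grad += np.asarray(gradient_saliency(model, coords).scores)
        pert += np.asarray(perturbation_importance(model, coords, "zero").scores)
    n = len(test.sequences)
    return {"gradient": (grad / n).tolist(), "perturbation": (pert / n).tolist()}
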