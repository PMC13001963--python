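import numpy as np
import pytest

from skelmotion import ModelConfig, h36m_layout
from skelmotion.skeleton_io import JointLayout, PoseSequence2D
from skelmotion.synthetic_motion import MotionParams, gen_pose_sequence


@pytest.fixture
def layout():
    return h36m_layout()


@pytest.fixture
def chain3():
    return JointLayout(("a", "b", "c"), (-1, 0, 1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_config():
    """Small configuration that trains in well under a second per epoch."""
    return ModelConfig(dm=8, df=16, attention_heads=4, n_scales=2,
                       segment_lengths=(12, 4), pad=3, epochs=3, seed=0)


@pytest.fixture
def small_pair(layout):
    """(2D, 3D) synthetic pair with 12 frames and 17 joints."""
    seq3d, seq2d = gen_pose_sequence(layout, MotionParams(n_frames=12, seed=7))
    return seq2d, seq3d


def random_seq2d(rng, f=8, j=5, n_missing=0):
    coords = rng.normal(size=(f, j, 2))
    conf = rng.uniform(0.2, 1.0, size=(f, j))
    observed = np.ones((f, j), dtype=bool)
    seq = PoseSequence2D(coords, conf, observed)
    if n_missing:
        for fr in range(f):
            idx = rng.choice(j, size=n_missing, replace=False)
            seq.coords[fr, idx] = 0
            seq.confidence[fr, idx] = 0
            seq.observed[fr, idx] = False
    return seq
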