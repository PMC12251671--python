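import numpy as np
import pytest

from cogpose.anthropometry import load_table
from cogpose.skeleton import Pose2D, Pose3D, make_bone_tree, make_layout
from cogpose.synth import SynthConfig, sample_pose3d, sample_skeleton


@pytest.fixture(scope="session")
def layout():
    return make_layout()


@pytest.fixture(scope="session")
def tree():
    return make_bone_tree()


@pytest.fixture(scope="session")
def table_m():
    return load_table("M")


@pytest.fixture(scope="session")
def table_f():
    return load_table("F")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_pose(rng):
    """An arbitrary (non-anatomical) valid 3D pose, mm scale."""
    return Pose3D(coords=rng.normal(0.0, 400.0, (133, 3)))


@pytest.fixture()
def articulated_pose(rng):
    """An anatomically articulated pose from the synthetic generator."""
    cfg = SynthConfig(seed=0)
    sk = sample_skeleton(cfg, rng)
    return sample_pose3d(sk, cfg, rng)


@pytest.fixture()
def random_pose2d(rng):
    coords = rng.normal(0.0, 100.0, (133, 2))
    return Pose2D(coords=coords, confidence=rng.uniform(0, 1, 133),
                  valid=np.ones(133, bool))
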