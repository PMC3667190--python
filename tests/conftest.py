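import numpy as np
import pytest

from natisc.prep import GroupDataset, Mask, SubjectData
from natisc.synthdata import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_synth():
    """Small but structurally complete cohort: 5 subjects, 2+2 components."""
    cfg = SynthConfig(
        n_subjects=5,
        grid_shape=(10, 10, 4),
        n_volumes=160,
        support_shape=(4, 4, 2),
        n_extrinsic=2,
        n_intrinsic=2,
        seed=7,
    )
    return generate_dataset(cfg)


def make_group(bolds, tr=2.5, shape=None, n_conf=6, rng=None):
    """Assemble a GroupDataset from a list of voxel x time arrays."""
    rng = rng or np.random.default_rng(0)
    v, t = bolds[0].shape
    shape = shape or (v, 1, 1)
    subjects = [
        SubjectData(b, rng.standard_normal((t, n_conf)) * 0.01, f"s{i}", tr)
        for i, b in enumerate(bolds)
    ]
    return GroupDataset(subjects, Mask.full(shape), tr)


@pytest.fixture
def make_group_factory():
    return make_group
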