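import numpy as np
import pytest

from skelfuse.data_model import CohortDataset, SkeletonMask


def random_mask(rng: np.random.Generator, shape=(8, 8, 8), p=0.4) -> SkeletonMask:
    mask = rng.random(shape) < p
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return SkeletonMask(mask=mask)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_mask(rng) -> SkeletonMask:
    return random_mask(rng)


@pytest.fixture
def tiny_cohort(rng) -> CohortDataset:
    """3 vs 3 subjects, one metric, 30-voxel line mask."""
    mask = np.zeros((5, 6, 1), dtype=bool)
    mask[:, :, 0] = True
    skel = SkeletonMask(mask=mask)
    x = rng.normal(size=(6, skel.n_voxels))
    return CohortDataset(
        metrics={"m": x},
        labels=np.array(list("AAABBB"), dtype=object),
        subject_ids=[f"s{i}" for i in range(6)],
        mask=skel,
    )
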