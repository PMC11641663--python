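import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from radgenmap.radiomics import BinaryMask, DiscretizedROI, ImageVolume
from radgenmap.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """14-patient cohort at pilot scale, shared across tests."""
    return generate_cohort(CohortConfig(n_patients=14, seed=42, image_shape=(16, 16, 16)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_roi(rng, max_side=6, ng_max=4):
    """A random small discretized ROI with a non-empty random mask."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    ng = int(rng.integers(1, ng_max + 1))
    levels = rng.integers(1, ng + 1, size=shape)
    level_grid = np.where(mask, levels, 0)
    return DiscretizedROI(level_grid.astype(np.int64), mask, 1.0)


@pytest.fixture
def toy_roi():
    """Fixed 4x4x1 grid exercising multiple runs, zones and dependencies."""
    levels = np.array(
        [[[1], [1], [2], [3]],
         [[1], [2], [2], [3]],
         [[4], [4], [1], [1]],
         [[4], [3], [3], [2]]],
        dtype=np.int64,
    )
    mask = np.ones_like(levels, dtype=bool)
    return DiscretizedROI(levels, mask, 1.0)


def make_volume(grid, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(grid, dtype=float), spacing)


def full_mask(shape):
    return BinaryMask(np.ones(shape, dtype=np.uint8))
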