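import numpy as np
import pytest

from contourqa import VoxelMask, shift


def make_cube(fill: int = 10, lattice: int = 12,
              spacing=(1.0, 1.0, 1.0)) -> VoxelMask:
    occ = np.zeros((lattice,) * 3, dtype=bool)
    occ[:fill, :fill, :fill] = True
    return VoxelMask(occ, spacing=spacing, label="cube")


@pytest.fixture
def cube() -> VoxelMask:
    """10x10x10 solid cube on a 12^3 lattice, 1 mm voxels."""
    return make_cube()


@pytest.fixture
def shifted_cube(cube) -> VoxelMask:
    """The same cube translated one voxel along the lattice diagonal."""
    return shift(cube, (1, 1, 1))


def random_mask(rng: np.random.Generator, shape=(9, 9, 9), p: float = 0.35,
                nonempty: bool = True) -> VoxelMask:
    occ = rng.random(shape) < p
    if nonempty and not occ.any():
        occ[tuple(rng.integers(0, s) for s in shape)] = True
    return VoxelMask(occ)


def random_blob(rng: np.random.Generator, shape=(16, 16, 12)) -> VoxelMask:
    """A random solid ball — a contour-like mask rather than voxel noise."""
    center = [rng.uniform(s * 0.3, s * 0.7) for s in shape]
    radius = rng.uniform(2.5, min(shape) * 0.35)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return VoxelMask(d2 <= radius ** 2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
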