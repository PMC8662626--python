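import math

import numpy as np
import pytest

from brainfd import generate_scale_schedule, menger_sponge


@pytest.fixture(scope="session")
def default_schedule():
    return generate_scale_schedule()


@pytest.fixture(scope="session")
def menger3():
    return menger_sponge(3)


@pytest.fixture(scope="session")
def menger4():
    return menger_sponge(4)


def brute_force_count(mask: np.ndarray, s: float) -> int:
    """Independent box-count oracle: pure-Python floor-triple enumeration.

    Applies the same grid definition as the implementation — cells of edge
    ``s`` anchored at the array origin, per-axis cell count
    ``max(1, ceil(d/s) - 1)`` with out-of-range cells folded onto the last
    kept cell — but via explicit per-voxel set enumeration, sharing no code
    with the vectorized path.
    """
    shape = mask.shape
    nbins = [max(1, math.ceil(d / s) - 1) for d in shape]
    occupied = set()
    for i, j, k in zip(*[axis.tolist() for axis in np.nonzero(mask)]):
        cell = tuple(
            min(math.floor(c / s), b - 1) for c, b in zip((i, j, k), nbins)
        )
        occupied.add(cell)
    return len(occupied)


@pytest.fixture(scope="session")
def random_masks():
    """Seeded batch of small random masks of assorted sizes and densities."""
    rng = np.random.default_rng(20211126)
    masks = []
    for _ in range(100):
        shape = tuple(rng.integers(4, 25, size=3))
        density = rng.uniform(0.02, 0.5)
        mask = rng.random(shape) < density
        if not mask.any():
            mask[tuple(d // 2 for d in shape)] = True
        masks.append(mask)
    return masks
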