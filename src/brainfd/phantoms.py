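"""Synthetic 3D masks with known dimension for validating the estimator.

Euclidean phantoms (filled cube → 3, one-voxel slab → 2, one-voxel line → 1)
probe the integer-dimension limits; the Menger sponge probes a genuinely
fractal target with similarity dimension log 20 / log 3 ≈ 2.7268; the random
blob (thresholded smoothed noise) has no analytic dimension and exists for
count-oracle equivalence tests only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_sessions import MAX_LABEL, LabelVolume

#: Similarity dimension of the Menger sponge.
MENGER_FD = math.log(20) / math.log(3)

#: Analytic dimension per phantom kind (None where undefined).
EXPECTED_FD: dict[str, float | None] = {
    "filled_cube": 3.0,
    "slab": 2.0,
    "line": 1.0,
    "menger_sponge": MENGER_FD,
    "random_blob": None,
}

KINDS = tuple(EXPECTED_FD)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom: kind, size (or recursion level), seed."""

    kind: str
    size_or_level: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; one of {KINDS}")
        if self.kind == "menger_sponge":
            if self.size_or_level < 1:
                raise ValueError("menger_sponge level must be >= 1")
        elif self.size_or_level < 2:
            raise ValueError(f"{self.kind} size must be >= 2")

    @property
    def expected_fd(self) -> float | None:
        return EXPECTED_FD[self.kind]


def menger_sponge(level: int) -> np.ndarray:
    """Level-L sponge on a (3**L)³ grid with exactly 20**L occupied voxels.

    Each recursion replaces every occupied cell by a 3×3×3 block with the
    six face centers and the body center removed.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    block = np.ones((3, 3, 3), dtype=bool)
    block[1, 1, :] = block[1, :, 1] = block[:, 1, 1] = False
    mask = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        mask = np.kron(mask, block)
    return mask


def random_blob(size: int, seed: int = 0, sigma: float = 2.0) -> np.ndarray:
    """Seeded morphological blob: Gaussian-smoothed noise above its median."""
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal((size,) * 3), sigma=sigma)
    mask = field > np.median(field)
    if not mask.any():  # pragma: no cover - median split always leaves voxels
        mask[size // 2, size // 2, size // 2] = True
    return mask


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Build the binary mask for a :class:`PhantomSpec`; deterministic given seed."""
    n = spec.size_or_level
    if spec.kind == "filled_cube":
        return np.ones((n, n, n), dtype=bool)
    if spec.kind == "slab":
        return np.ones((n, n, 1), dtype=bool)
    if spec.kind == "line":
        return np.ones((n, 1, 1), dtype=bool)
    if spec.kind == "menger_sponge":
        return menger_sponge(n)
    return random_blob(n, seed=spec.seed)


def embed_phantom(
    mask: np.ndarray,
    volume_shape: tuple[int, int, int],
    label: int,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelVolume:
    """Place a mask centered in a larger volume, carrying a region label.

    The phantom voxels take ``label`` (1–40); everything else is background,
    so region extraction recovers the original mask exactly.
    """
    if not (0 < label <= MAX_LABEL):
        raise ValueError(f"label must be in 1..{MAX_LABEL}, got {label}")
    mask = np.asarray(mask).astype(bool)
    if any(m > v for m, v in zip(mask.shape, volume_shape)):
        raise ValueError(f"mask shape {mask.shape} does not fit in {volume_shape}")
    data = np.zeros(volume_shape, dtype=np.int16)
    offsets = [(v - m) // 2 for v, m in zip(volume_shape, mask.shape)]
    sl = tuple(slice(o, o + m) for o, m in zip(offsets, mask.shape))
    data[sl][mask] = label
    return LabelVolume(data=data, spacing=spacing)
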