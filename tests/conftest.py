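"""Shared fixtures and the independent region-growing oracle."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from lungburden.phantom import PhantomSpec, TumorSpec, generate_phantom

# neighbor offsets per connectivity, used by the exhaustive BFS oracle
_OFFSETS_6 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if abs(dz) + abs(dy) + abs(dx) == 1
]
_OFFSETS_18 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if 1 <= abs(dz) + abs(dy) + abs(dx) <= 2
]
_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
OFFSETS = {6: _OFFSETS_6, 18: _OFFSETS_18, 26: _OFFSETS_26}


def bfs_region_grow(
    data: np.ndarray,
    seed: tuple[int, int, int],
    tolerance: float,
    connectivity: int = 26,
    voxel_size_um: float = 1.0,
    radius_um: float | None = None,
    domain: np.ndarray | None = None,
) -> np.ndarray:
    """Exhaustive breadth-first flood, re-checking the acceptance rule
    (|gray - gray(seed)| <= tolerance/2, domain, sphere radius) for
    every visited voxel. Deliberately naive: the reference the fast
    implementation is tested against.
    """
    shape = data.shape
    if domain is None:
        domain = np.ones(shape, dtype=bool)
    ref = float(data[seed])

    def accepted(v):
        if not domain[v]:
            return False
        if abs(float(data[v]) - ref) > tolerance / 2.0:
            return False
        if radius_um is not None:
            d2 = sum((a - b) ** 2 for a, b in zip(v, seed)) * voxel_size_um**2
            if d2 > radius_um**2:
                return False
        return True

    mask = np.zeros(shape, dtype=bool)
    if not accepted(seed):
        return mask
    mask[seed] = True
    queue = deque([seed])
    while queue:
        v = queue.popleft()
        for off in OFFSETS[connectivity]:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if not all(0 <= c < s for c, s in zip(w, shape)):
                continue
            if mask[w] or not accepted(w):
                continue
            mask[w] = True
            queue.append(w)
    return mask


@pytest.fixture(scope="session")
def sharp_phantom():
    """Noise-free phantom with one sharp spherical tumor of radius 8."""
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        tumors=[TumorSpec(center=(32, 30, 30), radius=8.0)],
        noise_sigma=0.0,
        rng_seed=1,
    )
    vol, labels = generate_phantom(spec)
    return spec, vol, labels


@pytest.fixture(scope="session")
def halo_phantom():
    """Noise-free phantom whose tumor carries a 2-voxel halo shell with
    the tumor's own gray value (the non-specific-stain condition)."""
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        tumors=[TumorSpec(center=(32, 30, 30), radius=8.0, halo_thickness=2.0)],
        noise_sigma=0.0,
        rng_seed=3,
    )
    vol, labels = generate_phantom(spec)
    return spec, vol, labels


@pytest.fixture(scope="session")
def noisy_phantom():
    """Two-tumor phantom with moderate acquisition noise (sigma = 50)."""
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        tumors=[
            TumorSpec(center=(32, 30, 30), radius=8.0),
            TumorSpec(center=(24, 40, 24), radius=5.0),
        ],
        noise_sigma=50.0,
        rng_seed=2,
    )
    vol, labels = generate_phantom(spec)
    return spec, vol, labels
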