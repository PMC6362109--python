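"""Seeded 3D region growing and organ/airway mask extraction.

The segmentation model mirrors the semi-automated workflow used on
stained-lung micro-CT data: a user (here, a config file) places seeds
inside structures of interest and a flooding algorithm accretes
connected voxels whose gray value stays within half the configured
tolerance of a fixed reference value. The reference is the seed voxel's
own gray value, held constant for the whole growth ("static" rule);
this makes the result order-independent and monotone in the tolerance.
An optional sphere radius (in μm, between voxel centers) confines the
flood — e.g. to keep a tumor growth from leaking into the trachea.

Internally a growth is computed as the connected component, under the
requested 6/18/26 connectivity, of the acceptance set

    {v : |gray(v) - gray(seed)| <= tolerance / 2}  ∩  domain  ∩  sphere

that contains the seed, which is exactly the set a breadth-first flood
would visit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volio import VoxelVolume

__all__ = [
    "Seed",
    "RegionGrowParams",
    "SegmentationResult",
    "region_grow",
    "compute_lung_mask",
    "segment_airways",
    "segment_tumors",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class Seed:
    """A 0-based voxel coordinate (z, y, x)."""

    z: int
    y: int
    x: int

    @property
    def zyx(self) -> tuple[int, int, int]:
        return (self.z, self.y, self.x)


@dataclass(frozen=True)
class RegionGrowParams:
    """Flooding rule parameters.

    tolerance
        Width of the accepted gray-value range; a voxel is accepted when
        its gray value differs from the reference by at most half of it.
    radius_um
        Optional sphere restriction: maximal Euclidean distance (μm)
        between a voxel center and the seed center. ``None`` = unlimited.
    connectivity
        6 (faces), 18 (faces+edges) or 26 (faces+edges+corners).
    reference
        Only ``"seed"`` is defined: the reference gray value is the seed
        voxel's value, fixed for the whole growth.
    """

    tolerance: float
    radius_um: float | None = None
    connectivity: int = 26
    reference: str = "seed"

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError(f"tolerance must be >= 0, got {self.tolerance}")
        if self.radius_um is not None and not self.radius_um > 0:
            raise ValueError(f"radius_um must be positive when set, got {self.radius_um}")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of 6/18/26, got {self.connectivity}")
        if self.reference != "seed":
            raise ValueError(f"unknown reference convention {self.reference!r}")


@dataclass
class SegmentationResult:
    """A boolean mask plus the provenance that produced it."""

    mask: np.ndarray
    seeds: list[Seed]
    params: list[RegionGrowParams]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _check_seed(seed: Seed, shape: tuple[int, int, int], domain: np.ndarray) -> None:
    if not all(0 <= c < s for c, s in zip(seed.zyx, shape)):
        raise ValueError(f"seed {seed.zyx} lies outside the grid of shape {shape}")
    if not domain[seed.zyx]:
        raise ValueError(f"seed {seed.zyx} lies outside the segmentation domain")


def _sphere_about(seed: Seed, shape, voxel_size_um: float, radius_um: float) -> np.ndarray:
    zz, yy, xx = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    d2 = (
        (zz - seed.z) ** 2 + (yy - seed.y) ** 2 + (xx - seed.x) ** 2
    ) * voxel_size_um**2
    return d2 <= radius_um**2


def _grow_one(
    vol: VoxelVolume, seed: Seed, params: RegionGrowParams, domain: np.ndarray
) -> np.ndarray:
    _check_seed(seed, vol.shape, domain)
    ref = float(vol.data[seed.zyx])
    accept = domain & (np.abs(vol.data.astype(np.int64) - ref) <= params.tolerance / 2.0)
    if params.radius_um is not None:
        accept &= _sphere_about(seed, vol.shape, vol.voxel_size_um, params.radius_um)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[params.connectivity])
    labeled, _ = ndimage.label(accept, structure=structure)
    return labeled == labeled[seed.zyx]


def region_grow(
    vol: VoxelVolume,
    seeds: list[Seed] | Seed,
    params: RegionGrowParams | list[RegionGrowParams],
    domain: np.ndarray | None = None,
) -> SegmentationResult:
    """Grow from one or more seeds and union the results.

    Each seed grows independently with its own parameters (a single
    ``RegionGrowParams`` is broadcast to all seeds), so the union does
    not depend on seed order. Every accepted voxel is connected to its
    generating seed through accepted voxels and, when a radius is set,
    lies within that radius of the seed center.
    """
    if isinstance(seeds, Seed):
        seeds = [seeds]
    if isinstance(params, RegionGrowParams):
        params_list = [params] * len(seeds)
    else:
        if len(params) != len(seeds):
            raise ValueError("need one RegionGrowParams per seed")
        params_list = list(params)
    if domain is None:
        domain = np.ones(vol.shape, dtype=bool)
    elif domain.shape != vol.shape:
        raise ValueError("domain mask shape does not match the volume")

    mask = np.zeros(vol.shape, dtype=bool)
    for seed, p in zip(seeds, params_list):
        mask |= _grow_one(vol, seed, p, domain)
    return SegmentationResult(mask=mask, seeds=list(seeds), params=params_list)


def compute_lung_mask(
    vol: VoxelVolume, background_threshold: float, closing_radius: int = 3
) -> np.ndarray:
    """Extract the whole-organ mask from a stained-lung volume.

    Voxels brighter than ``background_threshold`` are closed with a ball
    of ``closing_radius`` voxels, the largest connected component is
    kept, and enclosed holes (air-filled airway lumina) are filled —
    the burden denominator is the entire specimen, lumina included.
    """
    fg = vol.data > background_threshold
    if not fg.any():
        raise ValueError("no specimen found: no voxel exceeds the background threshold")
    if closing_radius > 0:
        zz, yy, xx = np.mgrid[
            -closing_radius : closing_radius + 1,
            -closing_radius : closing_radius + 1,
            -closing_radius : closing_radius + 1,
        ]
        ball = zz**2 + yy**2 + xx**2 <= closing_radius**2
        fg = ndimage.binary_closing(fg, structure=ball)
    labeled, n = ndimage.label(fg, structure=ndimage.generate_binary_structure(3, 3))
    if n == 0:
        raise ValueError("no specimen found: threshold leaves no connected component")
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    mask = labeled == int(np.argmax(counts))
    return ndimage.binary_fill_holes(mask)


def segment_airways(
    vol: VoxelVolume,
    trachea_seed: Seed,
    params: RegionGrowParams,
    lung_mask: np.ndarray,
    air_max_gray: float | None = None,
) -> SegmentationResult:
    """Grow the air-filled airway tree from a trachea seed.

    The flood runs over the organ mask only. A heuristic sanity check
    warns (and proceeds) when the seed's gray value does not look like
    air: above ``air_max_gray`` when given, otherwise above the
    midpoint between the darkest and the median gray inside the organ
    (air-filled lumina sit in the low tail of stained tissue).
    """
    seed_val = float(vol.data[trachea_seed.zyx]) if all(
        0 <= c < s for c, s in zip(trachea_seed.zyx, vol.shape)
    ) else None
    if seed_val is not None:
        if air_max_gray is not None:
            cutoff = air_max_gray
        else:
            organ_vals = vol.data[lung_mask]
            cutoff = 0.5 * (float(organ_vals.min()) + float(np.median(organ_vals)))
        if seed_val > cutoff:
            warnings.warn(
                f"trachea seed gray value {seed_val:.0f} is above the expected air range "
                f"(cutoff {cutoff:.0f}); proceeding anyway",
                stacklevel=2,
            )
    return region_grow(vol, trachea_seed, params, domain=lung_mask)


def segment_tumors(
    vol: VoxelVolume,
    seeds: list[Seed],
    params: RegionGrowParams,
    lung_mask: np.ndarray,
    exclude: list[np.ndarray] | np.ndarray | None = None,
    per_seed_params: list[RegionGrowParams | None] | None = None,
) -> SegmentationResult:
    """Segment tumorous tissue: union of per-seed growths inside the organ.

    Exclusion masks (e.g. the airway tree) restrict the domain *before*
    growth, so a flood cannot tunnel through excluded voxels. Per-seed
    parameter overrides allow different tolerances/radii per lesion;
    provenance records the parameters actually used for every seed.
    An empty seed list yields an empty mask.
    """
    domain = lung_mask.copy()
    if exclude is not None:
        excl_list = [exclude] if isinstance(exclude, np.ndarray) else list(exclude)
        for m in excl_list:
            domain &= ~m
    if not seeds:
        return SegmentationResult(mask=np.zeros(vol.shape, dtype=bool), seeds=[], params=[])
    if per_seed_params is None:
        params_list: list[RegionGrowParams] = [params] * len(seeds)
    else:
        if len(per_seed_params) != len(seeds):
            raise ValueError("per_seed_params must align with seeds")
        params_list = [p if p is not None else params for p in per_seed_params]
    return region_grow(vol, seeds, params_list, domain=domain)
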