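"""Synthetic stained-lung micro-CT phantoms with exact ground truth.

The generator emulates the contrast structure of an iodine-in-ethanol
(I2E) stained, ethanol-immersed *ex vivo* mouse lung as seen by
absorption micro-CT:

* a uniform **ethanol background** surrounding the organ;
* an ellipsoidal **lung** of stained parenchyma;
* a deterministic, recursively bifurcating **airway tree** whose lumina
  are air-dark and whose walls carry the bright stained-wall intensity;
* randomly placed bright **vessel** segments;
* **tumors** — perturbed spheres brighter than parenchyma, with either a
  sharp intensity step or a linear "diffuse" ramp at the boundary;
* optional **halo** shells of abnormal tissue (inflamed/dead tissue)
  around tumors, which by default share the tumor gray value — the
  non-specific-stain mechanism that makes intensity-based segmentation
  overestimate tumor burden;
* additive Gaussian acquisition noise, clipped to the 16-bit range.

Ground truth is returned as a co-registered :class:`~lungburden.volio.LabelVolume`
whose classes partition the grid. Identical spec + seed always yields
bit-identical output.

Absolute gray values per tissue class are free parameters of the model
(micro-CT gray scales are instrument- and reconstruction-dependent);
the defaults below only fix a plausible ordering air < ethanol <
parenchyma < vessel/airway wall < tumor = halo.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volio import (
    GRAY_MAX,
    LABEL_AIRWAY,
    LABEL_BACKGROUND,
    LABEL_HALO,
    LABEL_PARENCHYMA,
    LABEL_TUMOR,
    LABEL_VESSEL,
    LabelVolume,
    VoxelVolume,
    write_labels,
    write_volume,
)

__all__ = [
    "IntensityModel",
    "LungGeometry",
    "AirwayTreeSpec",
    "VesselSpec",
    "TumorSpec",
    "PhantomSpec",
    "generate_phantom",
    "true_burden_percent",
    "random_spec",
    "write_phantom",
]


@dataclass
class IntensityModel:
    """Mean gray value per tissue class, 16-bit scale."""

    background: float = 8000.0
    air: float = 2000.0
    parenchyma: float = 22000.0
    vessel: float = 30000.0
    tumor: float = 40000.0
    halo: float = 40000.0

    def as_label_map(self) -> dict[int, float]:
        return {
            LABEL_BACKGROUND: self.background,
            LABEL_PARENCHYMA: self.parenchyma,
            LABEL_TUMOR: self.tumor,
            LABEL_AIRWAY: self.air,
            LABEL_HALO: self.halo,
            LABEL_VESSEL: self.vessel,
        }


@dataclass
class LungGeometry:
    """Ellipsoidal organ: semi-axes and center, in voxels (z, y, x)."""

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float]

    def contains(self, zyx: np.ndarray | tuple[float, float, float]) -> np.ndarray:
        p = np.asarray(zyx, dtype=float)
        d = (p - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (d * d).sum(axis=-1) <= 1.0


@dataclass
class AirwayTreeSpec:
    """Deterministic recursive bifurcation (reproducibility over realism).

    The trachea enters at ``entry`` (on or near the lung surface) with
    direction ``entry_direction`` and carves an air-filled cylinder;
    each branch spawns two children whose directions alternate between
    the two axes orthogonal to the parent, with length and radius
    multiplied by the decay factors at every level.
    """

    depth: int = 3
    trachea_length: float = 14.0  # voxels
    trachea_radius: float = 2.5  # voxels
    length_decay: float = 0.7
    radius_decay: float = 0.7
    branch_angle_deg: float = 40.0
    entry_cap: float = 2.0  # voxels; the trachea is sutured shut in the prep, so the lumen starts below the surface
    entry: tuple[float, float, float] | None = None  # default: top of ellipsoid, axis 0
    entry_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)


@dataclass
class VesselSpec:
    """Randomly placed bright cylinder segments inside the lung."""

    n_vessels: int = 4
    radius_range: tuple[float, float] = (1.0, 2.0)  # voxels
    length_range: tuple[float, float] = (10.0, 25.0)  # voxels


@dataclass
class TumorSpec:
    """One lesion: a (possibly perturbed) sphere brighter than parenchyma.

    ``shape_irregularity`` in [0, 1] modulates the radial surface with a
    smooth deterministic angular perturbation; ``boundary_sharpness``
    selects a hard intensity step ("sharp") or a linear ramp of width
    ``ramp_width`` voxels ("diffuse"). For diffuse lesions the ground
    truth boundary sits at the 50 % intensity point, i.e. at the nominal
    perturbed radius, which gives an unambiguous truth for bias studies.
    """

    center: tuple[int, int, int]
    radius: float
    shape_irregularity: float = 0.0
    boundary_sharpness: str = "sharp"  # "sharp" | "diffuse"
    ramp_width: float = 3.0  # voxels, used only when diffuse
    halo_thickness: float = 0.0  # voxels; 0 = no halo shell

    def validate(self) -> None:
        if self.radius < 2:
            raise ValueError(f"tumor radius must be >= 2 voxels, got {self.radius}")
        if not 0.0 <= self.shape_irregularity <= 1.0:
            raise ValueError("shape_irregularity must lie in [0, 1]")
        if self.boundary_sharpness not in ("sharp", "diffuse"):
            raise ValueError(f"unknown boundary_sharpness {self.boundary_sharpness!r}")
        if self.boundary_sharpness == "diffuse" and not (0 < self.ramp_width < self.radius):
            raise ValueError("diffuse ramp width must be positive and smaller than the radius")
        if self.halo_thickness < 0:
            raise ValueError("halo_thickness must be >= 0")


@dataclass
class PhantomSpec:
    """Full description of one synthetic stained-lung volume."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = 13.0
    lung_geometry: LungGeometry | None = None  # default: centered ellipsoid, 80 % of grid
    airway_tree: AirwayTreeSpec = field(default_factory=AirwayTreeSpec)
    vessels: VesselSpec = field(default_factory=VesselSpec)
    tumors: list[TumorSpec] = field(default_factory=list)
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    noise_sigma: float = 0.0
    rng_seed: int = 0
    require_well_separated: bool = False

    def resolved_lung(self) -> LungGeometry:
        if self.lung_geometry is not None:
            return self.lung_geometry
        semi = tuple(0.40 * s for s in self.grid_shape)
        center = tuple((s - 1) / 2.0 for s in self.grid_shape)
        return LungGeometry(semi_axes=semi, center=center)  # type: ignore[arg-type]

    def validate(self) -> None:
        if any(s < 32 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be >= (32, 32, 32), got {self.grid_shape}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lung = self.resolved_lung()
        for i, t in enumerate(self.tumors):
            t.validate()
            if not bool(lung.contains(t.center)):
                raise ValueError(
                    f"tumor {i} center {t.center} lies outside the lung ellipsoid "
                    f"(semi-axes {lung.semi_axes}, center {lung.center})"
                )
        if self.require_well_separated:
            means = sorted(self.intensity_model.as_label_map().values())
            gaps = np.diff(means)
            # identical means (e.g. halo == tumor) collapse to one class
            gaps = gaps[gaps > 0]
            if self.noise_sigma > 0 and gaps.size and gaps.min() < 4 * self.noise_sigma:
                raise ValueError(
                    f"well-separated contrast requested but smallest class gap "
                    f"{gaps.min():.0f} < 4 x noise_sigma ({4 * self.noise_sigma:.0f})"
                )


# ---------------------------------------------------------------------------
# geometry rasterization helpers


def _voxel_centers(shape: tuple[int, int, int]):
    return np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]


def _carve_cylinder(
    mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float, flat_start: bool = False
) -> None:
    """Set True for voxels within `radius` of the segment p0-p1 (in-place).

    Ends are spherically capped; ``flat_start`` cuts the cap behind
    ``p0`` (used for the sutured trachea mouth). Operates on a local
    bounding box only, so repeated calls stay cheap.
    """
    lo = np.floor(np.minimum(p0, p1) - radius - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, mask.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]), indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
        inside = dist <= radius
    else:
        t_raw = ((pts - p0) @ d) / seg_len2
        t = np.clip(t_raw, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
        inside = dist <= radius
        if flat_start:
            inside &= t_raw >= 0
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub |= inside


def _rot(axis: int, deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i], m[i, j], m[j, i], m[j, j] = c, -s, s, c
    return m


def _rasterize_airways(spec: PhantomSpec, lung_inside: np.ndarray) -> np.ndarray:
    tree = spec.airway_tree
    lung = spec.resolved_lung()
    if tree.entry is None:
        entry = np.asarray(lung.center, dtype=float)
        entry[0] -= lung.semi_axes[0]  # top of the ellipsoid along the slicing axis
    else:
        entry = np.asarray(tree.entry, dtype=float)
    direction = np.asarray(tree.entry_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    lumen = np.zeros(spec.grid_shape, dtype=bool)

    def grow(p0: np.ndarray, d: np.ndarray, length: float, radius: float, level: int) -> None:
        p1 = p0 + d * length
        _carve_cylinder(lumen, p0, p1, radius, flat_start=(level == 1))
        if level >= tree.depth:
            return
        # children alternate their rotation axis so the tree fills 3D
        axis = 1 + (level % 2)  # rotate about y then x, never about z=flow axis
        for sign in (+1.0, -1.0):
            child_d = _rot(axis, sign * tree.branch_angle_deg) @ d
            child_d /= np.linalg.norm(child_d)
            grow(p1, child_d, length * tree.length_decay, radius * tree.radius_decay, level + 1)

    start = entry + tree.entry_cap * direction
    grow(start, direction, tree.trachea_length - tree.entry_cap, tree.trachea_radius, 1)
    return lumen & lung_inside  # lumina never extend past the organ


def _rasterize_vessels(spec: PhantomSpec, lung_inside: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = spec.vessels
    lung = spec.resolved_lung()
    mask = np.zeros(spec.grid_shape, dtype=bool)
    center = np.asarray(lung.center)
    semi = np.asarray(lung.semi_axes)
    for _ in range(v.n_vessels):
        # rejection-sample a start point well inside the organ
        for _try in range(100):
            p0 = center + (rng.uniform(-0.7, 0.7, size=3)) * semi
            if bool(lung.contains(p0)):
                break
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        length = rng.uniform(*v.length_range)
        radius = rng.uniform(*v.radius_range)
        _carve_cylinder(mask, p0, p0 + d * length, radius)
    return mask & lung_inside


def _tumor_fields(spec: PhantomSpec, rng: np.random.Generator):
    """Per-voxel tumor membership and intensity mixing fraction.

    Returns ``(tumor_mask, tumor_frac)`` where ``tumor_frac`` in [0, 1]
    is the maximal tumor-intensity weight over all lesions (1 inside,
    linear ramp across diffuse boundaries, 0 outside).
    """
    shape = spec.grid_shape
    tumor_mask = np.zeros(shape, dtype=bool)
    tumor_frac = np.zeros(shape, dtype=float)
    for t in spec.tumors:
        # deterministic per-lesion angular perturbation
        n_modes = 6
        dirs = rng.normal(size=(n_modes, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coefs = rng.uniform(-1, 1, size=n_modes)
        coefs /= max(np.abs(coefs).sum(), 1e-12)

        margin = t.radius * (1 + t.shape_irregularity) + (
            t.ramp_width if t.boundary_sharpness == "diffuse" else 0
        ) + 2
        c = np.asarray(t.center, dtype=float)
        lo = np.maximum(np.floor(c - margin).astype(int), 0)
        hi = np.minimum(np.ceil(c + margin).astype(int) + 1, shape)
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]), indexing="ij"
        )
        off = np.stack([zz, yy, xx], axis=-1).astype(float) - c
        dist = np.linalg.norm(off, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(dist[..., None] > 0, off / np.maximum(dist[..., None], 1e-12), 0.0)
        if t.shape_irregularity > 0:
            # smooth even perturbation g(u) in [-1, 1] from a few quadratic modes
            proj = u @ dirs.T  # (..., n_modes)
            g = (coefs * (2 * proj**2 - 1)).sum(axis=-1)
            r_dir = t.radius * (1.0 + t.shape_irregularity * g)
        else:
            r_dir = np.full(dist.shape, t.radius)
        signed = dist - r_dir  # <= 0 inside the lesion
        inside = signed <= 0
        if t.boundary_sharpness == "diffuse":
            frac = np.clip(0.5 - signed / t.ramp_width, 0.0, 1.0)
        else:
            frac = inside.astype(float)
        sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        tumor_mask[sl] |= inside
        np.maximum(tumor_frac[sl], frac, out=tumor_frac[sl])
    return tumor_mask, tumor_frac


def _halo_mask(spec: PhantomSpec, tumor_mask: np.ndarray) -> np.ndarray:
    """Morphological shell around each haloed tumor, clipped later to lung."""
    halo = np.zeros_like(tumor_mask)
    for t in spec.tumors:
        if t.halo_thickness <= 0:
            continue
        sub = np.zeros_like(tumor_mask)
        c = np.asarray(t.center, dtype=float)
        margin = t.radius * (1 + t.shape_irregularity) + t.halo_thickness + 3
        lo = np.maximum(np.floor(c - margin).astype(int), 0)
        hi = np.minimum(np.ceil(c + margin).astype(int) + 1, tumor_mask.shape)
        sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        region = tumor_mask[sl]
        n_iter = int(np.ceil(t.halo_thickness))
        struct = ndimage.generate_binary_structure(3, 3)
        dil = ndimage.binary_dilation(region, structure=struct, iterations=n_iter)
        sub[sl] = dil
        halo |= sub
    return halo & ~tumor_mask


# ---------------------------------------------------------------------------
# public API


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, LabelVolume]:
    """Generate one stained-lung phantom and its exact ground truth.

    The label volume partitions the grid (one class per voxel, tumor
    precedence highest), and the gray volume maps classes to their mean
    intensities, applies diffuse boundary ramps, then adds clipped
    Gaussian noise. Same spec + ``rng_seed`` gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.grid_shape
    lung = spec.resolved_lung()

    zz, yy, xx = _voxel_centers(shape)
    semi = lung.semi_axes
    cen = lung.center
    lung_inside = (
        ((zz - cen[0]) / semi[0]) ** 2
        + ((yy - cen[1]) / semi[1]) ** 2
        + ((xx - cen[2]) / semi[2]) ** 2
    ) <= 1.0

    # draw order fixed so the RNG stream is reproducible
    vessels = _rasterize_vessels(spec, lung_inside, rng)
    tumor_mask, tumor_frac = _tumor_fields(spec, rng)
    airway_lumen = _rasterize_airways(spec, lung_inside)
    halo = _halo_mask(spec, tumor_mask) & lung_inside

    # airway wall: bright stained shell one voxel thick around the lumen
    struct = ndimage.generate_binary_structure(3, 3)
    airway_wall = ndimage.binary_dilation(airway_lumen, structure=struct) & ~airway_lumen & lung_inside

    labels = np.zeros(shape, dtype=np.uint8)
    labels[lung_inside] = LABEL_PARENCHYMA
    labels[vessels] = LABEL_VESSEL
    labels[airway_wall] = LABEL_VESSEL
    labels[halo] = LABEL_HALO
    labels[airway_lumen] = LABEL_AIRWAY
    labels[tumor_mask] = LABEL_TUMOR  # tumor precedence is highest

    im = spec.intensity_model
    lut = np.zeros(256, dtype=float)
    for k, v in im.as_label_map().items():
        lut[k] = v
    gray = lut[labels]

    # diffuse boundaries: blend toward the tumor mean where frac in (0, 1);
    # never across air (lumen) or out of the organ
    blend = (tumor_frac > 0) & (labels != LABEL_AIRWAY) & lung_inside
    gray[blend] = tumor_frac[blend] * im.tumor + (1 - tumor_frac[blend]) * gray[blend]

    if spec.noise_sigma > 0:
        gray = gray + rng.normal(0.0, spec.noise_sigma, size=shape)
    gray = np.clip(np.rint(gray), 0, GRAY_MAX).astype(np.uint16)

    return (
        VoxelVolume(gray, spec.voxel_size_um),
        LabelVolume(labels, spec.voxel_size_um),
    )


def true_burden_percent(labels: LabelVolume, include_lumen: bool = True) -> float:
    """Ground-truth 3D burden: tumor voxels / organ voxels, as percent.

    The organ denominator is every non-background voxel; set
    ``include_lumen=False`` to drop air-filled airway lumina.
    """
    data = labels.data
    organ = data != LABEL_BACKGROUND
    if not include_lumen:
        organ &= data != LABEL_AIRWAY
    n_organ = int(organ.sum())
    if n_organ == 0:
        raise ValueError("label volume contains no organ voxels")
    return 100.0 * float((data == LABEL_TUMOR).sum()) / n_organ


def random_spec(
    rng_seed: int,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    n_tumors: tuple[int, int] = (1, 10),
    radius_range: tuple[float, float] = (3.0, 15.0),
    noise_sigma: float = 0.0,
    halo_thickness: float = 0.0,
    boundary_sharpness: str = "sharp",
    shape_irregularity: float = 0.0,
) -> PhantomSpec:
    """Draw a reproducible random phantom spec from a family.

    Tumor centers are rejection-sampled so each lesion (center plus 60 %
    of its radius) stays inside the lung ellipsoid; overlapping lesions
    are allowed, mirroring merged multifocal tumors.
    """
    rng = np.random.default_rng(rng_seed)
    base = PhantomSpec(grid_shape=grid_shape)
    lung = base.resolved_lung()
    tree = base.airway_tree
    semi = np.asarray(lung.semi_axes)
    cen = np.asarray(lung.center)
    # trachea axis: lesions are kept clear of the main airway entry
    entry = cen.copy()
    entry[0] -= semi[0]
    tdir = np.asarray(tree.entry_direction, dtype=float)
    tdir /= np.linalg.norm(tdir)
    n = int(rng.integers(n_tumors[0], n_tumors[1] + 1))
    tumors: list[TumorSpec] = []
    for _ in range(n):
        radius = float(rng.uniform(*radius_range))
        for _try in range(500):
            p = cen + rng.uniform(-1, 1, size=3) * semi
            d = (p - cen) / semi
            t = np.clip((p - entry) @ tdir, 0.0, tree.trachea_length)
            trachea_dist = np.linalg.norm(p - (entry + t * tdir))
            # keep most of the lesion inside the organ and off the trachea
            if (d * d).sum() <= (1 - 0.6 * radius / semi.min()) ** 2 and trachea_dist > (
                radius * (1 + shape_irregularity) + tree.trachea_radius + halo_thickness + 3
            ):
                break
        ramp = min(3.0, 0.5 * radius) if boundary_sharpness == "diffuse" else 3.0
        tumors.append(
            TumorSpec(
                center=tuple(int(round(v)) for v in p),  # type: ignore[arg-type]
                radius=radius,
                shape_irregularity=shape_irregularity,
                boundary_sharpness=boundary_sharpness,
                ramp_width=ramp,
                halo_thickness=halo_thickness,
            )
        )
    return PhantomSpec(
        grid_shape=grid_shape,
        tumors=tumors,
        noise_sigma=noise_sigma,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and persist a phantom: gray TIFF, label TIFF, spec echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol, labels = generate_phantom(spec)
    spec_echo = asdict(spec)
    paths = {
        "volume": write_volume(vol, out / "volume.tif", extra_meta={"phantom_spec": spec_echo}),
        "labels": write_labels(labels, out / "labels.tif", extra_meta={"phantom_spec": spec_echo}),
    }
    return paths
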