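"""End-to-end runs: config parsing, stage orchestration, provenance.

A run goes scan → segment → quantify: obtain a volume (generate a
phantom or read a TIFF), extract the organ mask, grow the airway tree
from a trachea seed, grow tumors from per-lesion seeds with the airway
mask excluded, then emit the histogram split, the burden report CSV and
a provenance file. All randomness flows from a single top-level seed,
so re-running a config reproduces identical numeric outputs.

Stage failures are surfaced as :class:`PipelineError` carrying the
stage name (e.g. ``segment:tumors``) and the offending parameter.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .phantom import (
    AirwayTreeSpec,
    IntensityModel,
    LungGeometry,
    PhantomSpec,
    TumorSpec,
    VesselSpec,
    generate_phantom,
)
from .quantify import (
    BurdenReport,
    build_report,
    histogram_split,
    write_report_csv,
)
from .segmentation import (
    RegionGrowParams,
    Seed,
    compute_lung_mask,
    region_grow,
    segment_airways,
    segment_tumors,
)
from .volio import LabelVolume, VoxelVolume, read_labels, read_volume, write_labels, write_mask, write_volume

logger = logging.getLogger("lungburden")

__all__ = [
    "PipelineError",
    "SegmentationSettings",
    "RunConfig",
    "run_pipeline",
    "default_demo_config",
    "phantom_spec_from_dict",
    "replicate_report",
]


class PipelineError(RuntimeError):
    """A stage failure with the stage name attached."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class SegmentationSettings:
    """Per-group segmentation parameters for one run.

    Defaults are matched to the phantom's default intensity model: the
    lung threshold sits between ethanol background and parenchyma, the
    airway tolerance accepts air but not stained tissue, and the tumor
    tolerance (half-width 8000 gray values) stays well inside the
    tumor–parenchyma gap.
    """

    lung_background_threshold: float = 15000.0
    lung_closing_radius: int = 3
    airway_params: RegionGrowParams = field(
        default_factory=lambda: RegionGrowParams(tolerance=16000.0)
    )
    tumor_params: RegionGrowParams = field(
        default_factory=lambda: RegionGrowParams(tolerance=16000.0)
    )
    exclude_airways: bool = True
    #: confine each phantom-seeded growth to a sphere just covering its
    #: lesion (the tool's radius restriction, as an operator would set it)
    confine_to_lesion: bool = True
    confine_margin_voxels: float = 2.0


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    rng_seed: int = 0
    sample: str = "sample"
    phantom: PhantomSpec | None = None
    volume_path: str | None = None
    labels_path: str | None = None
    voxel_size_um: float | None = None  # override when no sidecar exists
    settings: SegmentationSettings = field(default_factory=SegmentationSettings)
    trachea_seed: tuple[int, int, int] | None = None  # default: derived from phantom
    tumor_seeds: list[tuple[int, int, int]] | None = None  # default: phantom tumor centers
    slice_axis: int = 0
    slice_index: int | None = None  # None = central slice
    include_lumen: bool = True
    histogram_bins: int = 64
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.phantom is None and self.volume_path is None:
            raise PipelineError("config", "either a phantom spec or an input volume is required")
        if self.volume_path is not None and not Path(self.volume_path).exists():
            raise PipelineError("config", f"input volume {self.volume_path} does not exist")
        if self.labels_path is not None and not Path(self.labels_path).exists():
            raise PipelineError("config", f"label volume {self.labels_path} does not exist")
        if self.phantom is None and self.tumor_seeds is None:
            raise PipelineError("config", "tumor seeds are required when no phantom spec is given")


# ---------------------------------------------------------------------------
# config parsing


def _params_from_dict(d: dict) -> RegionGrowParams:
    return RegionGrowParams(
        tolerance=float(d["tolerance"]),
        radius_um=float(d["radius_um"]) if d.get("radius_um") is not None else None,
        connectivity=int(d.get("connectivity", 26)),
        reference=d.get("reference", "seed"),
    )


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a plain config mapping."""
    kwargs: dict = {}
    if "grid_shape" in d:
        kwargs["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
    for scalar in ("voxel_size_um", "noise_sigma", "rng_seed", "require_well_separated"):
        if scalar in d:
            kwargs[scalar] = d[scalar]
    if d.get("lung_geometry"):
        g = d["lung_geometry"]
        kwargs["lung_geometry"] = LungGeometry(
            semi_axes=tuple(float(v) for v in g["semi_axes"]),
            center=tuple(float(v) for v in g["center"]),
        )
    if d.get("airway_tree"):
        kwargs["airway_tree"] = AirwayTreeSpec(**d["airway_tree"])
    if d.get("vessels"):
        v = d["vessels"]
        kwargs["vessels"] = VesselSpec(
            n_vessels=int(v.get("n_vessels", 4)),
            radius_range=tuple(v.get("radius_range", (1.0, 2.0))),
            length_range=tuple(v.get("length_range", (10.0, 25.0))),
        )
    if d.get("intensity_model"):
        kwargs["intensity_model"] = IntensityModel(**d["intensity_model"])
    tumors = []
    for t in d.get("tumors", []):
        tumors.append(
            TumorSpec(
                center=tuple(int(v) for v in t["center"]),
                radius=float(t["radius"]),
                shape_irregularity=float(t.get("shape_irregularity", 0.0)),
                boundary_sharpness=t.get("boundary_sharpness", "sharp"),
                ramp_width=float(t.get("ramp_width", 3.0)),
                halo_thickness=float(t.get("halo_thickness", 0.0)),
            )
        )
    kwargs["tumors"] = tumors
    return PhantomSpec(**kwargs)


def config_from_dict(d: dict) -> RunConfig:
    settings = SegmentationSettings()
    seg = d.get("segmentation", {})
    if "lung" in seg:
        settings.lung_background_threshold = float(
            seg["lung"].get("background_threshold", settings.lung_background_threshold)
        )
        settings.lung_closing_radius = int(
            seg["lung"].get("closing_radius", settings.lung_closing_radius)
        )
    if "airways" in seg:
        settings.airway_params = _params_from_dict(seg["airways"])
    if "tumors" in seg:
        settings.tumor_params = _params_from_dict(seg["tumors"])
        settings.exclude_airways = bool(seg["tumors"].get("exclude_airways", True))

    slice_cfg = d.get("slice", {})
    slice_index = slice_cfg.get("index")
    if slice_index == "central":
        slice_index = None

    return RunConfig(
        rng_seed=int(d.get("rng_seed", 0)),
        sample=str(d.get("sample", "sample")),
        phantom=phantom_spec_from_dict(d["phantom"]) if d.get("phantom") else None,
        volume_path=d.get("volume"),
        labels_path=d.get("labels"),
        voxel_size_um=d.get("voxel_size_um"),
        settings=settings,
        trachea_seed=tuple(seg["airways"]["seed"]) if seg.get("airways", {}).get("seed") else None,
        tumor_seeds=[tuple(s) for s in seg.get("tumors", {}).get("seeds", [])] or None,
        slice_axis=int(slice_cfg.get("axis", 0)),
        slice_index=None if slice_index is None else int(slice_index),
        include_lumen=bool(d.get("include_lumen", True)),
        histogram_bins=int(d.get("histogram_bins", 64)),
        log_level=str(d.get("log_level", "INFO")),
    )


def config_from_yaml(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def default_demo_config(rng_seed: int = 0) -> RunConfig:
    """A self-contained demonstration run on a haloed three-tumor phantom."""
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size_um=13.0,
        tumors=[
            TumorSpec(center=(32, 30, 30), radius=10.0, shape_irregularity=0.2, halo_thickness=2.0),
            TumorSpec(center=(24, 40, 24), radius=6.0, halo_thickness=2.0),
            TumorSpec(center=(42, 26, 40), radius=5.0, halo_thickness=2.0),
        ],
        noise_sigma=500.0,
        rng_seed=rng_seed,
    )
    return RunConfig(rng_seed=rng_seed, sample="demo", phantom=spec)


# ---------------------------------------------------------------------------
# seed derivation and the run itself


def default_trachea_seed(spec: PhantomSpec, depth_voxels: float = 4.0) -> tuple[int, int, int]:
    """A point a few voxels down the trachea from its entry."""
    tree = spec.airway_tree
    lung = spec.resolved_lung()
    if tree.entry is None:
        entry = np.asarray(lung.center, dtype=float)
        entry[0] -= lung.semi_axes[0]
    else:
        entry = np.asarray(tree.entry, dtype=float)
    d = np.asarray(tree.entry_direction, dtype=float)
    d /= np.linalg.norm(d)
    p = entry + depth_voxels * d
    return tuple(int(round(v)) for v in p)  # type: ignore[return-value]


def _per_seed_params(spec: PhantomSpec, settings: SegmentationSettings) -> list[RegionGrowParams] | None:
    """Sphere-restricted per-lesion parameters for phantom-derived seeds.

    The growth sphere covers the lesion's maximal radial extent plus its
    halo shell, half the diffuse ramp, and a small margin — mirroring an
    operator who sets the tool's radius just around the lesion at hand.
    """
    if not settings.confine_to_lesion:
        return None
    out = []
    for t in spec.tumors:
        r_vox = t.radius * (1 + t.shape_irregularity) + t.halo_thickness + settings.confine_margin_voxels
        if t.boundary_sharpness == "diffuse":
            r_vox += t.ramp_width / 2
        out.append(dataclasses.replace(settings.tumor_params, radius_um=r_vox * spec.voxel_size_um))
    return out


def _resolve_seeds(cfg: RunConfig) -> tuple[tuple[int, int, int], list[tuple[int, int, int]]]:
    trachea = cfg.trachea_seed
    tumors = cfg.tumor_seeds
    if cfg.phantom is not None:
        if trachea is None:
            trachea = default_trachea_seed(cfg.phantom)
        if tumors is None:
            tumors = [tuple(int(c) for c in t.center) for t in cfg.phantom.tumors]
    return trachea, tumors or []  # type: ignore[return-value]


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute one full run; returns artifact paths and the report."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    masks_dir = out / "masks"

    # --- stage: input -----------------------------------------------------
    labels: LabelVolume | None = None
    if cfg.phantom is not None:
        try:
            vol, labels = generate_phantom(cfg.phantom)
        except ValueError as e:
            raise PipelineError("phantom", str(e)) from e
        write_volume(vol, out / "volume.tif")
        write_labels(labels, out / "labels.tif")
    else:
        try:
            vol = read_volume(cfg.volume_path, voxel_size_um=cfg.voxel_size_um)
            if cfg.labels_path:
                labels = read_labels(cfg.labels_path, voxel_size_um=cfg.voxel_size_um)
        except (ValueError, FileNotFoundError) as e:
            raise PipelineError("input", str(e)) from e
    logger.info("input: volume %s, %.1f um voxels", vol.shape, vol.voxel_size_um)

    # --- stage: segment:lung ----------------------------------------------
    s = cfg.settings
    try:
        lung_mask = compute_lung_mask(vol, s.lung_background_threshold, s.lung_closing_radius)
    except ValueError as e:
        raise PipelineError("segment:lung", str(e)) from e
    logger.info("segment:lung: %d voxels", int(lung_mask.sum()))

    # --- stage: segment:airways -------------------------------------------
    trachea, tumor_seed_list = _resolve_seeds(cfg)
    airway_mask = np.zeros(vol.shape, dtype=bool)
    if trachea is not None:
        seed = Seed(*trachea)
        if not all(0 <= c < n for c, n in zip(seed.zyx, vol.shape)) or not lung_mask[seed.zyx]:
            raise PipelineError(
                "segment:airways",
                f"seed group 'airways': trachea seed {seed.zyx} lies outside the lung mask",
            )
        airway_mask = segment_airways(vol, seed, s.airway_params, lung_mask).mask
    logger.info("segment:airways: %d voxels", int(airway_mask.sum()))

    # --- stage: segment:tumors --------------------------------------------
    tumor_seeds = [Seed(*t) for t in tumor_seed_list]
    for seed in tumor_seeds:
        if not all(0 <= c < n for c, n in zip(seed.zyx, vol.shape)) or not lung_mask[seed.zyx]:
            raise PipelineError(
                "segment:tumors",
                f"seed group 'tumors': seed {seed.zyx} lies outside the lung mask",
            )
    per_seed = (
        _per_seed_params(cfg.phantom, s)
        if (cfg.phantom is not None and cfg.tumor_seeds is None)
        else None
    )
    tumor_result = segment_tumors(
        vol,
        tumor_seeds,
        s.tumor_params,
        lung_mask,
        exclude=airway_mask if s.exclude_airways else None,
        per_seed_params=per_seed,
    )
    logger.info("segment:tumors: %d voxels from %d seeds", tumor_result.voxel_count, len(tumor_seeds))

    write_mask(lung_mask, masks_dir / "lung.tif", vol.voxel_size_um)
    write_mask(airway_mask, masks_dir / "airways.tif", vol.voxel_size_um)
    write_mask(tumor_result.mask, masks_dir / "tumors.tif", vol.voxel_size_um)

    # --- stage: quantify ---------------------------------------------------
    slice_index = cfg.slice_index
    if slice_index is None:
        slice_index = vol.shape[cfg.slice_axis] // 2
    try:
        hist = histogram_split(vol, lung_mask, tumor_result.mask, cfg.histogram_bins)
        report = build_report(
            tumor_result.mask,
            lung_mask,
            labels=labels,
            slice_axis=cfg.slice_axis,
            slice_index=slice_index,
            sample=cfg.sample,
            include_lumen=cfg.include_lumen,
        )
    except ValueError as e:
        raise PipelineError("quantify", str(e)) from e
    hist.to_frame().to_csv(out / "histogram.csv", index=False, lineterminator="\n")
    report_path = write_report_csv([report], out / "report.csv")
    logger.info(
        "quantify: 3D burden %.2f %%, slice %d burden %.2f %%",
        report.burden_3d_microct_percent,
        slice_index,
        report.burden_2d_microct_percent,
    )

    # --- provenance ---------------------------------------------------------
    prov = {
        "software": {"name": "lungburden", "version": __version__},
        "rng_seed": cfg.rng_seed,
        "config": _plain(asdict(cfg)),
        "voxel_counts": {
            "lung": int(lung_mask.sum()),
            "airways": int(airway_mask.sum()),
            "tumors": tumor_result.voxel_count,
        },
    }
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)

    return {
        "out_dir": out,
        "report": report,
        "report_csv": report_path,
        "histogram": hist,
        "lung_mask": lung_mask,
        "airway_mask": airway_mask,
        "tumor_mask": tumor_result.mask,
        "volume": vol,
        "labels": labels,
    }


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def replicate_report(
    spec: PhantomSpec,
    settings: SegmentationSettings | None = None,
    slice_rule: str = "central",
    rng_seed: int = 0,
    include_lumen: bool = True,
) -> BurdenReport:
    """Run generation + segmentation + reporting in memory for one phantom.

    ``slice_rule`` selects the virtual slice for the 2D columns:
    "central" (middle slice along axis 0) or "random" (uniform over
    slices that contain lung tissue, drawn from ``rng_seed``).
    """
    settings = settings or SegmentationSettings()
    vol, labels = generate_phantom(spec)
    lung_mask = compute_lung_mask(vol, settings.lung_background_threshold, settings.lung_closing_radius)
    trachea = Seed(*default_trachea_seed(spec))
    airway_mask = (
        segment_airways(vol, trachea, settings.airway_params, lung_mask).mask
        if lung_mask[trachea.zyx]
        else np.zeros(vol.shape, dtype=bool)
    )
    seeds = [Seed(*(int(c) for c in t.center)) for t in spec.tumors]
    result = segment_tumors(
        vol, seeds, settings.tumor_params, lung_mask,
        exclude=airway_mask if settings.exclude_airways else None,
        per_seed_params=_per_seed_params(spec, settings),
    )
    lung_slices = np.flatnonzero(lung_mask.any(axis=(1, 2)))
    if slice_rule == "central":
        slice_index = int(lung_slices[len(lung_slices) // 2])
    elif slice_rule == "random":
        rng = np.random.default_rng(rng_seed)
        slice_index = int(rng.choice(lung_slices))
    else:
        raise ValueError(f"unknown slice rule {slice_rule!r}")
    return build_report(
        result.mask,
        lung_mask,
        labels=labels,
        slice_axis=0,
        slice_index=slice_index,
        include_lumen=include_lumen,
    )
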