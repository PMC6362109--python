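"""Volume and mask I/O for reconstructed micro-CT data.

Everything in the package works on a single in-memory contract: a 3D
array in ``(z, y, x)`` axis order with unsigned 16-bit gray semantics,
plus the physical voxel edge length in micrometers. On disk a volume is
a multi-page TIFF (one page per z-slice) or a directory of per-slice
TIFF files in ascending numeric filename order, accompanied by a YAML
sidecar that carries the voxel size and provenance. TIFF tags are
deliberately not relied on for metadata — the sidecar is authoritative,
which keeps files portable across TIFF writers.

Boolean masks are stored as 8-bit TIFFs with values {0, 255}; integer
label volumes (ground-truth tissue classes for phantoms) as plain 8-bit
TIFFs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "VoxelVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
]

GRAY_MAX = 65535

#: integer tissue classes used by label volumes
LABEL_BACKGROUND = 0
LABEL_PARENCHYMA = 1
LABEL_TUMOR = 2
LABEL_AIRWAY = 3
LABEL_HALO = 4
LABEL_VESSEL = 5

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_PARENCHYMA: "parenchyma",
    LABEL_TUMOR: "tumor",
    LABEL_AIRWAY: "airway_lumen",
    LABEL_HALO: "halo",
    LABEL_VESSEL: "vessel_wall",
}


@dataclass
class VoxelVolume:
    """A reconstructed gray-value volume.

    Parameters
    ----------
    data
        3D array, axis order ``(z, y, x)``; values must fit unsigned
        16-bit range ``[0, 65535]``. Stored as ``uint16``.
    voxel_size_um
        Isotropic voxel edge length in micrometers (typically 12–13 μm
        for the stained-lung scans this package targets).
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"volume must have three non-degenerate axes, got shape {arr.shape}")
        if arr.dtype != np.uint16:
            if arr.size and (arr.min() < 0 or arr.max() > GRAY_MAX):
                raise ValueError("gray values outside the 16-bit range [0, 65535]")
            arr = arr.astype(np.uint16)
        if not (self.voxel_size_um > 0):
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """Co-registered integer ground-truth tissue classes for phantoms.

    Labels: 0 background, 1 parenchyma, 2 tumor, 3 airway lumen,
    4 halo/abnormal tissue, 5 vessel/airway wall. Every voxel carries
    exactly one label, so per-class counts partition the grid.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {arr.shape}")
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise ValueError("labels must fit 8-bit range")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def class_counts(self) -> dict[int, int]:
        counts = np.bincount(self.data.ravel(), minlength=6)
        return {k: int(counts[k]) for k in range(len(counts)) if counts[k]}


# ---------------------------------------------------------------------------
# sidecar metadata


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "volume.meta.yaml"
    return path.with_name(path.stem + ".meta.yaml")


def _plainify(obj):
    """Recursively coerce to YAML-safe plain Python types."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _write_sidecar(path: Path, voxel_size_um: float, extra: dict | None = None) -> None:
    meta = {"voxel_size_um": float(voxel_size_um)}
    if extra:
        meta.update(extra)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(_plainify(meta), fh, sort_keys=True)


def _read_sidecar(path: Path) -> dict | None:
    sc = _sidecar_path(path)
    if not sc.exists():
        return None
    with open(sc) as fh:
        return yaml.safe_load(fh)


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(p: Path) -> tuple:
    """Sort key: embedded integers compare numerically, text lexically."""
    parts = _NUM_RE.split(p.name)
    return tuple(int(s) if s.isdigit() else s for s in parts)


def _stack_slices(paths: list[Path]) -> np.ndarray:
    slices = []
    shape = None
    for p in paths:
        page = tifffile.imread(p)
        if page.ndim != 2:
            raise ValueError(f"slice file {p} is not a single 2D image")
        if shape is None:
            shape = page.shape
        elif page.shape != shape:
            raise ValueError(
                f"mixed slice shapes: {p} has shape {page.shape}, expected {shape}"
            )
        slices.append(page)
    return np.stack(slices, axis=0)


def _read_raw(path: str | Path) -> tuple[np.ndarray, dict | None]:
    path = Path(path)
    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")],
            key=_numeric_key,
        )
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in directory {path}")
        arr = _stack_slices(files)
    else:
        if not path.exists():
            raise FileNotFoundError(str(path))
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a 2D/3D TIFF, got {arr.ndim} dims")
    return arr, _read_sidecar(path)


# ---------------------------------------------------------------------------
# public API


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> VoxelVolume:
    """Read a gray-value volume from a multi-page TIFF or slice directory.

    Slice order follows page order for a multi-page file, ascending
    numeric filename order for a directory. The voxel size is taken
    from the YAML sidecar; if no sidecar exists ``voxel_size_um`` must
    be given explicitly.
    """
    arr, meta = _read_raw(path)
    if voxel_size_um is None:
        if meta is None or "voxel_size_um" not in meta:
            raise ValueError(
                f"no voxel size: {path} has no metadata sidecar and no voxel_size_um override was given"
            )
        voxel_size_um = float(meta["voxel_size_um"])
    return VoxelVolume(arr, voxel_size_um)


def write_volume(vol: VoxelVolume, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a volume as a 16-bit multi-page TIFF plus metadata sidecar.

    The round trip ``read_volume(write_volume(v))`` is the identity.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol.data, photometric="minisblack")
    _write_sidecar(path, vol.voxel_size_um, extra_meta)
    return path


def write_mask(mask: np.ndarray, path: str | Path, voxel_size_um: float | None = None) -> Path:
    """Write a boolean mask as an 8-bit TIFF with values {0, 255}."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError(f"mask must be boolean, got dtype {mask.dtype}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.where(mask, 255, 0).astype(np.uint8), photometric="minisblack")
    if voxel_size_um is not None:
        _write_sidecar(path, voxel_size_um)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a boolean mask; values other than {0, 255} are rejected."""
    arr, _ = _read_raw(path)
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise ValueError(f"{path}: mask contains values other than 0/255: {bad.tolist()}")
    return arr == 255


def write_labels(labels: LabelVolume, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a label volume as an 8-bit multi-page TIFF plus sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.data, photometric="minisblack")
    _write_sidecar(path, labels.voxel_size_um, extra_meta)
    return path


def read_labels(path: str | Path, voxel_size_um: float | None = None) -> LabelVolume:
    """Read an 8-bit label volume written by :func:`write_labels`."""
    arr, meta = _read_raw(path)
    if voxel_size_um is None:
        if meta is None or "voxel_size_um" not in meta:
            raise ValueError(
                f"no voxel size: {path} has no metadata sidecar and no voxel_size_um override was given"
            )
        voxel_size_um = float(meta["voxel_size_um"])
    return LabelVolume(arr, voxel_size_um)
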