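"""Burden quantification: histogram split, 3D and 2D burden, bias study.

Tumor burden is the fraction of the organ occupied by tumorous tissue —
a voxel volume fraction in 3D, a pixel area fraction on one slice in
2D. This module turns masks into those numbers and assembles the
three-method comparison a validation study reports per sample:

1. a *histology surrogate* — ground-truth tumor area fraction on one
   slice, standing in for a pathologist's 2D assessment (it counts only
   true tumor, never halo/abnormal tissue, because a pathologist
   excludes inflamed or dead tissue from the tumor contour);
2. the segmentation-based area fraction on the same virtual slice;
3. the segmentation-based 3D volume fraction.

For phantoms with ground truth the report also carries the true 3D
burden and signed errors, and :func:`bias_study` replicates the whole
pipeline over a phantom family to measure the systematic behavior of
the 3D estimator (e.g. halo-driven overestimation) and of single-slice
2D estimates against the true 3D burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .volio import (
    LABEL_AIRWAY,
    LABEL_BACKGROUND,
    LABEL_TUMOR,
    LabelVolume,
    VoxelVolume,
)

__all__ = [
    "HistogramSplit",
    "BurdenReport",
    "volume_fraction",
    "histogram_split",
    "slice_burden",
    "build_report",
    "reports_to_frame",
    "write_report_csv",
    "bias_study",
    "REPORT_METHOD_COLUMNS",
]

#: the three method columns of the per-sample comparison table
REPORT_METHOD_COLUMNS = (
    "H&E histological slice",
    "micro-CT virtual slice",
    "micro-CT volumetric image",
)


def volume_fraction(part: np.ndarray, whole: np.ndarray) -> float:
    """Percentage of `whole` voxels covered by `part` (intersected first)."""
    n_whole = int(whole.sum())
    if n_whole == 0:
        raise ValueError("empty reference mask: cannot compute a volume fraction")
    return 100.0 * int((part & whole).sum()) / n_whole


@dataclass
class HistogramSplit:
    """Aligned gray-value histograms of the whole organ and a segmented part."""

    bin_edges: np.ndarray
    counts_total: np.ndarray
    counts_segmented: np.ndarray

    @property
    def segmented_fraction_percent(self) -> float:
        return 100.0 * float(self.counts_segmented.sum()) / float(self.counts_total.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "counts_total": self.counts_total,
                "counts_segmented": self.counts_segmented,
            }
        )


def histogram_split(
    vol: VoxelVolume, whole: np.ndarray, part: np.ndarray, n_bins: int = 64
) -> HistogramSplit:
    """Gray-value distribution of the organ with the segmented part overlaid.

    Both histograms share bin edges spanning the gray range observed
    inside ``whole``; the part is intersected with the whole first, so
    the segmented fraction equals :func:`volume_fraction` exactly.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not whole.any():
        raise ValueError("empty reference mask: cannot build a histogram")
    part = part & whole
    vals_whole = vol.data[whole]
    lo, hi = float(vals_whole.min()), float(vals_whole.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    counts_total, _ = np.histogram(vals_whole, bins=edges)
    counts_seg, _ = np.histogram(vol.data[part], bins=edges)
    return HistogramSplit(bin_edges=edges, counts_total=counts_total, counts_segmented=counts_seg)


def slice_burden(part: np.ndarray, whole: np.ndarray, axis: int = 0, index: int = 0) -> float:
    """Area-fraction burden on one virtual slice, as percent."""
    if not 0 <= axis < part.ndim:
        raise ValueError(f"axis {axis} out of range")
    if not 0 <= index < part.shape[axis]:
        raise ValueError(f"slice index {index} outside axis {axis} extent {part.shape[axis]}")
    sl_part = np.take(part, index, axis=axis)
    sl_whole = np.take(whole, index, axis=axis)
    n_whole = int(sl_whole.sum())
    if n_whole == 0:
        raise ValueError(f"no lung tissue in slice {index} along axis {axis}")
    return 100.0 * int((sl_part & sl_whole).sum()) / n_whole


@dataclass
class BurdenReport:
    """One sample's burden numbers across the three estimation methods.

    ``burden_2d_truth_percent`` is the histology surrogate (ground-truth
    tumor label on the chosen slice); it is ``nan`` when no labels are
    available. Signed errors are estimate − truth.
    """

    sample: str
    burden_2d_truth_percent: float
    burden_2d_microct_percent: float
    burden_3d_microct_percent: float
    slice_axis: int
    slice_index: int
    true_3d_percent: float = float("nan")
    error_2d_percent: float = float("nan")
    error_3d_percent: float = float("nan")


def _organ_from_labels(labels: LabelVolume, include_lumen: bool = True) -> np.ndarray:
    organ = labels.data != LABEL_BACKGROUND
    if not include_lumen:
        organ &= labels.data != LABEL_AIRWAY
    return organ


def build_report(
    tumor_mask: np.ndarray,
    lung_mask: np.ndarray,
    labels: LabelVolume | None = None,
    slice_axis: int = 0,
    slice_index: int | None = None,
    sample: str = "sample",
    include_lumen: bool = True,
) -> BurdenReport:
    """Assemble the three-method burden comparison for one sample.

    The 2D columns require a slice selection; the histology-surrogate
    column and the error columns require ground-truth labels (phantom
    runs). The surrogate counts only the tumor label — halo/abnormal
    tissue is excluded, as a pathologist would exclude it.
    """
    if slice_index is None:
        raise ValueError("slice selection missing: 2D burden columns need slice_index")
    burden_3d = volume_fraction(tumor_mask, lung_mask)
    burden_2d = slice_burden(tumor_mask, lung_mask, axis=slice_axis, index=slice_index)
    truth_2d = float("nan")
    true_3d = float("nan")
    err2 = err3 = float("nan")
    if labels is not None:
        organ = _organ_from_labels(labels, include_lumen)
        tumor_true = labels.data == LABEL_TUMOR
        truth_2d = slice_burden(tumor_true, organ, axis=slice_axis, index=slice_index)
        true_3d = volume_fraction(tumor_true, organ)
        err3 = burden_3d - true_3d
        err2 = burden_2d - true_3d
    return BurdenReport(
        sample=sample,
        burden_2d_truth_percent=truth_2d,
        burden_2d_microct_percent=burden_2d,
        burden_3d_microct_percent=burden_3d,
        slice_axis=slice_axis,
        slice_index=slice_index,
        true_3d_percent=true_3d,
        error_2d_percent=err2,
        error_3d_percent=err3,
    )


def reports_to_frame(reports: list[BurdenReport]) -> pd.DataFrame:
    """Tabulate reports with the three fixed method columns."""
    rows = []
    for r in reports:
        rows.append(
            {
                "sample": r.sample,
                REPORT_METHOD_COLUMNS[0]: r.burden_2d_truth_percent,
                REPORT_METHOD_COLUMNS[1]: r.burden_2d_microct_percent,
                REPORT_METHOD_COLUMNS[2]: r.burden_3d_microct_percent,
                "slice_axis": r.slice_axis,
                "slice_index": r.slice_index,
                "true_3d_percent": r.true_3d_percent,
                "error_2d_percent": r.error_2d_percent,
                "error_3d_percent": r.error_3d_percent,
            }
        )
    return pd.DataFrame(rows)


def write_report_csv(reports: list[BurdenReport], path: str | Path) -> Path:
    """Write the comparison table; percentages rounded to one decimal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = reports_to_frame(reports)
    pct_cols = [c for c in df.columns if c.endswith("percent") or c in REPORT_METHOD_COLUMNS]
    df[pct_cols] = df[pct_cols].round(1)
    df.to_csv(path, index=False, float_format="%.1f", lineterminator="\n")
    return path


def plot_histogram_split(hist: HistogramSplit, ax=None, log: bool = True):
    """Plot whole-organ vs segmented-part gray-value distributions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    width = np.diff(hist.bin_edges)
    ax.bar(centers, hist.counts_total, width=width, color="0.7", label="whole organ")
    ax.bar(centers, hist.counts_segmented, width=width, color="tab:pink", label="segmented tumors")
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("gray value")
    ax.set_ylabel("voxel count")
    ax.legend()
    ax.set_title(f"segmented part: {hist.segmented_fraction_percent:.1f} % of organ volume")
    return ax


def bias_study(
    family: Callable[[int], "object"],
    run_replicate: Callable[["object", int], BurdenReport],
    n_replicates: int,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate the pipeline over a phantom family and summarize errors.

    ``family(seed)`` builds one phantom spec; ``run_replicate(spec, seed)``
    runs generation + segmentation + reporting and returns the replicate's
    :class:`BurdenReport`. Per-replicate seeds are drawn deterministically
    from ``rng_seed``. Returns the per-replicate table and an aggregate
    with mean signed error and dispersion for the 3D estimator (vs truth)
    and the single-slice 2D estimate (vs true 3D burden).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(rng_seed)
    reps: list[BurdenReport] = []
    for i in range(n_replicates):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = family(sub_seed)
        rep = run_replicate(spec, sub_seed)
        rep.sample = f"replicate_{i}"
        reps.append(rep)
    df = reports_to_frame(reps)
    summary = pd.DataFrame(
        {
            "estimator": ["3d_microct", "2d_single_slice"],
            "mean_signed_error_pp": [
                df["error_3d_percent"].mean(),
                df["error_2d_percent"].mean(),
            ],
            "sd_error_pp": [df["error_3d_percent"].std(), df["error_2d_percent"].std()],
            "mean_abs_error_pp": [
                df["error_3d_percent"].abs().mean(),
                df["error_2d_percent"].abs().mean(),
            ],
            "n": [len(df)] * 2,
        }
    )
    return df, summary
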