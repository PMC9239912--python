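"""Parcellated BOLD time-series extraction, Pearson functional connectivity
and functional quality metrics (tSNR, framewise displacement, FC summaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .grid import BinaryMask, LabelVolume, ParcellationTable, VoxelGrid, _require_same_grid

__all__ = [
    "BOLDSeries",
    "ROITimeSeriesMatrix",
    "FCMatrix",
    "extract_roi_timeseries",
    "pearson_fc",
    "tsnr",
    "framewise_displacement",
    "fc_summaries",
    "read_motion_params",
]


@dataclass(frozen=True)
class BOLDSeries:
    """4D BOLD volume (x, y, z, t) on a voxel grid."""

    grid: VoxelGrid
    data: np.ndarray
    repetition_time: float = 1.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4 or data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"BOLD shape {data.shape} incompatible with grid {self.grid.shape}"
            )
        if data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 timepoints")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class ROITimeSeriesMatrix:
    """T x N matrix of ROI-mean BOLD; invalid (empty) ROIs are NaN columns."""

    values: np.ndarray
    roi_indices: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        roi_indices = np.asarray(self.roi_indices, dtype=int)
        valid = np.asarray(self.valid, dtype=bool)
        if values.ndim != 2 or values.shape[1] != roi_indices.size != valid.size:
            raise ValueError("inconsistent ROI time-series dimensions")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "roi_indices", roi_indices)
        object.__setattr__(self, "valid", valid)

    def to_frame(self, names: list[str] | None = None) -> pd.DataFrame:
        cols = names if names is not None else [str(i) for i in self.roi_indices]
        return pd.DataFrame(self.values, columns=cols)


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric N x N Pearson correlation matrix; NaN marks missing pairs."""

    values: np.ndarray
    roi_indices: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("FC matrix must be square")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "roi_indices", np.asarray(self.roi_indices, dtype=int)
        )


def extract_roi_timeseries(
    bold: BOLDSeries, labeled: LabelVolume, table: ParcellationTable
) -> ROITimeSeriesMatrix:
    """Unweighted voxel-mean BOLD per ROI, columns in table order.

    ROIs with no voxels in the label volume become invalid NaN columns so the
    matrix keeps the full parcellation dimension.
    """
    _require_same_grid(bold, labeled)
    T = bold.n_timepoints
    n = table.n_rois
    values = np.full((T, n), np.nan)
    valid = np.zeros(n, dtype=bool)
    flat = bold.data.reshape(-1, T)
    labels_flat = labeled.data.ravel()
    for k, idx in enumerate(table.indices):
        sel = labels_flat == idx
        if sel.any():
            values[:, k] = flat[sel].mean(axis=0)
            valid[k] = True
    return ROITimeSeriesMatrix(values, table.indices.copy(), valid)


def pearson_fc(ts: ROITimeSeriesMatrix) -> FCMatrix:
    """Pearson correlation between all ROI time series.

    Pairs involving an invalid or zero-variance column are NaN; the diagonal
    is 1 for valid, non-constant ROIs.
    """
    T, n = ts.values.shape
    if T < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    usable = ts.valid & (np.nanstd(ts.values, axis=0) > 0)
    fc = np.full((n, n), np.nan)
    if usable.sum() >= 1:
        sub = ts.values[:, usable]
        r = np.corrcoef(sub, rowvar=False)
        r = np.atleast_2d(r)
        r = np.clip(r, -1.0, 1.0)
        idx = np.where(usable)[0]
        fc[np.ix_(idx, idx)] = r
        fc[idx, idx] = 1.0
    return FCMatrix(fc, ts.roi_indices.copy())


def tsnr(bold: BOLDSeries, mask: BinaryMask) -> tuple[np.ndarray, dict]:
    """Voxelwise temporal SNR (mean / sample SD) and in-mask summaries.

    Voxels with zero temporal SD get NaN in the map and are excluded from the
    summary statistics.
    """
    _require_same_grid(bold, mask)
    if not mask.data.any():
        raise ValueError("tSNR mask is empty")
    mean = bold.data.mean(axis=3)
    sd = bold.data.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = np.where(sd > 0, mean / sd, np.nan)
    in_mask = tmap[mask.data]
    finite = in_mask[np.isfinite(in_mask)]
    if finite.size == 0:
        raise ValueError("no voxel in the mask has temporal variance")
    summary = {
        "tsnr_mean": float(finite.mean()),
        "tsnr_median": float(np.median(finite)),
        "n_voxels": int(finite.size),
        "n_excluded_zero_sd": int(in_mask.size - finite.size),
    }
    return tmap, summary


def read_motion_params(path: str | Path) -> np.ndarray:
    """Read a 6-column motion-parameter file (FSL ``.par`` layout).

    Columns are 3 rotations in radians followed by 3 translations in mm.
    """
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(
            f"motion table must have 6 columns (3 rot, 3 trans), got {arr.shape}"
        )
    return arr


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 50.0
) -> tuple[np.ndarray, dict]:
    """Power-style framewise displacement from a T x 6 motion table.

    FD_t = sum |delta translation| + radius * sum |delta rotation|, with the
    first frame fixed at 0.  Summaries are over frames 2..T.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be T x 6")
    if motion.shape[0] < 2:
        raise ValueError("motion table needs at least 2 frames")
    rot, trans = motion[:, :3], motion[:, 3:]
    d_rot = np.abs(np.diff(rot, axis=0)).sum(axis=1)
    d_trans = np.abs(np.diff(trans, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_trans + head_radius_mm * d_rot])
    summary = {"fd_mean": float(fd[1:].mean()), "fd_max": float(fd[1:].max())}
    return fd, summary


def fc_summaries(fc: FCMatrix) -> dict:
    """Distribution summaries of the valid upper-triangle FC values."""
    n = fc.values.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = fc.values[iu]
    vals = vals[np.isfinite(vals)]
    valid_rois = np.isfinite(np.diagonal(fc.values)).sum()
    if valid_rois < 2 or vals.size == 0:
        raise ValueError("need at least 2 valid ROIs for FC summaries")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return {
        "fc_mean": float(vals.mean()),
        "fc_median": float(np.median(vals)),
        "fc_sd": sd,
        "fc_min": float(vals.min()),
        "fc_max": float(vals.max()),
        "fc_range": float(vals.max() - vals.min()),
        "fc_skewness": float(stats.skew(vals)),
        "fc_kurtosis": float(stats.kurtosis(vals)),
        "fc_prop_positive": float((vals > 0).mean()),
        "fc_prop_strong": float((np.abs(vals) > 0.5).mean()),
        "n_pairs": int(vals.size),
    }
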