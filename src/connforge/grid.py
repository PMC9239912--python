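"""Voxel-grid domain types and NIfTI / look-up-table I/O.

All volumes handled by this package live on a single shared voxel grid:
registration is the caller's responsibility.  Voxel indices are 0-based and
world coordinates follow the NIfTI affine convention (RAS, millimetres).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GridMismatchError",
    "VoxelGrid",
    "BinaryMask",
    "LabelVolume",
    "ParcellationTable",
    "load_mask",
    "load_labels",
    "save_mask",
    "save_labels",
]

HEMISPHERES = ("L", "R", "M")


class GridMismatchError(ValueError):
    """Raised when two volumes do not share the same voxel grid."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with a voxel-to-world (mm) affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (n x 3) to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_size_mm: float = 1.0) -> "VoxelGrid":
        affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
        return cls(tuple(shape), affine)


def _require_same_grid(*volumes) -> VoxelGrid:
    grid = volumes[0].grid
    for v in volumes[1:]:
        if not grid.matches(v.grid):
            raise GridMismatchError(
                f"volumes on different grids: {grid.shape} vs {v.grid.shape}"
            )
    return grid


@dataclass(frozen=True)
class BinaryMask:
    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {data.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class LabelVolume:
    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(data == np.round(data)):
                raise ValueError("label volume must hold integers")
            data = data.astype(np.int32)
        if data.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        if data.shape != self.grid.shape:
            raise ValueError(
                f"label shape {data.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "data", data)

    def labels_present(self) -> np.ndarray:
        u = np.unique(self.data)
        return u[u > 0]


@dataclass
class ParcellationTable:
    """ROI index -> (name, hemisphere, cortical flag) look-up table."""

    indices: np.ndarray
    names: list[str]
    hemispheres: list[str]
    cortical: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.cortical = np.asarray(self.cortical, dtype=bool)
        n = len(self.indices)
        if not (len(self.names) == len(self.hemispheres) == len(self.cortical) == n):
            raise ValueError("ragged parcellation table")
        if n == 0:
            raise ValueError("empty parcellation table")
        if np.any(self.indices <= 0):
            raise ValueError("ROI indices must be strictly positive")
        if len(set(self.indices.tolist())) != n:
            raise ValueError("duplicate ROI indices")
        if len(set(self.names)) != n or any(not s for s in self.names):
            raise ValueError("ROI names must be unique and non-empty")
        bad = [h for h in self.hemispheres if h not in HEMISPHERES]
        if bad:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {bad}")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def n_rois(self) -> int:
        return len(self.indices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.indices,
                "name": self.names,
                "hemisphere": self.hemispheres,
                "cortical": self.cortical.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParcellationTable":
        required = {"index", "name", "hemisphere", "cortical"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"look-up table missing columns: {sorted(missing)}")
        return cls(
            indices=df["index"].to_numpy(dtype=int),
            names=[str(s) for s in df["name"]],
            hemispheres=[str(s) for s in df["hemisphere"]],
            cortical=df["cortical"].to_numpy(dtype=int).astype(bool),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParcellationTable":
        df = pd.read_csv(path, sep="\t")
        return cls.from_frame(df)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# NIfTI I/O

def _grid_from_img(img: nib.Nifti1Image) -> VoxelGrid:
    shape = img.shape[:3]
    return VoxelGrid(tuple(int(s) for s in shape), np.asarray(img.affine))


def load_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    return BinaryMask(_grid_from_img(img), np.asanyarray(img.dataobj) > 0)


def load_labels(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return LabelVolume(_grid_from_img(img), np.rint(data).astype(np.int32))


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def save_labels(labels: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int32), labels.grid.affine)
    img.header.set_data_dtype(np.int32)
    nib.save(img, str(path))
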