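"""Tissue-mask refinement, gray-matter labeling and the labeled GM/WM
interface used as tractography seed/target masks.

Conventions (documented, the upstream tooling is silent on these):

* neighbor connectivity defaults to 26;
* voxels flagged both GM and WM are treated as GM;
* interface voxels take the majority label of their labeled GM neighbors,
  ties broken toward the smallest label index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import (
    BinaryMask,
    LabelVolume,
    ParcellationTable,
    _require_same_grid,
)

__all__ = [
    "merge_subcortical",
    "reassign_lesions",
    "label_gray_matter",
    "extract_interface",
    "label_interface",
    "roi_centroids",
    "roi_volumes",
    "connectivity_structure",
    "neighbor_offsets",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 boolean structuring element for 6/18/26-connectivity."""
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    return ndimage.generate_binary_structure(3, rank)


def neighbor_offsets(connectivity: int) -> np.ndarray:
    """(k, 3) integer offsets of the neighbors for a connectivity level."""
    struct = connectivity_structure(connectivity)
    offs = np.argwhere(struct) - 1
    return offs[np.any(offs != 0, axis=1)]


def merge_subcortical(gm: BinaryMask, subcortical: BinaryMask) -> BinaryMask:
    """Union a subcortical segmentation into the gray matter mask."""
    grid = _require_same_grid(gm, subcortical)
    return BinaryMask(grid, gm.data | subcortical.data)


def reassign_lesions(
    gm: BinaryMask, wm: BinaryMask, lesions: BinaryMask
) -> tuple[BinaryMask, BinaryMask]:
    """Move lesion voxels misclassified as gray matter back to white matter.

    Returns the corrected ``(gm, wm)`` pair: lesion voxels are removed from
    GM, and those that were removed are added to WM.
    """
    grid = _require_same_grid(gm, wm, lesions)
    moved = gm.data & lesions.data
    gm_out = gm.data & ~lesions.data
    wm_out = wm.data | moved
    return BinaryMask(grid, gm_out), BinaryMask(grid, wm_out)


def label_gray_matter(
    gm: BinaryMask, parcellation: LabelVolume, fill_radius_mm: float = 0.0
) -> LabelVolume:
    """Assign parcellation labels to gray matter voxels.

    GM voxels take the co-registered parcellation label at their location.
    GM voxels unlabeled in the parcellation optionally inherit the label of
    the nearest labeled voxel within ``fill_radius_mm`` (Euclidean distance
    in world mm); beyond that radius they stay 0.  Non-GM voxels are 0.
    """
    grid = _require_same_grid(gm, parcellation)
    if fill_radius_mm < 0:
        raise ValueError("fill_radius_mm must be >= 0")
    out = np.where(gm.data, parcellation.data, 0).astype(np.int32)
    if fill_radius_mm > 0:
        unlabeled = gm.data & (parcellation.data == 0)
        if unlabeled.any() and (parcellation.data > 0).any():
            dist, (ii, jj, kk) = ndimage.distance_transform_edt(
                parcellation.data == 0,
                sampling=grid.voxel_size,
                return_indices=True,
            )
            fill = unlabeled & (dist <= fill_radius_mm)
            out[fill] = parcellation.data[ii[fill], jj[fill], kk[fill]]
    return LabelVolume(grid, out)


def extract_interface(
    gm: BinaryMask, wm: BinaryMask, connectivity: int = 26
) -> BinaryMask:
    """White-matter voxels adjacent to gray matter (tractography seed layer).

    Voxels present in both masks are treated as GM and excluded from the
    interface.
    """
    grid = _require_same_grid(gm, wm)
    struct = connectivity_structure(connectivity)
    wm_only = wm.data & ~gm.data
    near_gm = ndimage.binary_dilation(gm.data, structure=struct)
    return BinaryMask(grid, wm_only & near_gm)


def label_interface(
    interface: BinaryMask, labeled_gm: LabelVolume, connectivity: int = 26
) -> LabelVolume:
    """Label each interface voxel by majority vote of its labeled GM neighbors.

    Ties break toward the smallest label index; voxels with no labeled GM
    neighbor stay 0.
    """
    grid = _require_same_grid(interface, labeled_gm)
    offsets = neighbor_offsets(connectivity)
    shape = np.asarray(grid.shape)
    voxels = np.argwhere(interface.data)
    out = np.zeros(grid.shape, dtype=np.int32)
    labels = labeled_gm.data
    for vox in voxels:
        nbrs = vox + offsets
        ok = np.all((nbrs >= 0) & (nbrs < shape), axis=1)
        nbr_labels = labels[tuple(nbrs[ok].T)]
        nbr_labels = nbr_labels[nbr_labels > 0]
        if nbr_labels.size == 0:
            continue
        counts = np.bincount(nbr_labels)
        # argmax returns the smallest index among maxima: the tie-break rule
        out[tuple(vox)] = int(np.argmax(counts))
    return LabelVolume(grid, out)


def roi_centroids(labeled: LabelVolume, table: ParcellationTable) -> pd.DataFrame:
    """World-coordinate (mm) centroids per ROI, in table order.

    ROIs with no voxels get NaN centroids and ``missing=True``.
    """
    rows = []
    for idx, name in zip(table.indices, table.names):
        vox = np.argwhere(labeled.data == idx)
        if vox.shape[0] == 0:
            rows.append((idx, name, np.nan, np.nan, np.nan, True))
        else:
            world = labeled.grid.voxel_to_world(vox)
            cx, cy, cz = world.mean(axis=0)
            rows.append((idx, name, cx, cy, cz, False))
    return pd.DataFrame(
        rows, columns=["index", "name", "x", "y", "z", "missing"]
    )


def roi_volumes(labeled: LabelVolume, table: ParcellationTable) -> pd.DataFrame:
    """Voxel counts and mm^3 volumes per ROI, in table order."""
    counts = np.bincount(
        labeled.data.ravel(), minlength=int(table.indices.max()) + 1
    )
    vox_vol = labeled.grid.voxel_volume_mm3
    n = np.array([counts[i] if i < counts.size else 0 for i in table.indices])
    return pd.DataFrame(
        {
            "index": table.indices,
            "name": table.names,
            "n_voxels": n,
            "volume_mm3": n * vox_vol,
        }
    )
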