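"""Synthetic phantoms and tables with known ground truth.

Everything the analysis modules consume can be generated here without any
data download: a spherical-shell brain phantom whose GM/WM interface is known
analytically, BOLD series with a planted ROI correlation structure,
multinomially sampled streamline counts from a known connection-probability
matrix, and subject-by-IDP tables with a planted latent effect.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .func import BOLDSeries
from .grid import BinaryMask, LabelVolume, ParcellationTable, VoxelGrid
from .masks import neighbor_offsets
from .sc import StreamlineCounts

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "make_bold",
    "make_counts",
    "make_idp_ratings",
    "make_motion",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the spherical-shell brain phantom."""

    shape: tuple[int, int, int] = (24, 24, 24)
    wm_radius: float = 6.0
    gm_thickness: float = 3.0
    parcels_per_hemisphere: int = 4
    lesion_count: int = 0
    lesion_radius: float = 1.5
    voxel_size_mm: float = 1.0
    connectivity: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gm_thickness < 1:
            raise ValueError("GM shell thickness must be >= 1 voxel")
        if self.parcels_per_hemisphere < 1:
            raise ValueError("need at least 1 parcel per hemisphere")
        if self.wm_radius < 1:
            raise ValueError("WM core radius must be >= 1 voxel")
        outer = self.wm_radius + self.gm_thickness
        if any(outer * 2 + 1 > s for s in self.shape):
            raise ValueError("phantom sphere does not fit inside the grid")
        if self.lesion_count < 0 or self.lesion_radius <= 0:
            raise ValueError("invalid lesion parameters")


@dataclass(frozen=True)
class Phantom:
    gm: BinaryMask
    wm: BinaryMask
    parcellation: LabelVolume
    table: ParcellationTable
    interface_truth: BinaryMask
    lesions: BinaryMask


def _brute_force_interface(
    wm: np.ndarray, gm: np.ndarray, connectivity: int
) -> np.ndarray:
    """Independent neighbor-enumeration construction of the GM/WM interface.

    Deliberately a plain voxel/offset loop so it can serve as an oracle for
    the morphological implementation in :mod:`connforge.masks`.
    """
    offsets = neighbor_offsets(connectivity)
    shape = np.asarray(wm.shape)
    out = np.zeros_like(wm)
    for vox in np.argwhere(wm & ~gm):
        for off in offsets:
            nbr = vox + off
            if np.any(nbr < 0) or np.any(nbr >= shape):
                continue
            if gm[tuple(nbr)]:
                out[tuple(vox)] = True
                break
    return out


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Spherical WM core + GM shell phantom with an angular-sector parcellation.

    The GM shell is split into ``parcels_per_hemisphere`` angular sectors per
    hemisphere (x below center = left).  The ground-truth interface is built
    by brute-force neighbor enumeration, independent of the morphological
    code path.  Lesion blobs are small spheres inside the WM core.
    """
    grid = VoxelGrid.isotropic(spec.shape, spec.voxel_size_mm)
    center = (np.asarray(spec.shape) - 1) / 2.0
    ii, jj, kk = np.indices(spec.shape)
    r = np.sqrt(
        (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
    )
    wm = r <= spec.wm_radius
    gm = (r > spec.wm_radius) & (r <= spec.wm_radius + spec.gm_thickness)

    # angular sectors in the (y, z) plane; hemisphere split along x
    npar = spec.parcels_per_hemisphere
    angle = np.arctan2(kk - center[2], jj - center[1])  # [-pi, pi)
    sector = np.floor((angle + np.pi) / (2 * np.pi) * npar).astype(int)
    sector = np.clip(sector, 0, npar - 1)
    left = ii < center[0]
    labels = np.where(gm, np.where(left, sector + 1, sector + 1 + npar), 0)

    indices = np.arange(1, 2 * npar + 1)
    names = [f"lh-sector{i:02d}" for i in range(1, npar + 1)] + [
        f"rh-sector{i:02d}" for i in range(1, npar + 1)
    ]
    hemis = ["L"] * npar + ["R"] * npar
    table = ParcellationTable(
        indices=indices,
        names=names,
        hemispheres=hemis,
        cortical=np.ones(2 * npar, dtype=bool),
    )
    interface = _brute_force_interface(wm, gm, spec.connectivity)

    rng = np.random.default_rng(spec.seed)
    lesions = np.zeros(spec.shape, dtype=bool)
    if spec.lesion_count > 0:
        wm_vox = np.argwhere(wm)
        picks = rng.choice(wm_vox.shape[0], size=spec.lesion_count, replace=False)
        for c in wm_vox[picks]:
            d = np.sqrt(
                (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
            )
            lesions |= (d <= spec.lesion_radius) & wm
    return Phantom(
        gm=BinaryMask(grid, gm),
        wm=BinaryMask(grid, wm),
        parcellation=LabelVolume(grid, labels),
        table=table,
        interface_truth=BinaryMask(grid, interface),
        lesions=BinaryMask(grid, lesions),
    )


def make_bold(
    labeled_gm: LabelVolume,
    roi_correlation: np.ndarray,
    T: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    repetition_time: float = 2.0,
    offset: float = 100.0,
) -> BOLDSeries:
    """BOLD series whose ROI-mean signals follow a target correlation matrix.

    Each ROI gets a latent signal drawn from a zero-mean multivariate normal
    with the requested correlation; every voxel of the ROI observes that
    latent plus iid Gaussian noise plus a constant offset (so tSNR is finite
    and positive, as in scanner-scaled data).
    """
    C = np.asarray(roi_correlation, dtype=float)
    labels = np.sort(labeled_gm.labels_present())
    n = labels.size
    if C.shape != (n, n):
        raise ValueError(
            f"correlation matrix is {C.shape}, label volume has {n} ROIs"
        )
    if not np.allclose(C, C.T):
        raise ValueError("target correlation must be symmetric")
    if not np.allclose(np.diagonal(C), 1.0):
        raise ValueError("target correlation must have unit diagonal")
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-8:
        raise ValueError("target correlation is not positive semidefinite")
    # eigendecomposition square root tolerates exact semidefiniteness
    vals, vecs = np.linalg.eigh(C)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
    rng = np.random.default_rng(seed)
    latents = rng.standard_normal((T, n)) @ root.T
    data = np.zeros(labeled_gm.grid.shape + (T,))
    for k, lab in enumerate(labels):
        sel = labeled_gm.data == lab
        nv = int(sel.sum())
        noise = rng.standard_normal((nv, T)) * noise_sd
        data[sel] = latents[:, k][None, :] + noise + offset
    return BOLDSeries(labeled_gm.grid, data, repetition_time)


def make_counts(
    true_prob: np.ndarray, streamlines_per_seed: int, seed: int = 0
) -> StreamlineCounts:
    """Multinomially sample streamline counts from connection probabilities.

    Each seed ROI sends ``streamlines_per_seed`` streamlines, allocated
    across target ROIs (plus a not-accepted remainder bin) according to its
    row of ``true_prob``; ``waytotal`` is the per-seed total sent.
    """
    P = np.asarray(true_prob, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("true_prob must be square")
    if np.any(P < 0):
        raise ValueError("probabilities must be non-negative")
    row_sums = P.sum(axis=1)
    if np.any(row_sums > 1 + 1e-9):
        raise ValueError("each row of true_prob must sum to <= 1")
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    counts = np.zeros((n, n), dtype=np.int64)
    if streamlines_per_seed < 0:
        raise ValueError("streamlines_per_seed must be >= 0")
    if streamlines_per_seed > 0:
        for i in range(n):
            probs = np.append(P[i], max(0.0, 1.0 - row_sums[i]))
            probs = probs / probs.sum()
            draw = rng.multinomial(streamlines_per_seed, probs)
            counts[i] = draw[:n]
    waytotal = np.full(n, streamlines_per_seed, dtype=np.int64)
    return StreamlineCounts(counts, waytotal, np.arange(1, n + 1))


def make_idp_ratings(
    n_per_group,
    p_idps: int,
    planted_salience: np.ndarray | None = None,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Subject-by-IDP table with a planted rank-1 group effect.

    Rating levels are 1..G with ``n_per_group`` subjects each (scalar or
    sequence).  Each subject's IDP vector is
    ``group_score * effect_size * planted_salience + N(0, noise_sd)``, where
    group scores are the centered, equally spaced rating levels.  With
    ``effect_size=0`` this is an exact null dataset.
    """
    if np.isscalar(n_per_group):
        raise ValueError("n_per_group must be a sequence of per-level counts")
    n_per_group = [int(v) for v in n_per_group]
    G = len(n_per_group)
    if G < 2:
        raise ValueError("need at least 2 rating groups")
    if any(v < 2 for v in n_per_group):
        raise ValueError("every rating group needs at least 2 subjects")
    if planted_salience is None:
        planted_salience = np.zeros(p_idps)
    sal = np.asarray(planted_salience, dtype=float)
    if sal.shape != (p_idps,):
        raise ValueError(
            f"planted salience has length {sal.size}, expected {p_idps}"
        )
    levels = np.arange(1, G + 1, dtype=float)
    scores = levels - levels.mean()
    rng = np.random.default_rng(seed)
    rows, ratings = [], []
    for g, n_g in enumerate(n_per_group):
        signal = scores[g] * effect_size * sal
        block = signal[None, :] + rng.standard_normal((n_g, p_idps)) * noise_sd
        rows.append(block)
        ratings.extend([g + 1] * n_g)
    values = np.vstack(rows)
    df = pd.DataFrame(values, columns=[f"idp{j:03d}" for j in range(p_idps)])
    return df, np.asarray(ratings)


def make_motion(
    T: int, step_sd_mm: float = 0.05, step_sd_rad: float = 0.001, seed: int = 0
) -> np.ndarray:
    """Random-walk motion-parameter table (T x 6: rotations then translations)."""
    if T < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    rot = np.cumsum(rng.standard_normal((T, 3)) * step_sd_rad, axis=0)
    trans = np.cumsum(rng.standard_normal((T, 3)) * step_sd_mm, axis=0)
    return np.hstack([rot, trans])
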