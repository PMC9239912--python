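"""Structural connectome assembly from probabilistic-tractography streamline
counts, summary metrics, and export to TheVirtualBrain connectivity zip.

Weights follow the connection-probability convention: the raw seed-by-target
streamline-count matrix divided by the total number of streamlines
successfully sent from the seed ROIs.  Weights and tract lengths are
symmetrized (tractography cannot resolve direction) and no thresholding is
applied.
"""

from __future__ import annotations

import io
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import ParcellationTable

__all__ = [
    "StreamlineCounts",
    "Connectome",
    "normalize_weights",
    "symmetrize",
    "symmetrize_lengths",
    "build_connectome",
    "sc_summaries",
    "export_tvb_zip",
    "read_tvb_zip",
    "read_counts",
]

TVB_FILES = (
    "weights.txt",
    "tract_lengths.txt",
    "centres.txt",
    "hemispheres.txt",
    "cortical.txt",
)

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly -> byte-stable re-export


@dataclass(frozen=True)
class StreamlineCounts:
    """Seed-by-target streamline counts plus per-seed totals sent."""

    counts: np.ndarray
    waytotal: np.ndarray
    roi_indices: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        waytotal = np.asarray(self.waytotal)
        roi_indices = np.asarray(self.roi_indices, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        n = counts.shape[0]
        if waytotal.shape != (n,) or roi_indices.shape != (n,):
            raise ValueError("waytotal / roi_indices length mismatch with counts")
        if np.any(counts < 0) or np.any(waytotal < 0):
            raise ValueError("streamline counts must be non-negative")
        if np.any(counts.sum(axis=1) > waytotal):
            warnings.warn(
                "row sums of counts exceed waytotal for some seeds", stacklevel=2
            )
        object.__setattr__(self, "counts", counts.astype(float))
        object.__setattr__(self, "waytotal", waytotal.astype(float))
        object.__setattr__(self, "roi_indices", roi_indices)

    @property
    def n_rois(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class Connectome:
    """Symmetric weights + tract lengths with per-ROI metadata."""

    weights: np.ndarray
    tract_lengths: np.ndarray
    table: ParcellationTable
    centroids: np.ndarray  # N x 3, mm; NaN rows = missing

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        tl = np.asarray(self.tract_lengths, dtype=float)
        c = np.asarray(self.centroids, dtype=float)
        n = self.table.n_rois
        if w.shape != (n, n) or tl.shape != (n, n):
            raise ValueError("weights/tract_lengths must be N x N matching the table")
        if c.shape != (n, 3):
            raise ValueError("centroids must be N x 3")
        if not np.allclose(w, w.T) or not np.allclose(tl, tl.T):
            raise ValueError("weights and tract_lengths must be symmetric")
        if np.any(np.diagonal(w) != 0) or np.any(np.diagonal(tl) != 0):
            raise ValueError("self-connections must be zero")
        if np.any(w < 0) or np.any(tl < 0):
            raise ValueError("weights and tract lengths must be non-negative")
        if np.any((tl > 0) & (w == 0)):
            raise ValueError("tract lengths must be zero where weights are zero")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "tract_lengths", tl)
        object.__setattr__(self, "centroids", c)


def normalize_weights(sc: StreamlineCounts, per_seed: bool = False) -> np.ndarray:
    """Convert streamline counts to connection probabilities.

    Default: divide every entry by the grand total of streamlines
    successfully sent from all seed ROIs.  ``per_seed=True`` instead divides
    each row by that seed's own waytotal.
    """
    if per_seed:
        if np.any(sc.waytotal == 0):
            raise ValueError("per-seed normalization requires nonzero waytotals")
        return sc.counts / sc.waytotal[:, None]
    total = sc.waytotal.sum()
    if total <= 0:
        raise ValueError("total waytotal is zero; cannot normalize")
    return sc.counts / total


def symmetrize(m: np.ndarray, method: str = "mean") -> np.ndarray:
    """Symmetrize a square matrix and zero its diagonal."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if method == "mean":
        out = (m + m.T) / 2.0
    elif method == "max":
        out = np.maximum(m, m.T)
    elif method == "sum":
        out = m + m.T
    else:
        raise ValueError(f"unknown symmetrization method {method!r}")
    np.fill_diagonal(out, 0.0)
    return out


def symmetrize_lengths(lengths: np.ndarray, weights_sym: np.ndarray) -> np.ndarray:
    """Symmetrize directed tract-length estimates.

    Pairwise mean when both directions produced streamlines, the single
    estimate when only one did, and 0 wherever the symmetrized weight is 0.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape != weights_sym.shape:
        raise ValueError("lengths and weights shapes differ")
    a, b = lengths, lengths.T
    both = (a > 0) & (b > 0)
    out = np.where(both, (a + b) / 2.0, np.maximum(a, b))
    out = np.where(weights_sym == 0, 0.0, out)
    np.fill_diagonal(out, 0.0)
    return out


def build_connectome(
    sc: StreamlineCounts,
    lengths: np.ndarray,
    table: ParcellationTable,
    centroids: np.ndarray,
    method: str = "mean",
    per_seed: bool = False,
) -> Connectome:
    """Normalize, symmetrize and package a connectome."""
    w = symmetrize(normalize_weights(sc, per_seed=per_seed), method=method)
    tl = symmetrize_lengths(lengths, w)
    return Connectome(w, tl, table, centroids)


def sc_summaries(conn: Connectome, table: ParcellationTable | None = None) -> dict:
    """Density and weight-distribution summaries of a connectome."""
    table = table if table is not None else conn.table
    w = conn.weights
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 ROIs")
    iu, ju = np.triu_indices(n, k=1)
    upper = w[iu, ju]
    hemi = np.asarray(table.hemispheres)
    inter = hemi[iu] != hemi[ju]
    left = (hemi[iu] == "L") & (hemi[ju] == "L")
    right = (hemi[iu] == "R") & (hemi[ju] == "R")

    def _density(sel: np.ndarray) -> float:
        return float((upper[sel] > 0).mean()) if sel.any() else float("nan")

    nz = upper[upper > 0]
    logw = np.log10(nz) if nz.size else np.array([])
    return {
        "sc_density": float((upper > 0).mean()),
        "sc_density_interhemispheric": _density(inter),
        "sc_density_left": _density(left),
        "sc_density_right": _density(right),
        "sc_n_disconnected": int((w.sum(axis=1) == 0).sum()),
        "sc_log10_weight_mean": float(logw.mean()) if logw.size else float("nan"),
        "sc_log10_weight_median": float(np.median(logw)) if logw.size else float("nan"),
        "sc_log10_weight_sd": float(logw.std(ddof=1)) if logw.size > 1 else float("nan"),
        "sc_weight_min_nonzero": float(nz.min()) if nz.size else float("nan"),
        "sc_weight_max": float(w.max()),
        "n_rois": n,
    }


# ---------------------------------------------------------------------------
# TheVirtualBrain zip format


def _sanitize_name(name: str) -> str:
    out = "_".join(name.split())
    return out


def _matrix_text(m: np.ndarray) -> str:
    buf = io.StringIO()
    np.savetxt(buf, m, fmt=_FLOAT_FMT, delimiter=" ", newline="\n")
    return buf.getvalue()


def export_tvb_zip(conn: Connectome, path: str | Path,
                   table: ParcellationTable | None = None) -> Path:
    """Write a TheVirtualBrain-compatible connectivity zip.

    Contains weights.txt, tract_lengths.txt, centres.txt (name x y z),
    hemispheres.txt (0 = left/midline, 1 = right), cortical.txt (0/1), all
    with one row per ROI in parcellation-table order.
    """
    table = table if table is not None else conn.table
    missing = [
        name
        for name, c in zip(table.names, conn.centroids)
        if not np.all(np.isfinite(c))
    ]
    if missing:
        raise ValueError(f"cannot export: missing centroids for ROIs {missing}")
    centres_lines = []
    for name, (x, y, z) in zip(table.names, conn.centroids):
        centres_lines.append(
            f"{_sanitize_name(name)} {_FLOAT_FMT % x} {_FLOAT_FMT % y} {_FLOAT_FMT % z}"
        )
    hemis = "\n".join("1" if h == "R" else "0" for h in table.hemispheres) + "\n"
    cort = "\n".join("1" if c else "0" for c in table.cortical) + "\n"
    payload = {
        "weights.txt": _matrix_text(conn.weights),
        "tract_lengths.txt": _matrix_text(conn.tract_lengths),
        "centres.txt": "\n".join(centres_lines) + "\n",
        "hemispheres.txt": hemis,
        "cortical.txt": cort,
    }
    path = Path(path)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for fname in TVB_FILES:
            zf.writestr(fname, payload[fname])
    return path


def read_tvb_zip(path: str | Path) -> tuple[Connectome, ParcellationTable]:
    """Read a connectivity zip written by :func:`export_tvb_zip`."""
    with zipfile.ZipFile(str(path)) as zf:
        names = set(zf.namelist())
        missing = [f for f in TVB_FILES if f not in names]
        if missing:
            raise ValueError(f"zip missing required files: {missing}")
        weights = np.loadtxt(io.StringIO(zf.read("weights.txt").decode()), ndmin=2)
        lengths = np.loadtxt(
            io.StringIO(zf.read("tract_lengths.txt").decode()), ndmin=2
        )
        centre_rows = [
            ln.split()
            for ln in zf.read("centres.txt").decode().splitlines()
            if ln.strip()
        ]
        hemi_flags = [
            int(v) for v in zf.read("hemispheres.txt").decode().split()
        ]
        cort_flags = [int(v) for v in zf.read("cortical.txt").decode().split()]
    roi_names = [r[0] for r in centre_rows]
    centroids = np.array([[float(v) for v in r[1:4]] for r in centre_rows])
    n = weights.shape[0]
    if not (len(roi_names) == len(hemi_flags) == len(cort_flags) == n):
        raise ValueError("inconsistent row counts across zip payload files")
    table = ParcellationTable(
        indices=np.arange(1, n + 1),
        names=roi_names,
        hemispheres=["R" if h else "L" for h in hemi_flags],
        cortical=np.asarray(cort_flags, dtype=bool),
    )
    return Connectome(weights, lengths, table, centroids), table


# ---------------------------------------------------------------------------
# Tractography text ingest


def _load_matrix(path: str | Path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                row = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value on line {lineno}") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}: ragged matrix, line {lineno} has {len(row)} "
                    f"columns, expected {width}"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    return np.asarray(rows)


def read_counts(
    counts_path: str | Path,
    waytotal_path: str | Path,
    roi_indices: np.ndarray | None = None,
) -> StreamlineCounts:
    """Read a streamline-count matrix and per-seed waytotal text files."""
    counts = _load_matrix(counts_path)
    if counts.shape[0] != counts.shape[1]:
        raise ValueError(
            f"{counts_path}: counts matrix is {counts.shape}, expected square"
        )
    waytotal_path = Path(waytotal_path)
    if not waytotal_path.exists():
        raise FileNotFoundError(f"waytotal file not found: {waytotal_path}")
    waytotal = np.loadtxt(str(waytotal_path), ndmin=1)
    if waytotal.size != counts.shape[0]:
        raise ValueError(
            f"waytotal has {waytotal.size} entries for {counts.shape[0]} seed ROIs"
        )
    if roi_indices is None:
        roi_indices = np.arange(1, counts.shape[0] + 1)
    return StreamlineCounts(counts, waytotal, roi_indices)
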