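"""Mean-centered partial least squares relating imaging metrics (IDPs) to
ordinal QC ratings, with permutation tests for latent-variable significance
and bootstrap ratios for salience reliability.

The cross-block structure is the rating-group mean matrix of z-scored IDPs,
centered on the grand mean of group means (mean-centered task PLS).  Its SVD
yields, per latent variable, an IDP salience pattern, a rating-group design
contrast and a singular value; latent variables are ordered by singular
value and each explains ``100 * s_l^2 / sum(s^2)`` percent of the
cross-block covariance.

Permutation p-values use the add-one estimator
``p = (1 + #{s_perm >= s_obs}) / (1 + n_perm)``.  Bootstrap resampling is
stratified within rating groups; bootstrap saliences are aligned to the
original solution by orthogonal Procrustes rotation of the design saliences
before standard errors are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

__all__ = [
    "PLSModel",
    "prepare",
    "pls_svd",
    "permutation_test",
    "bootstrap_ratios",
    "reliable_idps",
    "fit_pls",
    "load_idp_table",
]


@dataclass
class PLSModel:
    saliences: np.ndarray           # p x L
    design_saliences: np.ndarray    # g x L
    singular_values: np.ndarray     # L
    pct_covariance: np.ndarray      # L, sums to 100
    perm_p: np.ndarray | None       # L
    bootstrap_ratios: np.ndarray | None  # p x L
    salience_se: np.ndarray | None  # p x L
    group_levels: np.ndarray        # g rating levels, ascending
    idp_names: list[str]
    n_permutations: int = 0
    n_bootstrap: int = 0
    seed: int | None = None

    @property
    def n_latent(self) -> int:
        return self.singular_values.size


def _as_matrix(idps) -> tuple[np.ndarray, list[str]]:
    if isinstance(idps, pd.DataFrame):
        return idps.to_numpy(dtype=float), [str(c) for c in idps.columns]
    arr = np.asarray(idps, dtype=float)
    if arr.ndim != 2:
        raise ValueError("IDP matrix must be 2-dimensional (subjects x IDPs)")
    return arr, [f"idp{j:03d}" for j in range(arr.shape[1])]


def _impute_and_zscore(values: np.ndarray) -> np.ndarray:
    """Median-impute missing entries, then z-score columns (ddof=1).

    Columns with zero variance after imputation are set to all zeros rather
    than producing NaNs; they carry no group information.
    """
    x = values.copy()
    for j in range(x.shape[1]):
        col = x[:, j]
        miss = ~np.isfinite(col)
        if miss.all():
            raise ValueError(f"IDP column {j} is entirely missing")
        if miss.any():
            col[miss] = np.median(col[~miss])
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    z = np.zeros_like(x)
    ok = sd > 0
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return z


def _group_rows(ratings: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    ratings = np.asarray(ratings)
    levels = np.unique(ratings)
    if levels.size < 2:
        raise ValueError("need at least 2 rating groups")
    members = [np.where(ratings == lv)[0] for lv in levels]
    small = [str(lv) for lv, m in zip(levels, members) if m.size < 2]
    if small:
        raise ValueError(f"rating groups with fewer than 2 subjects: {small}")
    return levels, members


def prepare(idps, ratings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Build the centered group-mean matrix (g x p) for the PLS SVD.

    IDP columns are median-imputed and z-scored over all subjects, averaged
    within each rating group, and centered by subtracting the grand mean of
    the group means from every column.

    Returns ``(M, group_levels)``.
    """
    values, _ = _as_matrix(idps)
    levels, members = _group_rows(ratings)
    if values.shape[0] != np.asarray(ratings).shape[0]:
        raise ValueError("IDP rows and ratings length differ")
    z = _impute_and_zscore(values)
    gm = np.stack([z[m].mean(axis=0) for m in members])
    return gm - gm.mean(axis=0, keepdims=True), levels


def pls_svd(
    M: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD of the centered group-mean matrix.

    Returns ``(saliences p x L, singular_values L, design_saliences g x L,
    pct_covariance L)``, with latent variables ordered by singular value.
    ``L = min(g - 1, p)`` (mean-centering removes one rank).  Sign
    convention: the largest-magnitude design salience of each LV is made
    positive.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite values in the cross-block matrix")
    g, p = M.shape
    L = min(g - 1, p) if g > 1 else min(g, p)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    U, s, V = U[:, :L], s[:L], Vt[:L].T
    for l in range(L):
        mag = np.abs(U[:, l])
        # first index whose magnitude is (numerically) maximal, so exact
        # ties are broken deterministically toward the smallest index
        k = int(np.argmax(mag >= mag.max() * (1 - 1e-12)))
        if U[k, l] < 0:
            U[:, l] = -U[:, l]
            V[:, l] = -V[:, l]
    total = float((s**2).sum())
    pct = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    return V, s, U, pct


def permutation_test(
    idps,
    ratings: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    max_statistic: bool = False,
) -> np.ndarray:
    """Permutation p-value per latent variable.

    Ratings are reshuffled across subjects without replacement while IDP rows
    stay fixed; each permuted dataset is re-prepared and re-decomposed.  With
    ``max_statistic=True`` every observed singular value is compared against
    the maximum permuted singular value instead of its rank-matched one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ratings = np.asarray(ratings)
    M, _ = prepare(idps, ratings)
    _, s_obs, _, _ = pls_svd(M)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(s_obs)
    for _ in range(n_perm):
        perm = rng.permutation(ratings)
        Mp, _ = prepare(idps, perm)
        _, s_perm, _, _ = pls_svd(Mp)
        if max_statistic:
            exceed += s_perm.max() >= s_obs
        else:
            exceed += s_perm >= s_obs
    return (1.0 + exceed) / (1.0 + n_perm)


def bootstrap_ratios(
    idps,
    ratings: np.ndarray,
    n_boot: int = 500,
    seed: int | None = None,
    align: str = "procrustes",
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap ratios (salience / bootstrap SE) and the SEs themselves.

    Subjects are resampled with replacement within each rating group.  Each
    resample's saliences are aligned to the original solution — by orthogonal
    Procrustes rotation of the design saliences (default) or by per-LV sign
    flipping (``align='sign'``) — before the elementwise standard deviation
    is taken as the SE.  Elements with SE = 0 get an infinite ratio.
    """
    if align not in ("procrustes", "sign"):
        raise ValueError("align must be 'procrustes' or 'sign'")
    ratings = np.asarray(ratings)
    values, _ = _as_matrix(idps)
    levels, members = _group_rows(ratings)
    M, _ = prepare(values, ratings)
    V0, s0, U0, _ = pls_svd(M)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, *V0.shape))
    for b in range(n_boot):
        rows = np.concatenate([rng.choice(m, size=m.size, replace=True)
                               for m in members])
        Mb, _ = prepare(values[rows], ratings[rows])
        Vb, sb, Ub, _ = pls_svd(Mb)
        if align == "procrustes":
            R, _ = orthogonal_procrustes(Ub, U0)
            Vb = Vb @ R
        else:
            flip = np.sign(np.sum(Ub * U0, axis=0))
            flip[flip == 0] = 1.0
            Vb = Vb * flip
        boot[b] = Vb
    se = boot.std(axis=0, ddof=1)
    # SVD jitter leaves O(eps) spread even on deterministic data; saliences
    # are unit-norm so an absolute cutoff is safe
    se[se < 1e-12] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, V0 / se, np.inf * np.sign(V0))
        bsr = np.where((se == 0) & (V0 == 0), np.inf, bsr)
    return bsr, se


def reliable_idps(model: PLSModel, lv: int = 0, threshold: float = 2.0) -> list[str]:
    """IDP names with |bootstrap ratio| >= threshold on one latent variable,
    sorted by descending |BSR|."""
    if model.bootstrap_ratios is None:
        raise ValueError("model has no bootstrap ratios")
    if not 0 <= lv < model.n_latent:
        raise IndexError(f"latent variable index {lv} out of range")
    col = model.bootstrap_ratios[:, lv]
    sel = np.where(np.abs(col) >= threshold)[0]
    order = sel[np.argsort(-np.abs(col[sel]))]
    return [model.idp_names[i] for i in order]


def fit_pls(
    idps,
    ratings: np.ndarray,
    n_perm: int = 1000,
    n_boot: int = 500,
    seed: int | None = None,
) -> PLSModel:
    """Run the full analysis: SVD + permutation test + bootstrap ratios."""
    values, names = _as_matrix(idps)
    ratings = np.asarray(ratings)
    M, levels = prepare(values, ratings)
    V, s, U, pct = pls_svd(M)
    perm_p = (
        permutation_test(values, ratings, n_perm=n_perm, seed=seed)
        if n_perm > 0
        else None
    )
    if n_boot > 0:
        seed_boot = None if seed is None else seed + 1
        bsr, se = bootstrap_ratios(values, ratings, n_boot=n_boot, seed=seed_boot)
    else:
        bsr = se = None
    return PLSModel(
        saliences=V,
        design_saliences=U,
        singular_values=s,
        pct_covariance=pct,
        perm_p=perm_p,
        bootstrap_ratios=bsr,
        salience_se=se,
        group_levels=levels,
        idp_names=names,
        n_permutations=n_perm,
        n_bootstrap=n_boot,
        seed=seed,
    )


def load_idp_table(path, rating_col: str = "rating") -> tuple[pd.DataFrame, np.ndarray]:
    """Read a subject-by-IDP TSV with an ordinal rating column."""
    df = pd.read_csv(path, sep="\t")
    if rating_col not in df.columns:
        raise ValueError(f"rating column {rating_col!r} not in table")
    ratings = df[rating_col].to_numpy()
    idps = df.drop(columns=[rating_col])
    idps = idps.select_dtypes(include=[np.number])
    if idps.shape[1] == 0:
        raise ValueError("no numeric IDP columns found")
    return idps, ratings
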