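"""Inter-subject representational similarity analysis (IS-RSA).

A behavioral representational dissimilarity matrix (RDM) holds the
Euclidean distance between every pair of subjects' item-response vectors
(here: the 10 short-video-addiction items). A neural RDM per parcel
holds 1 - Pearson r between the subjects' voxel-wise ALFF patterns.
IS-RSA correlates the two RDMs over subject pairs, parcel by parcel,
using the strictly-lower triangle (diagonal excluded; entries taken in
numpy ``tril_indices`` row-major order — the order is immaterial to the
correlation but fixed here so vectors are reproducible bit-for-bit).

Parametric p-values treat the n(n-1)/2 pair entries as independent,
which they are not; they are reported for fidelity with common practice
and Bonferroni-corrected across parcels. A Mantel permutation test —
jointly permuting one RDM's rows and columns, which respects the pair
dependence — is provided as the calibrated alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .alff import ALFFMaps

__all__ = [
    "RDM",
    "behavioral_rdm",
    "neural_rdm",
    "lower_triangle",
    "isrsa_map",
    "mantel_permutation",
]


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix over subjects."""

    matrix: np.ndarray
    metric: str  # 'euclidean' or 'one_minus_pearson'
    subject_ids: list

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        self.matrix = m

    @property
    def n(self):
        return self.matrix.shape[0]


def lower_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle entries; length n(n-1)/2 exactly."""
    m = np.asarray(matrix)
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def behavioral_rdm(items, subject_ids=None) -> RDM:
    """Pairwise Euclidean distances between subjects' item vectors.

    ``items`` is subjects x items (DataFrame or array). Subjects with any
    missing item are excluded with a warning.
    """
    if isinstance(items, pd.DataFrame):
        if subject_ids is None:
            subject_ids = list(items.index)
        arr = items.to_numpy(dtype=float)
    else:
        arr = np.asarray(items, dtype=float)
        if subject_ids is None:
            subject_ids = list(range(arr.shape[0]))
    keep = np.isfinite(arr).all(axis=1)
    if not keep.all():
        dropped = [s for s, k in zip(subject_ids, keep) if not k]
        warnings.warn(f"excluding {len(dropped)} subject(s) with missing items: {dropped[:5]}...")
        arr = arr[keep]
        subject_ids = [s for s, k in zip(subject_ids, keep) if k]
    d = squareform(pdist(arr, metric="euclidean"))
    return RDM(matrix=d, metric="euclidean", subject_ids=list(subject_ids))


def _pattern_corr_rdm(patterns: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows of a subjects x features matrix."""
    sd = patterns.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance pattern for subject index {bad.tolist()}")
    z = (patterns - patterns.mean(axis=1, keepdims=True)) / sd[:, None]
    r = z @ z.T / patterns.shape[1]
    out = 1.0 - r
    np.fill_diagonal(out, 0.0)
    return (out + out.T) / 2  # enforce exact symmetry against float noise


def neural_rdm(maps: ALFFMaps, parcel: int) -> RDM:
    """1 - Pearson r between subjects' voxel-wise ALFF patterns in a parcel."""
    if not 0 <= parcel < maps.n_parcels:
        raise IndexError(f"parcel {parcel} out of range 0..{maps.n_parcels - 1}")
    patterns = maps.values[:, parcel, :]
    if patterns.shape[1] < 3:
        raise ValueError("need >= 3 voxels in the parcel")
    return RDM(
        matrix=_pattern_corr_rdm(patterns),
        metric="one_minus_pearson",
        subject_ids=list(maps.subject_ids),
    )


def _pair_corr_p(r: np.ndarray, n_pairs: int) -> np.ndarray:
    rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = rr * np.sqrt((n_pairs - 2) / (1 - rr**2))
    return 2 * stats.t.sf(np.abs(t), df=n_pairs - 2)


def isrsa_map(behav: RDM, maps: ALFFMaps, alpha: float = 0.05) -> pd.DataFrame:
    """Per-parcel Pearson r between neural and behavioral RDM lower triangles.

    Subject order must match exactly between ``behav`` and ``maps`` —
    a mismatch raises, it is never silently reindexed. Bonferroni
    correction uses m = n_parcels.
    """
    if list(behav.subject_ids) != list(maps.subject_ids):
        raise ValueError("subject order differs between behavioral RDM and ALFF maps")
    n = behav.n
    bv = lower_triangle(behav.matrix)
    bv_c = bv - bv.mean()
    bv_ss = np.sqrt((bv_c**2).sum())
    if bv_ss == 0:
        raise ValueError("behavioral RDM has zero variance over pairs")

    i, j = np.tril_indices(n, k=-1)
    rs = np.empty(maps.n_parcels)
    for parcel in range(maps.n_parcels):
        nv = _pattern_corr_rdm(maps.values[:, parcel, :])[i, j]
        nv_c = nv - nv.mean()
        denom = np.sqrt((nv_c**2).sum()) * bv_ss
        rs[parcel] = (nv_c @ bv_c) / denom if denom > 0 else np.nan
    n_pairs = n * (n - 1) // 2
    p_raw = _pair_corr_p(rs, n_pairs)
    p_bonf = np.minimum(1.0, maps.n_parcels * p_raw)
    return pd.DataFrame({
        "parcel": np.arange(maps.n_parcels),
        "r": rs,
        "p_raw": p_raw,
        "p_bonferroni": p_bonf,
        "significant": p_bonf < alpha,
    })


def mantel_permutation(rdm_a: RDM, rdm_b: RDM, n_perm: int = 1000, seed: int = 0):
    """One-sided Mantel test of positive RDM-RDM correlation.

    Subject labels of ``rdm_b`` are permuted (rows and columns jointly).
    p = (1 + #{permuted r >= observed r}) / (1 + n_perm). Returns
    (observed_r, p).
    """
    if list(rdm_a.subject_ids) != list(rdm_b.subject_ids):
        raise ValueError("subject order differs between RDMs")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = rdm_a.n
    if factorial(n) < n_perm:
        warnings.warn(f"only {factorial(n)} distinct permutations exist for n={n}")
    tri = np.tril_indices(n, k=-1)
    av = rdm_a.matrix[tri]
    av_c = av - av.mean()
    av_norm = np.sqrt((av_c**2).sum())

    def corr_with_a(bmat_rows):
        bv = bmat_rows
        bv_c = bv - bv.mean(axis=-1, keepdims=True)
        denom = np.sqrt((bv_c**2).sum(axis=-1)) * av_norm
        return (bv_c @ av_c) / denom

    obs = float(corr_with_a(rdm_b.matrix[tri][None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    permuted = rdm_b.matrix[perms[:, :, None], perms[:, None, :]]  # (n_perm, n, n)
    pv = permuted[:, tri[0], tri[1]]
    perm_r = corr_with_a(pv)
    p = (1 + int(np.sum(perm_r >= obs))) / (1 + n_perm)
    return obs, p
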