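"""Parcel-level brain-behavior association.

Relates parcel-mean ALFF to a behavioral trait (SVA total) while
controlling covariates (age, gender, parental education, head motion),
one regression per parcel, corrected across parcels. The statistic is
the partial correlation between trait and ALFF given the covariates,
computed by residualizing both on the covariates — numerically identical
to the t-test of the trait coefficient in the joint regression and easy
to check against a brute-force oracle. With no covariates it reduces to
the plain Pearson correlation.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alff import ALFFMaps

__all__ = ["parcel_association", "roi_correlation"]

_CORRECTIONS = {"bonferroni": "bonferroni", "bh_fdr": "fdr_bh"}


def _design(n, covariates):
    if covariates is None:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    return np.column_stack([np.ones(n), cov])


def _residualize(v, Z):
    beta, _, _, _ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def parcel_association(
    maps: ALFFMaps,
    trait,
    covariates=None,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partial correlation of the trait with each parcel's mean ALFF.

    Returns one row per parcel: beta (slope of ALFF on trait given
    covariates), partial_r, t, p_raw, p_corrected, significant. The
    covariate block must not be collinear with the trait — that is an
    error, never a silent drop.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    trait = np.asarray(trait, dtype=float)
    n = maps.n_subjects
    if trait.shape != (n,):
        raise ValueError("trait length must equal number of subjects")
    Z = _design(n, covariates)
    n_cov = Z.shape[1] - 1
    if n <= n_cov + 2:
        raise ValueError("need n > number of covariates + 2")
    full = np.column_stack([Z, trait])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise np.linalg.LinAlgError(
            "covariates are collinear with the trait (or each other)"
        )
    rt = _residualize(trait, Z)
    rt_sd = rt.std()
    if rt_sd == 0:
        raise ValueError("trait has no variance after covariate adjustment")

    means = maps.parcel_means()  # (n, p)
    ra = means - Z @ np.linalg.lstsq(Z, means, rcond=None)[0]
    ra_sd = ra.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        partial_r = (ra * rt[:, None]).mean(axis=0) / (ra_sd * rt_sd)
        beta = (ra * rt[:, None]).sum(axis=0) / (rt**2).sum()  # slope ALFF ~ trait | cov
    df = n - 2 - n_cov
    rr = np.clip(partial_r, -1 + 1e-15, 1 - 1e-15)
    t = rr * np.sqrt(df / (1 - rr**2))
    p_raw = 2 * stats.t.sf(np.abs(t), df=df)
    _, p_corr, _, _ = multipletests(p_raw, alpha=alpha, method=_CORRECTIONS[correction])
    return pd.DataFrame({
        "parcel": np.arange(maps.n_parcels),
        "beta": beta,
        "partial_r": partial_r,
        "t": t,
        "p_raw": p_raw,
        "p_corrected": p_corr,
        "significant": p_corr < alpha,
        "method": correction,
    })


def roi_correlation(roi_values, trait, covariates=None) -> SimpleNamespace:
    """Pearson correlation of a per-subject ROI summary with the trait.

    Returns r and two-sided p; when covariates are given, also the
    covariate-adjusted partial correlation (r_partial, p_partial), since
    reports often leave ambiguous which of the two a scatterplot shows.
    """
    v = np.asarray(roi_values, dtype=float)
    tr = np.asarray(trait, dtype=float)
    if v.shape != tr.shape or v.ndim != 1:
        raise ValueError("roi_values and trait must be aligned vectors")
    if len(v) < 3:
        raise ValueError("need >= 3 subjects")
    if v.std() == 0 or tr.std() == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = stats.pearsonr(v, tr)
    out = SimpleNamespace(r=float(r), p=float(p), n=len(v),
                          r_partial=None, p_partial=None)
    if covariates is not None:
        Z = _design(len(v), covariates)
        rv, rt = _residualize(v, Z), _residualize(tr, Z)
        if rv.std() == 0 or rt.std() == 0:
            raise ValueError("constant input after covariate adjustment")
        rp = float(np.corrcoef(rv, rt)[0, 1])
        df = len(v) - 2 - (Z.shape[1] - 1)
        tstat = rp * np.sqrt(df / (1 - min(rp**2, 1 - 1e-15)))
        out.r_partial = rp
        out.p_partial = float(2 * stats.t.sf(abs(tstat), df=df))
    return out
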