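"""Simple mediation (X -> M -> Y) with percentile-bootstrap inference.

The model is the classic three-regression decomposition:

    M = i1 + a*X (+ covariates)
    Y = i2 + c'*X + b*M (+ covariates)
    Y = i3 + c*X (+ covariates)

with indirect effect a*b, total effect c = c' + a*b (an exact OLS
identity when all three are fit on the same rows), and proportion
mediated 100*a*b/c. The confidence interval for a*b comes from a
case (subject-level) percentile bootstrap, the common default of
macro-style mediation tools; 5000 resamples by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MediationResult",
    "fit_ols",
    "mediate",
    "mediation_from_correlations",
    "subgroup_mediate",
]


def fit_ols(y, predictors) -> SimpleNamespace:
    """Ordinary least squares with an explicit design (no implicit intercept).

    Returns beta, standard errors from the residual variance, residuals
    and df. Raises on rank deficiency rather than silently dropping
    columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {p} columns)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    return SimpleNamespace(beta=beta, se=se, residuals=resid, df_resid=df, sigma2=sigma2)


@dataclass
class MediationResult:
    """Point estimates and bootstrap CI for one mediation model."""

    a: float
    b: float
    c: float
    cprime: float
    indirect: float
    ci_low: float
    ci_high: float
    ci_level: float
    prop_mediated: float  # percent; NaN when |c| ~ 0
    n: int
    n_boot: int
    seed: int
    covariate_names: tuple = ()
    boot_indirect: np.ndarray | None = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        """True when the percentile CI excludes zero."""
        return (self.ci_low > 0) or (self.ci_high < 0)

    def summary_row(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "cprime": self.cprime,
            "indirect": self.indirect, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "prop_mediated_pct": self.prop_mediated,
            "n": self.n, "n_boot": self.n_boot,
        }


def _with_intercept(*cols):
    n = len(cols[0])
    return np.column_stack([np.ones(n)] + list(cols))


def _boot_paths(x, m, y, cov, idx, chunk=256):
    """Vectorized per-resample a and b via batched normal equations."""
    n = len(x)
    cov_cols = [] if cov is None else [cov[:, j] for j in range(cov.shape[1])]
    A = _with_intercept(x, *cov_cols)               # m ~ 1 + x + cov
    B = _with_intercept(x, m, *cov_cols)            # y ~ 1 + x + m + cov
    a_out = np.empty(idx.shape[0])
    b_out = np.empty(idx.shape[0])
    for start in range(0, idx.shape[0], chunk):
        sl = idx[start:start + chunk]
        Ab, mb = A[sl], m[sl]
        Bb, yb = B[sl], y[sl]
        Ga = np.einsum("cni,cnj->cij", Ab, Ab)
        ha = np.einsum("cni,cn->ci", Ab, mb)
        Gb = np.einsum("cni,cnj->cij", Bb, Bb)
        hb = np.einsum("cni,cn->ci", Bb, yb)
        try:
            beta_a = np.linalg.solve(Ga, ha[..., None])[..., 0]
            beta_b = np.linalg.solve(Gb, hb[..., None])[..., 0]
        except np.linalg.LinAlgError:  # degenerate resample: fall back per-row
            beta_a = np.stack([np.linalg.lstsq(Ab[i], mb[i], rcond=None)[0]
                               for i in range(len(sl))])
            beta_b = np.stack([np.linalg.lstsq(Bb[i], yb[i], rcond=None)[0]
                               for i in range(len(sl))])
        a_out[start:start + len(sl)] = beta_a[:, 1]
        b_out[start:start + len(sl)] = beta_b[:, 2]
    return a_out, b_out


def mediate(
    x, m, y,
    covariates=None,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
    covariate_names: tuple = (),
) -> MediationResult:
    """Estimate the mediation paths with a percentile bootstrap CI.

    ``x``, ``m``, ``y`` are aligned vectors; rows with any missing value
    (including in ``covariates``) are dropped listwise. The resampling
    unit is the subject; the RNG is seeded so results are reproducible.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = None
    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(x):
            cov = cov.T
        keep &= np.isfinite(cov).all(axis=1)
    x, m, y = x[keep], m[keep], y[keep]
    if cov is not None:
        cov = cov[keep]
    n = len(x)
    if n < 10:
        raise ValueError(f"need >= 10 complete cases, got {n}")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")

    cov_cols = [] if cov is None else [cov[:, j] for j in range(cov.shape[1])]
    fit_a = fit_ols(m, _with_intercept(x, *cov_cols))
    fit_b = fit_ols(y, _with_intercept(x, m, *cov_cols))
    fit_c = fit_ols(y, _with_intercept(x, *cov_cols))
    a = float(fit_a.beta[1])
    cprime = float(fit_b.beta[1])
    b = float(fit_b.beta[2])
    c = float(fit_c.beta[1])
    indirect = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_a, boot_b = _boot_paths(x, m, y, cov, idx)
    boot_ind = boot_a * boot_b
    alpha = 1 - ci_level
    ci_low, ci_high = np.quantile(boot_ind, [alpha / 2, 1 - alpha / 2])

    if abs(c) < 1e-12:
        prop = np.nan
    else:
        prop = 100.0 * indirect / c
    return MediationResult(
        a=a, b=b, c=c, cprime=cprime, indirect=indirect,
        ci_low=float(ci_low), ci_high=float(ci_high), ci_level=ci_level,
        prop_mediated=prop, n=n, n_boot=n_boot, seed=seed,
        covariate_names=tuple(covariate_names), boot_indirect=boot_ind,
    )


def mediation_from_correlations(r_xm: float, r_my: float, r_xy: float) -> dict:
    """Standardized path algebra from a printed 3-variable correlation matrix.

    For standardized X, M, Y:
        a  = r_xm
        b  = (r_my - r_xy*r_xm) / (1 - r_xm^2)
        c' = (r_xy - r_my*r_xm) / (1 - r_xm^2)
        c  = r_xy,   indirect = a*b,   prop = 100*a*b/c.

    Useful for checking a reported mediation decomposition against the
    correlation table it came from (no covariates).
    """
    denom = 1 - r_xm**2
    if denom <= 0:
        raise ValueError("|r_xm| must be < 1")
    a = r_xm
    b = (r_my - r_xy * r_xm) / denom
    cprime = (r_xy - r_my * r_xm) / denom
    indirect = a * b
    return {
        "a": a, "b": b, "cprime": cprime, "c": r_xy, "indirect": indirect,
        "prop_mediated_pct": 100.0 * indirect / r_xy if r_xy != 0 else np.nan,
    }


def subgroup_mediate(
    cohort: pd.DataFrame,
    x: str, m: str, y: str,
    split: str = "addiction_class",
    covariates: tuple = (),
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
    min_n: int = 30,
) -> dict:
    """Mediation within each level of a grouping column, plus a correlation
    screen (X-Y and M-Y Pearson r with p) so 'no X-Y association but M-Y
    present' patterns are visible.

    Subgroups with fewer than ``min_n`` complete cases are skipped with a
    warning. Returns {level: {"mediation": MediationResult, "screen": dict}}.
    """
    out = {}
    cols = [x, m, y, *covariates]
    for level, grp in sorted(cohort.groupby(split, observed=True)):
        data = grp.dropna(subset=cols)
        if len(data) < min_n:
            warnings.warn(f"subgroup {level!r}: only {len(data)} complete cases; skipped")
            continue
        cov = data[list(covariates)].to_numpy() if covariates else None
        # same seed in every subgroup: identical strata must give identical results
        res = mediate(
            data[x], data[m], data[y], covariates=cov,
            n_boot=n_boot, ci_level=ci_level, seed=seed,
            covariate_names=tuple(covariates),
        )
        r_xy, p_xy = stats.pearsonr(data[x], data[y])
        r_my, p_my = stats.pearsonr(data[m], data[y])
        out[level] = {
            "mediation": res,
            "screen": {"r_xy": float(r_xy), "p_xy": float(p_xy),
                       "r_my": float(r_my), "p_my": float(p_my), "n": len(data)},
        }
    return out
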