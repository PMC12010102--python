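"""Scale scoring, addiction classification and descriptive statistics.

Implements sum scoring of 6-point Likert scales (short-video addiction,
bullying victimization with verbal/physical/relational subdimensions,
positive/negative affect), the gender-specific addiction cutoff (33 for
females, 31 for males), Cronbach's alpha, Harman's single-factor test for
common-method bias, and the pooled-variance group comparisons a study of
this design reports (two-sample t from summary statistics, 2x2 chi-square
without continuity correction, pairwise Pearson correlation tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScaleDefinition",
    "DEFAULT_SCALES",
    "score_scale",
    "score_cohort",
    "classify_addiction",
    "cronbach_alpha",
    "harman_single_factor",
    "pearson_corr_matrix",
    "pooled_t_test",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """One summed Likert scale, optionally split into subscales.

    Parameters
    ----------
    name : str
        Scale label (column name of the resulting total).
    items : tuple of str
        Item column names, e.g. ``("sva_item01", ..., "sva_item10")``.
    response_range : tuple of int
        Inclusive valid response range, default 1..6.
    subscales : dict
        Mapping subscale name -> tuple of item ids; every subscale item
        must belong to ``items``.
    cutoffs : dict or None
        Gender-specific classification cutoffs, e.g. ``{"F": 33, "M": 31}``.
        A score >= cutoff classifies the subject as addicted.
    """

    name: str
    items: tuple
    response_range: tuple = (1, 6)
    subscales: dict = field(default_factory=dict)
    cutoffs: dict | None = None

    def __post_init__(self):
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"duplicate item ids in scale {self.name!r}")
        for sub, sub_items in self.subscales.items():
            extra = set(sub_items) - set(self.items)
            if extra:
                raise ValueError(
                    f"subscale {sub!r} items {sorted(extra)} not in scale {self.name!r}"
                )


def _items(prefix: str, n: int) -> tuple:
    return tuple(f"{prefix}_item{i:02d}" for i in range(1, n + 1))


def default_scales(
    n_sva: int = 10,
    n_vb: int = 4,
    n_pb: int = 4,
    n_rb: int = 4,
    n_na: int = 10,
    n_pa: int = 10,
) -> dict:
    """Study scale definitions with configurable item counts."""
    vb, pb, rb = _items("vb", n_vb), _items("pb", n_pb), _items("rb", n_rb)
    return {
        "SVA": ScaleDefinition(
            "SVA", _items("sva", n_sva), cutoffs={"F": 33, "M": 31}
        ),
        "BV": ScaleDefinition(
            "BV", vb + pb + rb, subscales={"VB": vb, "PB": pb, "RB": rb}
        ),
        "NA": ScaleDefinition("NA", _items("na", n_na)),
        "PA": ScaleDefinition("PA", _items("pa", n_pa)),
    }


DEFAULT_SCALES = default_scales()


def score_scale(items: pd.DataFrame, definition: ScaleDefinition) -> pd.DataFrame:
    """Sum-score one scale (and its subscales) for every subject.

    Subjects missing any item of the scale are scored NaN on the total and
    all subscales (listwise within the scale). Returns a DataFrame indexed
    like ``items`` with one column per total/subscale.
    """
    missing = set(definition.items) - set(items.columns)
    if missing:
        raise KeyError(
            f"scale {definition.name!r}: item columns not found: {sorted(missing)}"
        )
    block = items[list(definition.items)].astype(float)
    lo, hi = definition.response_range
    vals = block.to_numpy()
    with np.errstate(invalid="ignore"):
        out_of_range = np.nanmin(vals) < lo or np.nanmax(vals) > hi
    if out_of_range:
        raise ValueError(
            f"scale {definition.name!r}: responses outside {lo}..{hi}"
        )
    complete = block.notna().all(axis=1)
    out = pd.DataFrame(index=items.index)
    out[definition.name] = block.sum(axis=1).where(complete)
    for sub, sub_items in definition.subscales.items():
        out[sub] = block[list(sub_items)].sum(axis=1).where(complete)
    return out


def score_cohort(
    table: pd.DataFrame,
    scales: dict | None = None,
    demographics: tuple = ("age", "gender", "group", "mother_edu", "father_edu", "fd"),
) -> pd.DataFrame:
    """Score every scale and attach demographics and the addiction class.

    ``table`` is the item-level questionnaire (one row per subject). The
    returned scored cohort carries scale totals, subscale totals, any
    demographic columns present, and ``addiction_class`` from the SVA
    cutoffs when an SVA scale with cutoffs is defined.
    """
    scales = DEFAULT_SCALES if scales is None else scales
    parts = [score_scale(table, d) for d in scales.values()]
    scored = pd.concat(parts, axis=1)
    for col in demographics:
        if col in table.columns:
            scored[col] = table[col]
    sva = scales.get("SVA")
    if sva is not None and sva.cutoffs and "gender" in scored.columns:
        scored["addiction_class"] = classify_addiction(
            scored[sva.name], scored["gender"], cutoffs=sva.cutoffs
        )
    return scored


def classify_addiction(
    score, gender, cutoffs: dict | None = None
):
    """Classify addicted vs nonaddicted by gender-specific cutoff (>=).

    ``score`` and ``gender`` may be scalars or aligned vectors; gender must
    be 'M' or 'F'. Returns 'addicted' / 'nonaddicted' (NaN score -> NaN).
    """
    cutoffs = {"F": 33, "M": 31} if cutoffs is None else cutoffs
    score_arr = pd.Series(score) if np.isscalar(score) else pd.Series(score)
    gender_arr = pd.Series([gender] * len(score_arr)) if isinstance(gender, str) else pd.Series(gender)
    gender_arr.index = score_arr.index
    bad = ~gender_arr.isin(list(cutoffs))
    if bad.any():
        raise ValueError(
            f"gender must be one of {sorted(cutoffs)}; got {sorted(gender_arr[bad].unique())}"
        )
    cut = gender_arr.map(cutoffs).astype(float)
    out = pd.Series(
        np.where(score_arr >= cut, "addicted", "nonaddicted"), index=score_arr.index
    )
    out = out.where(score_arr.notna())
    if np.isscalar(score):
        return out.iloc[0]
    return out


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha for one scale's item block (complete cases).

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total),
    with unbiased (n-1) sample variances.
    """
    x = np.asarray(items, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("cronbach_alpha needs >= 2 items and >= 3 subjects")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero variance of the scale total; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1 - item_var / total_var)


def harman_single_factor(items: pd.DataFrame | np.ndarray) -> tuple[int, float]:
    """Harman's single-factor common-method-bias test.

    Unrotated principal-component extraction over all study items on
    complete cases: eigen-decompose the item correlation matrix and report
    (number of eigenvalues > 1, percent of total variance explained by the
    first factor). Bias is conventionally flagged when the first factor
    exceeds 40%.
    """
    x = np.asarray(items, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more complete cases than items")
    r = np.corrcoef(x, rowvar=False)
    if not np.all(np.isfinite(r)):
        raise ValueError("singular/degenerate item correlation matrix")
    eigvals = np.linalg.eigvalsh(r)[::-1]
    n_gt1 = int(np.sum(eigvals > 1))
    first_pct = 100.0 * eigvals[0] / x.shape[1]
    return n_gt1, first_pct


def pearson_corr_matrix(
    scored: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation table with two-sided p-values.

    Rows with any missing value among ``variables`` are dropped (listwise).
    Returns (r, p) square DataFrames.
    """
    data = scored[variables].dropna()
    n = len(data)
    if n < 3:
        raise ValueError("need >= 3 complete cases")
    arr = data.to_numpy(dtype=float)
    if np.any(arr.std(axis=0) == 0):
        const = [v for v, s in zip(variables, arr.std(axis=0)) if s == 0]
        raise ValueError(f"constant variable(s): {const}; r undefined")
    r = np.corrcoef(arr, rowvar=False)
    # two-sided p from the t transform, df = n-2
    rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = rr * np.sqrt((n - 2) / (1 - rr**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    idx = pd.Index(variables)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Student's pooled-variance two-sample t from summary statistics.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2. Pooled (not Welch)
    variance matches degrees of freedom printed as n1+n2-2 in group tables.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance; t undefined")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=df)
    return float(t), int(df), float(p)


def chi_square_2x2(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (chi2, df=1, p). Expected counts must all be positive.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if obs.sum() <= 0 or np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal; chi-square undefined")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if np.any(expected <= 0):
        raise ValueError("nonpositive expected count")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, 1, p
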