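"""Synthetic cohorts with known ground truth.

Two generators provide the test bed for every downstream stage:

* ``gen_questionnaire_cohort`` draws latent traits from the mediation
  structural model  BV -> NA -> SVA  (standardized paths a, b, c'), turns
  each latent into 6-point Likert items by equiprobable-threshold
  discretization, and attaches demographics. All latents are unit
  variance, so the generating paths are directly the standardized
  regression coefficients an analysis should recover.

* ``gen_resting_parcels`` builds BOLD-like parcel x voxel x time signals
  as band-limited sums of sinusoids (0.01-0.1 Hz) plus white noise. In
  designated parcels the sinusoid amplitudes scale with a subject trait
  (amplitude coupling, detectable by ALFF-trait association); in others
  the voxel-amplitude pattern mixes a behavior-driven component with an
  idiosyncratic one (pattern coupling, detectable by inter-subject RSA).

Reproducibility: each generator owns one RNG stream seeded from
``SeedSequence([stream_id, seed])`` with stream 0 for the questionnaire
(PCG64) and stream 1 for the neural generator (SFC64, chosen for bulk
normal-draw speed), so the two never share draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenParams",
    "NeuroGenParams",
    "ParcelTimeseriesSet",
    "implied_latent_corr",
    "gen_questionnaire_cohort",
    "gen_resting_parcels",
]

_Q_STREAM = 0
_N_STREAM = 1


@dataclass(frozen=True)
class GenParams:
    """Questionnaire generator parameters (standardized path scale)."""

    n_subjects: int = 1000
    a_true: float = 0.4        # BV -> NA
    b_true: float = 0.3        # NA -> SVA given BV
    cprime_true: float = 0.18  # BV -> SVA given NA
    item_loading: float = 0.8
    n_items: dict = field(
        default_factory=lambda: {"sva": 10, "vb": 4, "pb": 4, "rb": 4, "na": 10, "pa": 10}
    )
    likert_levels: int = 6
    seed: int = 0
    female_prop: float = 0.5915
    group: str = "CS"

    def __post_init__(self):
        if self.likert_levels < 2:
            raise ValueError("likert_levels must be >= 2")
        if not 0 <= self.item_loading <= 1:
            raise ValueError("item_loading must lie in [0, 1]")
        c = self.c_true
        if not -1 < c < 1:
            raise ValueError(f"implied total effect c = {c:.3f} outside (-1, 1)")
        if self.resid_var_na <= 0 or self.resid_var_sva <= 0:
            raise ValueError(
                "paths imply a non-positive-definite latent covariance "
                f"(residual variances {self.resid_var_na:.3f}, {self.resid_var_sva:.3f})"
            )

    @property
    def c_true(self) -> float:
        """Implied total effect c = c' + a*b."""
        return self.cprime_true + self.a_true * self.b_true

    @property
    def resid_var_na(self) -> float:
        return 1.0 - self.a_true**2

    @property
    def resid_var_sva(self) -> float:
        a, b, cp = self.a_true, self.b_true, self.cprime_true
        return 1.0 - (cp**2 + b**2 + 2 * a * b * cp)


def implied_latent_corr(p: GenParams) -> np.ndarray:
    """Closed-form correlation matrix of (BV, NA, SVA) latents.

    With unit-variance latents: corr(BV,NA)=a, corr(BV,SVA)=c'+ab,
    corr(NA,SVA)=b+a*c'.
    """
    a, b, cp = p.a_true, p.b_true, p.cprime_true
    r_bn = a
    r_bs = cp + a * b
    r_ns = b + a * cp
    return np.array([[1, r_bn, r_bs], [r_bn, 1, r_ns], [r_bs, r_ns, 1.0]])


def _discretize(x: np.ndarray, levels: int) -> np.ndarray:
    """Map standard-normal values to 1..levels via equiprobable thresholds."""
    from scipy.stats import norm

    thresholds = norm.ppf(np.arange(1, levels) / levels)
    return 1 + np.searchsorted(thresholds, x, side="left").astype(np.int64)


def gen_questionnaire_cohort(p: GenParams) -> tuple[pd.DataFrame, dict]:
    """Generate an item-level questionnaire table plus its truth record.

    Returns ``(table, truth)``. The table has one row per subject with
    subject_id, demographics (age, gender, group, mother_edu, father_edu,
    fd) and integer item columns named ``<scale>_item##``. The truth
    record stores the generating parameters, the latent values (for
    unattenuated parameter-recovery checks) and the seed.
    """
    rng = np.random.default_rng([_Q_STREAM, p.seed])
    n = p.n_subjects
    a, b, cp = p.a_true, p.b_true, p.cprime_true

    bv = rng.standard_normal(n)
    na = a * bv + np.sqrt(p.resid_var_na) * rng.standard_normal(n)
    sva = cp * bv + b * na + np.sqrt(p.resid_var_sva) * rng.standard_normal(n)
    pa = rng.standard_normal(n)  # scored but structurally independent
    latent_of = {"sva": sva, "vb": bv, "pb": bv, "rb": bv, "na": na, "pa": pa}

    lam = p.item_loading
    resid = np.sqrt(1 - lam**2)
    table = {}
    for scale, k in p.n_items.items():
        latent = latent_of[scale]
        for i in range(1, k + 1):
            raw = lam * latent + resid * rng.standard_normal(n)
            table[f"{scale}_item{i:02d}"] = _discretize(raw, p.likert_levels)

    gender = np.where(rng.random(n) < p.female_prop, "F", "M")
    age_lo, age_hi = (12, 16) if p.group == "MSS" else (17, 24)
    demo = {
        "subject_id": [f"S{i:05d}" for i in range(1, n + 1)],
        "age": rng.integers(age_lo, age_hi + 1, size=n),
        "gender": gender,
        "group": p.group,
        "mother_edu": rng.integers(1, 6, size=n),
        "father_edu": rng.integers(1, 6, size=n),
        "fd": np.round(rng.lognormal(mean=-2.0, sigma=0.4, size=n), 4),
    }
    df = pd.DataFrame({**demo, **table})
    truth = {
        "params": p,
        "seed": p.seed,
        "latents": pd.DataFrame(
            {"bv": bv, "na": na, "sva": sva, "pa": pa}, index=df["subject_id"]
        ),
        "implied_corr": implied_latent_corr(p),
    }
    return df, truth


@dataclass(frozen=True)
class NeuroGenParams:
    """Resting-state-like signal generator parameters."""

    n_subjects: int = 100
    n_parcels: int = 200
    n_voxels_per_parcel: int = 16
    n_timepoints: int = 300
    tr_seconds: float = 2.0
    coupling_parcels: tuple = ()
    coupling_strength: float = 0.0
    pattern_coupling_parcels: tuple = ()
    pattern_strength: float | None = None  # defaults to coupling_strength
    noise_sd: float = 1.0
    n_sinusoids: int = 5
    base_amplitude: float = 1.0
    seed: int = 0
    band: tuple = (0.01, 0.1)

    def __post_init__(self):
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_band_bins < 3:
            raise ValueError(
                f"band {self.band} contains only {self.n_band_bins} frequency "
                "bins on this grid; need >= 3 (lengthen the run or widen the band)"
            )

    @property
    def n_band_bins(self) -> int:
        freqs = np.fft.rfftfreq(self.n_timepoints, d=self.tr_seconds)
        lo, hi = self.band
        return int(np.sum((freqs >= lo) & (freqs <= hi)))

    @property
    def pattern_weight(self) -> float:
        w = self.coupling_strength if self.pattern_strength is None else self.pattern_strength
        return float(np.clip(w, 0.0, 1.0))


@dataclass
class ParcelTimeseriesSet:
    """Per-subject parcel x voxel x timepoint signals on a shared grid."""

    data: np.ndarray  # (n_subjects, n_parcels, n_voxels, n_timepoints)
    tr_seconds: float
    subject_ids: list
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("data must be (subjects, parcels, voxels, timepoints)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length must match data")

    @property
    def n_subjects(self):
        return self.data.shape[0]

    @property
    def n_parcels(self):
        return self.data.shape[1]


def gen_resting_parcels(
    p: NeuroGenParams,
    trait: np.ndarray,
    item_profile: np.ndarray | None = None,
) -> tuple[ParcelTimeseriesSet, dict]:
    """Generate band-limited signals with planted trait coupling.

    Parameters
    ----------
    trait : (n_subjects,) array
        Behavioral trait (e.g. SVA total). In ``coupling_parcels`` the
        sinusoid amplitudes scale with ``1 + coupling_strength * z(trait)``.
    item_profile : (n_subjects, n_items) array, optional
        Item-level behavior used for pattern coupling; behaviorally
        similar subjects receive similar voxel-amplitude patterns in
        ``pattern_coupling_parcels``. Defaults to the trait as a single
        column.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.shape != (p.n_subjects,):
        raise ValueError("trait length must equal n_subjects")
    if item_profile is None:
        item_profile = trait[:, None]
    item_profile = np.asarray(item_profile, dtype=float)
    if item_profile.shape[0] != p.n_subjects:
        raise ValueError("item_profile rows must equal n_subjects")

    # SFC64: much faster bulk normal generation than the default bit
    # generator, which matters for the multi-replicate simulations
    rng = np.random.Generator(
        np.random.SFC64(np.random.SeedSequence([_N_STREAM, p.seed]))
    )
    n_s, n_p, n_v, n_t = p.n_subjects, p.n_parcels, p.n_voxels_per_parcel, p.n_timepoints
    k = p.n_sinusoids
    t = np.arange(n_t) * p.tr_seconds

    z = (trait - trait.mean()) / trait.std() if trait.std() > 0 else np.zeros(n_s)
    gain = np.ones(n_s)
    coupled = np.zeros(n_p, dtype=bool)
    coupled[list(p.coupling_parcels)] = True
    patterned = np.zeros(n_p, dtype=bool)
    patterned[list(p.pattern_coupling_parcels)] = True

    # standardized item profile -> unit-variance behavioral scores per voxel
    prof = item_profile - item_profile.mean(axis=0)
    prof_sd = prof.std(axis=0)
    prof_sd[prof_sd == 0] = 1.0
    prof = prof / prof_sd
    w = p.pattern_weight

    data = np.empty((n_s, n_p, n_v, n_t), dtype=np.float32)
    for parcel in range(n_p):
        freqs = rng.uniform(*p.band, size=k)
        basis = np.concatenate(
            [np.cos(2 * np.pi * freqs[:, None] * t), np.sin(2 * np.pi * freqs[:, None] * t)]
        ).astype(np.float32)  # (2k, n_t)

        amp = p.base_amplitude * np.abs(rng.normal(1.0, 0.3, size=(n_s, n_v, k)))
        if coupled[parcel]:
            g = np.clip(1.0 + p.coupling_strength * z, 0.05, None)
            amp *= g[:, None, None]
        # voxel gain field: behavior-driven mixture in patterned parcels
        idio = rng.standard_normal((n_s, n_v))
        if patterned[parcel] and w > 0:
            mix = rng.standard_normal((prof.shape[1], n_v)) / np.sqrt(prof.shape[1])
            behav = prof @ mix
            behav_sd = behav.std()
            if behav_sd > 0:
                behav = behav / behav_sd
            field = np.sqrt(w) * behav + np.sqrt(1 - w) * idio
        else:
            field = idio
        amp *= np.exp(0.5 * field)[:, :, None]

        phase = rng.uniform(0, 2 * np.pi, size=(n_s, n_v, k))
        coeff = np.concatenate([amp * np.cos(phase), amp * np.sin(phase)], axis=2)
        signal = coeff.astype(np.float32) @ basis
        noise = rng.standard_normal((n_s, n_v, n_t), dtype=np.float32)
        data[:, parcel] = signal + p.noise_sd * noise

    subject_ids = [f"S{i:05d}" for i in range(1, n_s + 1)]
    pts = ParcelTimeseriesSet(data=data, tr_seconds=p.tr_seconds, subject_ids=subject_ids)
    truth = {
        "params": p,
        "seed": p.seed,
        "trait": trait,
        "coupling_parcels": tuple(p.coupling_parcels),
        "pattern_coupling_parcels": tuple(p.pattern_coupling_parcels),
    }
    return pts, truth
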