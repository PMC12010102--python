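# Methods

## Structural model and questionnaire generator

The questionnaire generator (`svamech.synthetic.gen_questionnaire_cohort`)
draws unit-variance latent traits per subject:

- `bv ~ N(0, 1)`
- `na = a·bv + e₁`, with `Var(e₁) = 1 − a²`
- `sva = c'·bv + b·na + e₂`, with
  `Var(e₂) = 1 − (c'² + b² + 2·a·b·c')`

so all three latents have exactly unit variance and the implied total
effect is `c = c' + a·b`. Defaults `a = 0.4`, `b = 0.3`, `c' = 0.18` give
an indirect effect of 0.12 and a proportion mediated of 40%, magnitudes
typical of adolescent survey studies of this question. The constructor
rejects parameter combinations whose implied residual variances are not
positive.

Items are generated as `loading·latent + √(1 − loading²)·noise`
(default loading 0.8) and discretized to a 6-point Likert scale with
equiprobable thresholds `Φ⁻¹(k/6)`. All 12 bullying items (three 4-item
subscales: verbal, physical, relational) load on the single BV latent;
the 10 positive-affect items load on an independent latent and act as a
discriminant-validity control. Demographics (age, gender, group, parental
education, head motion `fd`) are generated independently of the latents;
the female proportion defaults to 0.5915.

**What the generator emulates:** sum-score reliabilities near 0.94,
scale intercorrelations near the 0.3–0.4 range, a Harman first factor
well under 40%, realistic addiction rates under the gender-specific
cutoffs. **What it does not emulate:** item-level residual correlations,
differential item functioning, floor/ceiling asymmetries, missingness
mechanisms, or any true dependence of demographics on the traits.
Consequently observed sum-score paths are attenuated relative to the
latent paths by roughly the product of the scale reliabilities;
parameter-recovery checks therefore run on the stored latents, and the
attenuation itself is verified against the closed-form
`r_obs ≈ a·√(rel_BV·rel_NA)`.

## Neural generator

`gen_resting_parcels` builds per-parcel BOLD-like signals as a shared
basis of K = 5 cosine/sine pairs with frequencies drawn uniformly in the
ALFF band (0.01–0.1 Hz), combined per subject/voxel with random
amplitudes and phases via a single matrix multiply, plus white noise
(σ = 1). Sharing the sinusoid basis within a parcel is what gives voxel
patterns subject-level structure for IS-RSA while keeping generation a
GEMM rather than per-voxel loops.

Two couplings can be planted:

- **Amplitude coupling** (detected by trait–ALFF association): the
  sinusoid amplitude in selected parcels is scaled by
  `g = clip(1 + strength·z(trait), 0.05, ∞)`.
- **Pattern coupling** (detected by IS-RSA): a voxel gain field
  `exp(0.5·(√w·(z-profile @ M) + √(1−w)·idio))` mixes a projection of
  the subject's z-scored item profile with idiosyncratic noise, so
  subjects with similar item profiles get similar multivoxel ALFF
  patterns in the selected parcels.

Questionnaire and neural data use independent RNG streams derived from
`SeedSequence([stream_id, seed])`; the neural stream uses the SFC64 bit
generator because bulk float32 normal generation dominates its runtime.
Defaults (16 voxels/parcel, 300 timepoints at TR = 2 s) keep a
100-subject × 200-parcel simulation around 2–3 s while leaving ≥ 3
frequency bins inside the band, the minimum the constructor enforces.

## ALFF

Time series are linearly detrended by exact projection onto an
orthonormal `[1, t]` basis (a GEMM, idempotent to machine precision),
then transformed with a real FFT; the single-sided amplitude spectrum is
`2|X(f)|/N` and ALFF is the **mean** amplitude over the inclusive band
`[0.01, 0.1]` Hz (band edges matched with 1e-9 tolerance). Oracles
enforced by tests: a constant series gives exactly 0; ALFF is homogeneous
of degree 1; a pure out-of-band sinusoid at 0.2 Hz leaks ≤ 1% of an
in-band tone on the default grid; white-noise ALFF matches the analytic
expectation `σ√(π/N)`. Processing is chunked (8192 rows) so detrend and
FFT stay cache-resident.

## Mediation

Three OLS regressions (NA on BV; SVA on BV; SVA on BV + NA, plus any
covariates) give `a`, `c`, and `(c', b)`. The decomposition
`c = c' + a·b` holds as an algebraic identity of OLS and is asserted to
1e-10 on every fit. Inference on `a·b` uses the percentile case
bootstrap (default 5000 resamples) — resampling subjects, not residuals —
because the product of coefficients is not normal in finite samples.
Bootstrap fits solve batched normal equations via `np.linalg.solve` in
chunks of 256 resamples, falling back to `lstsq` on singular resamples.
Simulation checks: at n = 1000 the 95% percentile CI covers the true
indirect effect in 93–97% of replicates; estimates at n = 5000 recover
the latent paths within ±0.05. The proportion mediated `100·a·b/c` is
reported as NaN when |c| < 1e-12. Subgroup analyses reuse the same
bootstrap seed in every stratum so identical strata give identical
results.

## IS-RSA and Mantel

Behavioral RDMs are Euclidean distances over the 10 SVA item responses;
neural RDMs are `1 − Pearson` over voxel ALFF patterns per parcel. The
IS-RSA statistic is the Pearson correlation of the strictly lower
triangles (n(n−1)/2 pairs). The parametric p-value treats those pairs as
independent, which they are not — it is anticonservative, which the null
simulation in the test suite demonstrates — so it is reported only as a
screening value with Bonferroni correction over parcels, and the Mantel
permutation test (joint row/column permutation of one RDM,
`p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)`, one-sided) is the
inferential follow-up. The permutation null is calibrated: across 500
independent-RDM replicates its p-values pass a KS uniformity test.
Power: with pattern coupling of strength 0.5 planted in 2 of 200 parcels
at n = 100, both parcels rank in the IS-RSA top 5 and survive Bonferroni
in ≥ 80% of replicates.

## Statistical conventions

- Group comparisons from summary statistics use the pooled-variance
  t test (df = n₁ + n₂ − 2), not Welch.
- The 2×2 chi-square uses the Pearson statistic **without** continuity
  correction.
- Addiction classification uses inclusive gender-specific cutoffs:
  female ≥ 33, male ≥ 31 on the SVA sum score.
- Harman's single-factor test extracts unrotated principal components
  from the item correlation matrix; a first factor above 40% flags
  possible common-method bias.
- Multiple-comparison corrections: Bonferroni (default) or
  Benjamini–Hochberg FDR via statsmodels.

## Limitations

- Generators produce multivariate-normal latents; heavy tails, response
  styles, and clustered sampling (schools, classrooms) are not modeled.
- Mediation estimates are associational; the bootstrap quantifies
  sampling uncertainty, not causal identification.
- The BOLD model omits hemodynamics, autocorrelated (1/f) noise, motion
  artifacts, and spatial smoothness; it is a test bed for the estimators,
  not a biophysical simulator.
- IS-RSA uses a single distance metric per domain; rank-based variants
  (Spearman RDM correlation) are not implemented.
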