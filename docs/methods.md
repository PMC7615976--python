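# Methods

## The model

targetmr estimates the causal effect of a modifiable exposure (the
motivating case: LDL cholesterol) on an outcome (stroke subtypes, brain
small-vessel-disease imaging biomarkers) from two-sample GWAS summary
statistics, using genetic variants as instrumental variables.  All
estimators are derived under the linear instrumental-variable
summary-statistic model: variant *j* has true exposure effect γ_j and
direct (pleiotropic) outcome effect α_j, and the true outcome effect is

    Γ_j = θ·γ_j + α_j .

A variant is a *valid* instrument when α_j = 0; then its Wald ratio
θ_j = β_Yj/β_Xj estimates θ, with first-order standard error
σ_θj = σ_Yj/|β_Xj| (the uncertainty in β_Xj is neglected, the usual
convention when instruments are strong).  Exposure and outcome effects
come from non-overlapping samples, so their estimation errors are
independent.

In *drug-target* mode, instruments are restricted to variants in or near
the gene encoding a drug's target (cis variants, region ± flank), so that
θ proxies pharmacological modulation of the exposure through that target
rather than the exposure at large.

## Estimators

- **IVW** — θ̂ = Σ w_j β_Xj β_Yj / Σ w_j β_Xj², w_j = 1/σ_Yj²: the
  through-origin weighted regression of outcome on exposure effects.
  Fixed-effect SE = (Σ w_j β_Xj²)^{-1/2}.  The default *multiplicative
  random-effects* model inflates this SE by max(1, √(Q/(J−1))) with Q the
  Cochran heterogeneity statistic; the clamp at 1 means heterogeneity can
  only widen, never narrow, the interval.  A single instrument degenerates
  to its Wald ratio (labelled so in the output).
- **MR-Egger** — instruments are oriented so every β_Xj ≥ 0 (negating both
  effects, which leaves the Wald ratio unchanged), then β_Y is regressed
  on β_X *with an intercept* (weights 1/σ_Yj²).  The intercept estimates
  the average directional pleiotropic effect under the InSIDE assumption
  (instrument strength independent of direct effects); the slope is the
  pleiotropy-adjusted causal estimate.  Both SEs are inflated by
  max(1, √(RSS_w/(J−2))).  Inference uses normal rather than t quantiles,
  consistent with the IVW convention here; at typical instrument counts
  the difference is small, and the choice is isolated in one place.
- **Weighted median** — the 50% weighted quantile of the Wald ratios
  (weights ∝ σ_θj⁻², cumulative-midpoint interpolation), consistent when
  instruments carrying ≥ 50% of the weight are valid.  Its SE comes from a
  parametric bootstrap, θ_j* ~ N(θ_j, σ_θj²), default 1000 draws, seeded.
- **Contamination mixture** — each instrument is modelled as valid
  (θ_j ~ N(θ, σ_θj²)) or invalid (θ_j ~ N(0, σ_θj² + ψ²)); the profile
  log-likelihood takes the larger of the two log-densities per variant and
  is maximised over a uniform grid (default 2001 points spanning the ratio
  range ± 3 SD; ties go to the smallest candidate, for determinism).
  ψ defaults to 1.5 × SD of the ratios ("auto"), falling back to 1 with a
  warning when that SD is 0; the value used is always recorded in the
  result's extras, together with the valid-variant classification at the
  optimum.  Inference is by likelihood-ratio inversion at the χ²₁ 95%
  cut-off (3.841); the confidence region can be a union of disjoint
  intervals and is reported as such — no SE or p-value is attached.

All single-interval 95% CIs use the conventional multiplier 1.96.

## Instrument selection and harmonization

Candidates passing the p-value threshold are greedily clumped: best p
first (ties broken lexicographically by variant id, so runs are
reproducible), discarding everything with r² above the threshold against
a kept variant.  Defaults — p ≤ 5×10⁻⁸, r² ≤ 0.1, cis flank 100 kb — are
the field-standard drug-target settings and are fully configurable; they
are deliberately not presented as any particular study's values.
Variants absent from the LD matrix are treated as uncorrelated and
logged.  Cis selection converts 1-based summary-statistic positions to
the 0-based half-open BED convention before windowing.

Harmonization aligns the outcome record onto the exposure's effect
allele: direct match, swap (negate), strand complement, or
complement-swap; anything else is dropped with a log entry.  Palindromic
variants (A/T, C/G) cannot be strand-resolved from alleles alone: policy
`drop` removes them, the default policy `infer` keeps those whose effect
allele frequencies are both outside 0.5 ± 0.08 and aligns by frequency
concordance, dropping the rest.  Variants with β_X = 0 are dropped
(undefined ratio).

Instrument strength is summarised by the mean F statistic,
F_j = β_Xj²/σ_Xj², with mean F > 10 the conventional adequacy threshold.

## Diagnostics

Cochran's Q = Σ w_j (β_Yj − θ̂ β_Xj)² about the fixed-effect IVW fit,
referred to χ²(J−1); per-variant contributions are returned alongside.
Note the first-order weights neglect the exposure-side term θ²σ_Xj² of
the residual variance: when θ ≠ 0 and the exposure sample is not much
larger than the outcome sample, Q is inflated by a factor of roughly
1 + θ²σ_X²/σ_Y², and its type-I error exceeds the nominal level (about
12% instead of 5% at θ = 0.3 with equal samples of 10⁵).  Calibration is
therefore assessed under the global null (θ = 0), where the χ² reference
is exact; with real data this means Q should be read as slightly
anti-conservative for strongly causal exposure-outcome pairs.  The Egger
intercept test re-exports the intercept fit above.  The
exclusion-sensitivity workflow (variants flagged by an external
phenome-wide lookup, supplied as a plain-text id list) removes the
flagged instruments and reruns all estimators, reporting paired
before/after estimates; a method that falls below its instrument minimum
is reported as unavailable rather than failing the run.

## Study pipeline

`run_study` crosses every unit of analysis (genome-wide and/or each gene
target) with every outcome: select → harmonize → mean F → estimators →
diagnostics → rescale → OR conversion.  Effects are reported per 1 unit
*decrease* of the exposure by default, with `sd_to_unit` (default 38.67,
≈ 1 SD of LDL-c in mg/dL) converting SD-scaled GWAS effects to the
reporting unit; binary-outcome effects (log-odds) are exponentiated to
odds ratios after rescaling.  Benjamini–Hochberg q-values are computed
over the IVW p-values of all unit × outcome pairs in the run — IVW is the
main analysis, the sensitivity estimators are reported unadjusted — and
the family actually used is written to the run log, since reasonable
alternatives (within-target, within-outcome) exist.  A pair with no
surviving instruments yields an NA row and a logged reason; the run
continues.  Given a config (including its seed), outputs are byte-for-byte
reproducible.

## The simulator

`simulate_two_sample` draws, per variant: EAF uniform in `maf_range`
(default 0.05–0.5); |γ_j| uniform in `exposure_effect_range` (default
0.05–0.15 per SD, i.e. roughly 0.2–1.7% of variance per variant at these
frequencies — a realistic cis-instrument strength) with random sign
(`random_sign=False` makes all effects positive, the textbook condition
under which the Egger intercept is consistent for a directional
pleiotropy mean — with random-sign γ the orientation step averages the
pleiotropy to zero); α_j ~ N(pleiotropy_mean, pleiotropy_sd²) for the
round(invalid_fraction·J) variants chosen by a seeded shuffle, 0
otherwise.  Observed effects add independent Gaussian noise with the
standardized-trait SE 1/√(2p(1−p)n) per sample (defaults n = 10⁵ each).
Validity flags are defined as α_j = 0 exactly.  `correlated_pleiotropy`
introduces cor(α, γ) ≠ 0 among invalid variants to probe InSIDE
violation.  Binary outcomes reuse the Gaussian summary-statistic
approximation on the log-odds scale — two-sample MR consumes only
summary statistics, so no individual-level logistic simulation is needed.
Alleles are drawn from non-palindromic pairs so the default harmonization
policy keeps every simulated variant.

What the simulator does *not* emulate: LD-correlated effect estimates
(the block LD matrix drives clumping, but estimation noise is drawn
independently per variant), winner's curse from in-sample instrument
discovery, sample overlap between the two GWAS, population stratification,
and allele-frequency differences between samples.  Passing tests
therefore validate the estimators and the pipeline under the model they
assume, not robustness to those real-data artefacts.

`simulate_ld_blocks` builds a block-constant correlation matrix (within
r, between 0), which is positive semi-definite for any r in [0, 1); it is
fully deterministic, the seed argument being accepted only for interface
uniformity.  `simulate_study` composes gene regions, a shared exposure
draw per gene, per-outcome effects with per-(gene, outcome) θ, and a
block LD matrix into a ready-to-run study on disk.

## Validation surface and problem sizes

The test suite and `scripts/acceptance.py` check, at desk scale:
closed-form agreement of IVW/Egger/Q/BH with direct normal-equation and
step-up evaluations (≤ 4 instruments, tolerance 1e−10); parameter
recovery (50 variants, n = 10⁵/10⁵, θ = 0.3, 200 replicates: median IVW
within 0.01, CI coverage 92–98%); type-I calibration of Q and the Egger
intercept under the global null (500 replicates, band 2–9%); null-study
FDR (200 simulated 2-gene × 2-outcome studies, ≤ 8% significant rows);
robustness ordering under 30% directional contamination (weighted median
and contamination mixture strictly closer to θ than IVW in median
absolute error, 200 replicates); an end-to-end protective drug-target
study (3 genes × 1 binary outcome, n = 2×10⁵, 100 replicates) measuring
detection power and the reported OR; and byte-identical reruns.  These
sizes keep the full suite to a few minutes on one core while leaving
Monte-Carlo error well inside the asserted bands.

## Known limitations

- First-order Wald-ratio SEs and the Q inflation noted above; a
  second-order option is a natural extension hook.
- No proxy-variant search, Steiger directionality filtering, MR-PRESSO,
  multivariable MR or colocalization; exclusion lists replace live
  phenome-scan queries.
- The ConMix grid is bounded by the observed ratio range ± 3 SD; a true
  effect far outside the ratio cloud (impossible when most instruments
  are valid) would be clipped to the grid edge.
- LD clumping assumes the supplied correlation matrix is on the same
  allele orientation as the summary statistics; only r² is consumed, so
  orientation errors do not propagate.
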