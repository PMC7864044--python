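# Methods

This document records the statistical model behind each analysis
stage, the default parameters and their rationale, what the synthetic
generators do and do not emulate, and the numerical choices that are
not obvious from the code.

## 1. Star-model arithmetic

A star model is a multiset of chain lengths `{ℓ₁ ≥ … ≥ ℓ_k}`,
`1 ≤ k ≤ n_sites` (default 6), where chain `i` consists of `ℓᵢ`
cytochrome units attached to one core site. With `U = Σ ℓᵢ` total
units:

- each chain contributes exactly one heme to a core site (the terminal
  tethered heme) and `ℓᵢ − 1` hemes to cytochrome pockets, plus each
  non-terminal unit's pocket is filled by its neighbour's heme — net
  result: `k` hemes in core sites, `U − k` in cytochrome pockets;
- heme-location fractions are therefore exact rationals,
  `f_cyt = (U−k)/U` and `f_hthp = k/U`, kept as `fractions.Fraction`
  and only rounded for display.

`partitions_exact(U, k)` enumerates partitions of `U` into exactly `k`
positive parts recursively in canonical (non-increasing) order; a
lower bound `ceil(remaining/parts_left)` on the next part prunes the
recursion. The test suite checks it against an independent
brute-force enumerator for all `U ≤ 20`, `k ≤ 6`.

## 2. Spectral unmixing

Model: a mixture spectrum `m(λ)` on the fit window (default
350–700 nm, covering Soret and Q/charge-transfer bands while skipping
the far-UV protein region) is `f·a(λ) + (1−f)·b(λ) + ε`, with `a`, `b`
the unit-area-normalized basis spectra of the two heme environments
and iid noise `ε`. Least squares has the closed form

    f* = Σ (m−b)(a−b) / Σ (a−b)²,

clipped to `[0, 1]` (the physical range; clipping is flagged). The
delta-method standard error uses the residual variance
`sse/(n−1)` (one fitted parameter):

    sd_f = sqrt( sse/(n−1) / Σ (a−b)² ).

A 0.001-step grid search over `f` is kept as an independent oracle;
the closed form matches it to within one step on noisy data.
Unit-area normalization (trapezoidal integral = 1 on the window)
makes `f` a heme-count fraction under the assumption of equal
integrated per-heme extinction for the two environments.

Absorbances are *not* required to be non-negative: baseline-subtracted
experimental spectra (and additive-noise synthetic ones) dip slightly
below zero, and clipping them would bias the fit.

## 3. Gel densitometry

- Lane profiles: identical-size rectangular ROIs (validated equal,
  in-bounds, non-overlapping), grayscale inverted (`max − pixel`) and
  summed across the lane width, so stained bands become positive
  peaks.
- Baseline: a straight line through the medians of two flanking
  anchor regions (`flank_width ≥ 3` rows) on either side of the band
  window, subtracted before integration. Medians resist single-pixel
  outliers in the flanks.
- Peak area: trapezoidal integral of the baseline-corrected profile
  over the band window, with negative excursions clipped to zero
  (noise below the baseline should not cancel band signal).
- Calibration: ordinary least squares of area on ladder concentration
  (`scipy.stats.linregress`, ≥ 3 distinct concentrations), residual
  sd on `n − 2` degrees of freedom.
- Inverse prediction: `c₀ = (A₀ − intercept)/slope`, clipped at zero,
  flagged `extrapolated` outside the ladder range, with the standard
  first-order inverse-prediction error

      sd = (s/|slope|) · sqrt(1/m + 1/n + (c₀ − c̄)² / S_cc),

  where `m` is the number of replicate sample lanes averaged at the
  area level. This assumes homoscedastic area noise; under
  multiplicative (CV-type) noise it is approximate but empirically
  conservative at mid-ladder concentrations (≥ 90 % two-sd coverage at
  CV 0.15 in the acceptance tests).

## 4. Stoichiometry inference

`U = n_sites · c_cyt / c_hthp` with the first-order (delta-method)
standard deviation of a ratio:

    sd_U = U · sqrt( (sd_cyt/c_cyt)² + (sd_hthp/c_hthp)² ).

Integer reporting uses round-half-up (`floor(x+0.5)`), matching how
such ratios are conventionally quoted (10.85 → 11, 15.56 → 16).

**Why a lognormal Monte-Carlo oracle.** A ratio of Gaussian variables
has no finite variance (the denominator crosses zero with positive
probability), so a Gaussian Monte-Carlo check of `sd_U` is
ill-posed — at the larger relative errors it disagrees with the
first-order formula by > 10 % and keeps growing with sample size.
Concentrations are positive quantities with multiplicative error, so
the acceptance oracle draws lognormal variables matched to each
mean/sd; against that oracle the delta method agrees within ~3 % for
both test inputs.

**Model ranking.** Candidate `U` values span
`[U_obs − ΔU, U_obs + ΔU]` with `ΔU = max(2·sd_U, 2)`; for each `U`
and `k ≤ n_sites` all partitions are enumerated and scored by

    score = ((U − U_obs)/σ_U)² + ((f_cyt − f_obs)/σ_f)²,

with `σ_U = max(sd_U, 0.5)` (half-unit floor: `U` is an integer) and
`σ_f = max(sd_f, 10⁻³)` when a measured fraction uncertainty is
supplied, else a conservative default `σ_f = 0.05`. Inverse-variance
weighting matters: the spectral fraction is typically measured ~100×
more precisely than the gel-derived `U` (sd_f ≈ 0.002 vs sd_U ≈ 4),
and weighting it accordingly is what lets the precise fraction
override a noisy unit count. At the study noise levels this yields
≥ 90 % top-ranked recovery of the true `(11, 6)` structure over 50
seeds (measured 98 %); with a flat `σ_f = 0.05` recovery drops to
~60 % because near-miss families like `(9, 5)` (`f = 4/9 ≈ 0.444`)
are not penalized for their fraction mismatch. Ties are broken by
smaller `U`, then larger `k`, then lexicographically larger chains,
making the ranking fully deterministic.

## 5. Geometry and DLS

Both building blocks are treated as rigid disks/cylinders in a plane:
core diameter `d_core = 6 nm` (upper end of the 5–6 nm range; the
value the flat-arrangement sums use) and `d_unit = 2.5 nm` per
cytochrome unit. The maximum in-plane span runs through the core and
along the two longest chains:

    d_max = d_core + (ℓ₁ + ℓ₂) · d_unit    (ℓ₂ = 0 for one chain).

DLS summaries are the mode (first/smallest bin on ties) and the
number-weighted mean of the distribution. `compare_size` classifies
the observed diameter against `d_max` with a relative tolerance
(default 0.15, roughly DLS repeatability): `flat-consistent` within
tolerance, `flexible/compact` below it, `larger-than-model` above it.

## 6. Synthetic generators

The emulation is statistical, not photophysical. Defaults describe
the study conditions; they are pure functions of parameters and seed.

- **Spectra**: sums of Gaussian bands on a 250–800 nm, 1 nm grid.
  Cytochrome-type: 417/10/1.0, 532/12/0.08, 562/10/0.09
  (center nm / sigma nm / relative height); hexamer-type: 402/10/1.0,
  500/12/0.08, 534.5/12/0.06 and the diagnostic 623/14/0.08 band.
  Heights are free parameters chosen to reproduce the qualitative
  Soret:Q ratios; bases are unit-area normalized. Mixtures add
  Gaussian noise scaled to a fraction (default 1 %) of the Soret
  maximum.
- **Gels**: bands are Gaussian in migration distance at rows fixed by
  a log-linear mass→row rule (12 kDa cytochrome, 6 kDa core monomer),
  amplitude = concentration × species staining coefficient
  (cyt 0.018, hthp 0.045 intensity units/µM) × a multiplicative
  factor `max(1 + N(0, CV), 0)` with CV 0.15, the 10–20 % scatter
  typical of stained band areas. A linear background drift and faint
  pixel noise (sd 0.002) are added; images are clipped at zero.
  Ladders: 2–10 µM (core) and 2–30 µM (cytochrome). Bands closer
  than 3σ produce a warning in the truth record, not an error.
- **DLS**: binned histograms of lognormal diameter draws (default
  median 8.3 nm, σ_log 0.2, 10⁴ particles, 64 bins).
- **Scenario**: true chains `{2,2,2,2,2,1}` at core monomer 2.6 µM
  (hence cytochrome 11/6 · 2.6 µM), duplicate sample lanes plus both
  ladders on one gel, and sub-seeds `seed`, `seed+1`, `seed+2` for
  mixture, gel and DLS so the three measurements are independent.

Not emulated: band shapes beyond Gaussians, spectral baseline drift,
inner-filter effects, gel smearing/smiling, staining saturation,
DLS intensity→number conversion artifacts.

## 7. Limitations

- The two-basis unmixing assumes equal integrated per-heme extinction
  and exactly two spectral environments; free heme or misfolded
  species would bias `f`.
- `U` is a population average; the enumeration treats the sample as a
  single dominant species and will blur over genuine mixtures.
- The inverse-prediction error model is homoscedastic while real band
  noise is closer to multiplicative; coverage is adequate but the sd
  is not exact.
- The geometry model is a rigid flat upper bound, not a hydrodynamic
  model: it brackets but does not predict the DLS diameter.
- SEC calibration (log-linear mass vs elution volume) is provided as
  plumbing for apparent-mass estimates only; no elution volumes are
  predicted.
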