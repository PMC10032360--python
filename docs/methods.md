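# Methods

## Overview

The package implements two complementary voxelwise analyses of
multi-subject naturalistic fMRI against a continuous stimulus rating,
plus the synthetic data generator used to validate them end to end.

**Stimulus model.** A panel of raters continuously judges a stimulus
feature; traces sampled every 4 s (0.25 Hz) are averaged, linearly
interpolated onto volume-acquisition times (volumes before stimulus
onset or after offset take the nearest stimulus value), and convolved
with the canonical double-gamma HRF — h(t) ∝ Γ(6,1).pdf(t) −
Γ(16,1).pdf(t)/6 on a 32-s kernel sampled at TR, unit-sum normalized so
the convolution has DC gain 1. Inter-rater reliability is ICC(2,1)
(two-way random effects, absolute agreement, single rater), computed
from the timepoint × rater mean squares; ICC(3,1) is available as a
config option. Linear interpolation (rather than block averaging) onto
the TR grid and the ICC variant are documented choices where the
analysis convention is not dictated by the data.

**Magnitude (GLM) arm.** Per subject, every in-mask voxel series is
Savitzky–Golay detrended (240-s window rounded to the nearest odd sample
count — 93 samples at TR 2.6 s — polynomial order 3, polynomial edge
fits) and regressed by OLS on [convolved regressor | DCT high-pass basis
| intercept], with K = floor(2·T·TR/cutoff) drift columns at the 128-s
cutoff (K = 18 for 467 volumes). No first-level prewhitening is applied:
with a slow naturalistic regressor (lag-1 autocorrelation ≈ 0.98) and
AR(1) noise at ρ = 0.3, the first-level t is inflated by roughly
√((1+ρρₓ)/(1−ρρₓ)) ≈ 1.35, so first-level t maps are diagnostic only;
all inference happens at the second level, where the one-sample t over
subject **beta** maps uses between-subject variance and remains valid
under arbitrary first-level autocorrelation.

**Synchronization (ISPS) arm.** The detrended data are band-pass
filtered to 0.04–0.07 Hz (2nd-order Butterworth, forward–backward, so
the phase response cancels), the instantaneous phase is the angle of the
analytic signal, and each subject's leave-one-out similarity is the mean
circular cosine of their phase differences with every other subject. The
cosine form is adopted because it is bounded, equals 1 only at perfect
alignment, and satisfies the exact identity mean_s sim_s =
(N·R² − 1)/(N − 1) with the group phase-locking value R — the module's
primary correctness oracle. An angular-distance alternative
(1 − mean|wrapped Δφ|/π) is available behind a config switch for
sensitivity analysis; the identity applies to the cosine form only. The
first and last 10 samples of each similarity series are excluded from
the Pearson correlation with the convolved regressor (Hilbert end
effects; configurable); r is Fisher z-transformed with |r| clipped at
1 − 1e−12.

**Second level.** One-sample t (df = N−1) for the population maps.
Trait models enter all standardized covariates jointly plus an
intercept, so each trait's coefficient is adjusted for the others; this
mutual-adjustment model is order-invariant, which matches the intent of
entering each trait "as a regressor of no interest to the other". A
sequential Gram–Schmidt mode is available for comparison. Trait scores
are z-scored before entry so coefficients are per-SD and the intercept
is the grand mean.

**Cluster inference.** Clusters form at an uncorrected voxel threshold
(default p < 0.001 on the t map, one- or two-tailed) under
26-connectivity (6 and 18 available). Family-wise error is controlled by
the nonparametric max-statistic permutation test: sign-flipping of
subject maps for the one-sample model (valid under a symmetric null),
whole-row permutation of the covariates for the regression model (simple
permutation, not Freedman–Lane — a documented limitation under strong
nuisance collinearity). The permutation statistic is **cluster mass**
(sum of |t| over the cluster) by default rather than cluster extent: on
small grids the max-size distribution is heavily tied at small integers,
which makes the size-based test markedly conservative, whereas mass is
continuous and gives essentially exact control (empirical FWER ≈ 0.045
at nominal 0.05 in the calibration test). Extent remains available via
`cluster_stat="size"`, and cluster tables always report extent (k), the
peak voxel (highest |t|, ties to the lowest linear index) and both p
values. The uncorrected cluster p is estimated from the pooled
permutation cluster statistics and capped at the corrected p so the
table invariant corrected ≥ uncorrected always holds. An optional
Benjamini–Hochberg pass over the uncorrected p values provides the
cluster-FDR mode.

**Quadrant overlay.** A voxel inside significant clusters of *both*
arms is labelled by its sign pair (GLM±ISPS±); a voxel significant in
only one arm is labelled none. This is the "logical overlay" of
convergent and divergent magnitude/synchrony relationships.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume —
not scanner physics, head motion, spatial smoothness, slice timing or
hemodynamic nonlinearity, and no spatial autocorrelation beyond the
region structure. Passing tests therefore demonstrate the correctness
and calibration of the *analysis machinery* under the assumed generative
model, not robustness to real-world artifacts.

- **Rating trace**: low-pass-filtered Gaussian noise, min–max scaled to
  [0, 1], sampled every 4 s. The smoothness cutoff defaults to 0.02 Hz.
  This keeps the regressor's power inside the analysis window bounded by
  the 128-s high-pass (0.0078 Hz) below and the synchrony band (0.04 Hz)
  above: a faster trace would leak shared stimulus-locked power into the
  0.04–0.07 Hz band of every amplitude-responsive region, coupling the
  two arms by construction and blurring exactly the
  amplitude/synchrony dissociation the design is meant to expose.
- **Rater panel**: shared trace + slowly varying rater-specific noise,
  clipped to [0, 1]. `calibrate_rater_noise` bisects the noise SD until
  the Monte-Carlo expected ICC(2,1) hits a target (0.57 by default);
  expected ICC is monotone non-increasing in the noise SD.
- **Traits**: a 4-variate latent Gaussian copula over (AQ total, O-LIFE
  total, AQ social skills, O-LIFE introvertive anhedonia) binned by
  quantile mapping onto binomial marginals whose means match published
  descriptives (16.8/50, 11.2/43, 3.1/10, 2.2/10). Latent correlations:
  totals 0.305, social subscales 0.528, part–whole 0.6, cross terms
  0.6 × the totals target. Binning attenuates the realized correlations
  by under 5% (0.295 and 0.502 at n = 50 000).
- **Archetype regions**: four signed archetypes span the overlay
  quadrants. The amplitude component is β·ĉ(t) (ĉ the unit-SD convolved
  regressor; β positive for AMP+, negative for AMP−; default 0.5
  noise-SD units). The synchrony component mixes one shared band-limited
  (0.04–0.07 Hz) series per region with a subject-specific band-limited
  series: x = A·[w(t)·s(t) + (1−w(t))·η_j(t)], where the shared weight
  w(t) ramps from 0.1 to 0.9 with the min–max-normalized regressor
  (SYNC+) or against it (SYNC−, "amplitude rises, phases scatter"), and
  A defaults to 1 noise-SD. Voxel noise is stationary AR(1) (ρ = 0.3,
  the minimal temporally correlated choice; SD 1). Trait effects scale a
  subject's regional β or shared weight by (1 + sign·magnitude·z(trait)),
  default magnitude 0.4 — a 1-SD trait shift changes the regional effect
  by 40%, a moderate individual-difference effect chosen from the power
  arithmetic below. All generators are pure functions of their seed.

**Effect-size arithmetic.** With T = 460 volumes and unit noise, the
first-level SE of β is ≈ 1/√T ≈ 0.05, so β = 0.5 is a ~10σ first-level
effect and the 20-subject one-sample group t is far above any cluster
threshold, while the trait slope −β·magnitude = −0.2 per SD against a
between-subject SD of ~0.1 gives the n = 40 regression test high power.
These defaults were fixed from this arithmetic (plus one pilot run of
the mechanism) before the recovery tests were frozen.

## Problem sizes and numerical choices

Desk-scale defaults keep every simulation on one CPU in minutes: the
default fixture is 20 subjects × 16×16×8 voxels × 460 volumes with four
64-voxel regions; the trait-recovery study uses 40 subjects × 10×10×6 ×
250 volumes; error-control calibration uses 12×12×6 null maps, 200
permutations and 200 replicates. Permutation p values use the
add-one estimator (1 + #{perm ≥ obs})/(1 + n_perm), so n_perm must
satisfy 1/(1+n_perm) ≤ α (a resolution error otherwise). Degenerate
inputs are flagged rather than silently dropped: zero-variance voxels
get beta 0 / t NaN, constant phases get NaN, and NaNs propagate through
the similarity average.

## Known limitations

- Covariate permutation is simple row permutation; under strong
  collinearity between the tested covariate and nuisance covariates a
  Freedman–Lane scheme would be preferable.
- First-level OLS without prewhitening over-states single-subject t
  values (see above); only betas feed the second level.
- The generator's regions are rectangular and internally homogeneous;
  cluster extents are meaningful only relative to this geometry.
- The angular-distance similarity form shares the cosine form's
  qualitative behaviour but not the PLV identity; results quoted in the
  package use the cosine form unless stated otherwise.
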