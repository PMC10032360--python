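# neurosync

Complementary voxelwise analyses of naturalistic-stimulus fMRI: the
**magnitude** of the BOLD response to a continuous stimulus feature, and
the **intersubject phase synchronization** (ISPS) of that response across
viewers — together with a synthetic multi-subject BOLD generator that
plants recoverable ground truth for every stage.

## The scientific problem

When many people watch the same movie, a brain region can respond to a
stimulus feature (for example, the amount of biological motion on screen)
in two distinct ways that a conventional GLM cannot separate:

1. its **amplitude** can rise or fall with the feature — the classical
   voxelwise regression of BOLD on an HRF-convolved stimulus regressor;
2. its activity can become more or less **synchronized across viewers**
   as the feature waxes and wanes, even with no mean amplitude change.

The second phenomenon is captured by ISPS: each subject's band-limited
(0.04–0.07 Hz) voxel series x(t) is turned into an instantaneous phase
φ(t) = arg(x(t) + i·H[x(t)]) via the Hilbert transform, and the
leave-one-out phase similarity of subject *s* with the rest of the sample
is

    sim_s(v, t) = (1 / (N−1)) · Σ_{j≠s} cos(φ_s(v,t) − φ_j(v,t)) ∈ [−1, 1].

Its subject mean is tied exactly to the group phase-locking value
R(v,t) = |mean_j exp(iφ_j)| by `mean_s sim_s = (N·R² − 1)/(N − 1)`, an
identity the test suite verifies to 1e−10. Each subject's similarity
series is correlated with the HRF-convolved stimulus regressor and Fisher
z-transformed; the z maps enter the same two-stage random-effects group
models as the first-level GLM betas (one-sample t; multiple regression on
standardized trait covariates, each trait adjusted for the other).
Cluster inference is nonparametric: an uncorrected voxel threshold
(p < 0.001) forms 26-connected clusters, and a max-statistic permutation
test (sign-flipping for one-sample, covariate-row permutation for
regression) controls the family-wise error over cluster mass.

Crossing the signs of the two analyses yields a quadrant overlay —
convergent (+/+, −/−) or divergent (+/−, −/+) regions — and entering
questionnaire scores (AQ autistic traits, O-LIFE schizotypy) as mutually
adjusted second-level covariates asks which individual differences track
amplitude and which track synchrony.

## Worked example

```bash
python analysis/01_simulate.py       # synthetic study -> scratch/dataset
python analysis/02_glm_arm.py        # magnitude arm
python analysis/03_isps_arm.py       # synchronization arm
python analysis/04_quadrant_overlay.py
python analysis/05_trait_effects.py
```

`01_simulate.py` builds a 20-subject, 16×16×8-voxel, 460-volume (TR
2.6 s) ensemble with four planted 64-voxel archetype regions and a rater
panel calibrated to the published reliability; it prints, among other
things:

```
"calibrated_rater_noise_sd": 0.1563,
"panel_icc_2_1": 0.584,
"trait_corr_totals": 0.285,
```

i.e. the five simulated raters agree at ICC(2,1) ≈ 0.58 and the two trait
totals correlate at ≈ 0.3 in this 20-subject draw. `04_quadrant_overlay.py`
then reports

```
"quadrant_voxel_counts":   {"GLM+ISPS+": 64, "GLM+ISPS-": 64, "GLM-ISPS+": 64, "GLM-ISPS-": 64},
"planted_label_agreement": {"GLM+ISPS+": 1.0, "GLM+ISPS-": 1.0, "GLM-ISPS+": 1.0, "GLM-ISPS-": 1.0},
"false_label_rate_in_null": 0.0
```

— every planted region is recovered with its designed sign pair and no
null voxel is mislabelled. `05_trait_effects.py` plants a negative AQ
effect on regional amplitude and a negative O-LIFE effect on regional
synchrony (traits correlated ≈ 0.3) and recovers the dissociation: the
AQ contrast is strongly negative in the magnitude arm (median t ≈ −58,
sign recovered in 20/20 replicates) and null in the synchronization arm,
while the O-LIFE contrast is negative in the synchronization arm (median
t ≈ −6.3, 20/20) and null in the magnitude arm.

There is also a thin CLI (`neurosync simulate`, `neurosync run-all
--config run.yaml`, `neurosync report`) for disk-based runs; see
`neurosync --help`.

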