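"""Synthetic generators: rating traces, rater panels, traits, ensembles."""

import numpy as np
import pytest
from scipy import signal

from neurosync.exceptions import InvalidArgumentError
from neurosync.glm import build_design, fit_first_level
from neurosync.isps import (
    couple_similarity_to_regressor,
    instantaneous_phase,
    loo_phase_similarity,
)
from neurosync.preprocess import bandpass
from neurosync.synth import (
    RegionSpec,
    SimulationConfig,
    TraitEffect,
    estimate_panel_icc,
    generate_ensemble,
    generate_rater_panel,
    generate_rating_trace,
    generate_trait_table,
)

from conftest import make_regressor, small_ensemble


class TestRatingTrace:
    def test_sample_count_and_bounds(self):
        trace = generate_rating_trace(duration_s=1176, dt=4, seed=1)
        assert len(trace.values) == 294  # 19.6 min at one sample per 4 s
        assert trace.values.min() >= 0.0 and trace.values.max() <= 1.0

    def test_deterministic_and_seed_sensitive(self):
        a = generate_rating_trace(1176, 4, seed=1)
        b = generate_rating_trace(1176, 4, seed=1)
        c = generate_rating_trace(1176, 4, seed=2)
        assert np.array_equal(a.values, b.values)
        assert np.any(a.values != c.values)

    def test_power_is_slow(self):
        trace = generate_rating_trace(1176, 4, seed=3)
        f, p = signal.periodogram(trace.values - trace.values.mean(), fs=0.25)
        assert p[f < 0.1].sum() > 0.9 * p.sum()

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            generate_rating_trace(-10, 4, seed=0)
        with pytest.raises(InvalidArgumentError):
            generate_rating_trace(100, 0, seed=0)


class TestRaterPanel:
    def test_zero_noise_reproduces_the_trace(self, smooth_trace):
        panel = generate_rater_panel(smooth_trace, 5, rater_noise_sd=0.0, seed=4)
        for t in panel:
            assert np.array_equal(t.values, smooth_trace.values)

    def test_needs_two_raters(self, smooth_trace):
        with pytest.raises(InvalidArgumentError):
            generate_rater_panel(smooth_trace, 1, 0.1, seed=0)

    def test_expected_icc_monotone_in_noise(self, smooth_trace):
        iccs = [
            estimate_panel_icc(smooth_trace, 5, sd, seed=11, n_reps=10)
            for sd in (0.05, 0.15, 0.4, 1.0)
        ]
        assert all(a >= b - 0.02 for a, b in zip(iccs, iccs[1:]))

    def test_huge_noise_destroys_agreement(self, smooth_trace):
        icc = estimate_panel_icc(smooth_trace, 5, 10.0, seed=12, n_reps=10)
        assert icc < 0.2


class TestTraitTable:
    def test_target_correlation_recovered_at_study_size(self):
        traits = generate_trait_table(97, seed=5)
        df = traits.df
        r_tot = np.corrcoef(df.aq_total, df.olife_total)[0, 1]
        r_soc = np.corrcoef(df.aq_social_skills, df.olife_introversion)[0, 1]
        assert 0.155 <= r_tot <= 0.455  # target 0.305 +- sampling error
        assert 0.378 <= r_soc <= 0.678  # target 0.528 +- sampling error

    def test_null_target_gives_small_correlation(self):
        traits = generate_trait_table(97, target_corr_total=0.0, seed=6)
        r = np.corrcoef(traits.df.aq_total, traits.df.olife_total)[0, 1]
        assert abs(r) < 0.3

    def test_scores_within_instrument_ranges(self):
        df = generate_trait_table(200, seed=7).df
        assert df.aq_total.between(0, 50).all()
        assert df.olife_total.between(0, 43).all()
        assert df.aq_social_skills.between(0, 10).all()
        assert df.olife_introversion.between(0, 10).all()
        assert (df.dtypes != float).all()  # integer scores

    def test_deterministic(self):
        a = generate_trait_table(40, seed=8).df
        b = generate_trait_table(40, seed=8).df
        assert a.equals(b)

    def test_infeasible_targets_rejected(self):
        # strong negative social target against strong positive part-whole
        # paths makes the latent matrix indefinite
        with pytest.raises(InvalidArgumentError):
            generate_trait_table(50, target_corr_total=0.9,
                                 target_corr_social=-0.95, seed=9)


class TestEnsemble:
    def test_bit_identical_for_identical_seed(self):
        ens_a, _, _, _ = small_ensemble(seed=21)
        ens_b, _, _, _ = small_ensemble(seed=21)
        for a, b in zip(ens_a.images, ens_b.images):
            assert np.array_equal(a.data, b.data)

    def test_seed_changes_data(self):
        ens_a, _, _, _ = small_ensemble(seed=21)
        ens_b, _, _, _ = small_ensemble(seed=22)
        assert not np.array_equal(ens_a.images[0].data, ens_b.images[0].data)

    def test_noise_free_amplitude_region_tracks_regressor(self):
        # dominant amplitude term, faint oscillation: every subject's voxel
        # correlates with the convolved regressor at r > 0.99
        regions = (RegionSpec("amp", "AMP+SYNC+", (1, 5, 1, 5, 1, 5),
                              amp_effect=1.0, sync_effect=0.1),)
        cfg = SimulationConfig(
            n_subjects=4, grid=(8, 8, 6), n_volumes=120, tr=2.6,
            region_specs=regions, noise_sd=0.0, seed=13,
        )
        reg = make_regressor(120, 2.6, seed=13)
        ens, _ = generate_ensemble(cfg, reg)
        for img in ens.images:
            r = np.corrcoef(img.data[2, 2, 2], reg.values)[0, 1]
            assert r > 0.99

    def test_noise_free_sync_region_dissociates(self):
        # AMP-SYNC+ with no amplitude effect: first-level t stays below the
        # voxel-forming threshold while ISPS coupling is strong — verified
        # with the pipeline's own downstream stages as oracle
        from scipy import stats

        regions = (RegionSpec("sync", "AMP-SYNC+", (1, 5, 1, 5, 1, 5),
                              amp_effect=0.0, sync_effect=1.0),)
        cfg = SimulationConfig(
            n_subjects=8, grid=(8, 8, 6), n_volumes=300, tr=2.6,
            region_specs=regions, noise_sd=0.0, seed=14,
        )
        reg = make_regressor(300, 2.6, seed=14)
        ens, _ = generate_ensemble(cfg, reg)
        design = build_design(reg)
        voxel = (2, 2, 2)
        for img in ens.images:
            _, t = fit_first_level(img, design)
            assert abs(t.data[voxel]) < stats.t.ppf(1 - 0.001, t.df)
        phases = [instantaneous_phase(bandpass(img)) for img in ens.images]
        sims = loo_phase_similarity(phases)
        rs = [
            np.tanh(couple_similarity_to_regressor(s, reg).data[voxel])
            for s in sims
        ]
        # leave-one-out similarity carries circular sampling noise at small
        # N, so individual r values scatter around ~0.5; the planted
        # coupling must dominate for every subject and for the group
        assert np.median(rs) > 0.5
        assert min(rs) > 0.25

    def test_mismatched_inputs_rejected(self):
        cfg = SimulationConfig(n_subjects=4, grid=(8, 8, 6), n_volumes=120,
                               tr=2.6, region_specs=(), seed=1)
        with pytest.raises(InvalidArgumentError):
            generate_ensemble(cfg, make_regressor(119, 2.6))
        traits = generate_trait_table(3, seed=2)
        with pytest.raises(InvalidArgumentError):
            generate_ensemble(cfg, make_regressor(120, 2.6), traits)

    def test_trait_effect_requires_trait_table(self):
        regions = (RegionSpec("amp", "AMP+SYNC-", (1, 5, 1, 5, 1, 5)),)
        cfg = SimulationConfig(
            n_subjects=4, grid=(8, 8, 6), n_volumes=120, tr=2.6,
            region_specs=regions,
            trait_effects=(TraitEffect("aq_total", "amp"),), seed=1,
        )
        with pytest.raises(InvalidArgumentError):
            generate_ensemble(cfg, make_regressor(120, 2.6))

    def test_overlapping_regions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SimulationConfig(
                grid=(8, 8, 6), n_volumes=120,
                region_specs=(
                    RegionSpec("a", "AMP+SYNC+", (0, 4, 0, 4, 0, 4)),
                    RegionSpec("b", "AMP-SYNC-", (2, 6, 2, 6, 2, 6)),
                ),
            )

    def test_ground_truth_labels_partition_regions(self):
        _, truth, _, cfg = small_ensemble(seed=3)
        assert truth.region_mask("AMP+SYNC-").sum() == 64
        assert truth.region_mask("AMP-SYNC+").sum() == 64
        assert truth.region_mask("null").sum() == np.prod(cfg.grid) - 128
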