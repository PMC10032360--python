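"""Cluster formation, permutation FWE control, BH step, quadrant overlay."""

import numpy as np
import pandas as pd
import pytest

from neurosync.exceptions import InvalidArgumentError, ResolutionError
from neurosync.inference import (
    ClusterResult,
    benjamini_hochberg,
    form_clusters,
    permutation_correct,
    quadrant_overlay,
)
from neurosync.types import StatMap

GRID = (12, 12, 6)


def t_map(values, df=19):
    mask = np.ones(GRID, bool)
    return StatMap(values, "t", mask, df=df)


def null_maps(rng, n=20, effect=None):
    mask = np.ones(GRID, bool)
    maps = []
    for _ in range(n):
        d = rng.standard_normal(GRID)
        if effect is not None:
            d += effect
        maps.append(StatMap(d, "beta", mask))
    return maps


class TestFormClusters:
    def test_planted_cube_is_one_cluster(self):
        data = np.zeros(GRID)
        data[2:5, 2:5, 2:5] = 10.0
        table = form_clusters(t_map(data), voxel_p=0.001, tail="positive").table
        assert len(table) == 1
        assert table.loc[0, "size"] == 27

    @pytest.mark.parametrize("connectivity, n_expected", [(26, 1), (6, 2)])
    def test_corner_touching_voxels(self, connectivity, n_expected):
        data = np.zeros(GRID)
        data[0, 0, 0] = 10.0
        data[1, 1, 1] = 10.0
        table = form_clusters(
            t_map(data), voxel_p=0.001, tail="positive", connectivity=connectivity
        ).table
        assert len(table) == n_expected

    def test_negative_tail(self):
        data = np.zeros(GRID)
        data[0:2, 0:2, 0:2] = -10.0
        assert len(form_clusters(t_map(data), tail="negative").table) == 1
        assert len(form_clusters(t_map(data), tail="positive").table) == 0

    def test_empty_suprathreshold_set_is_not_an_error(self):
        table = form_clusters(t_map(np.zeros(GRID))).table
        assert len(table) == 0

    def test_peak_reporting(self):
        data = np.zeros(GRID)
        data[2:5, 2, 2] = [5.0, 9.0, 6.0]
        table = form_clusters(t_map(data), tail="positive").table
        assert (table.loc[0, ["peak_x", "peak_y", "peak_z"]] == [3, 2, 2]).all()
        assert table.loc[0, "peak_stat"] == 9.0


class TestBenjaminiHochberg:
    def test_textbook_step_up_example(self):
        # hand-evaluated: at q=0.05 with m=5, thresholds i*q/m =
        # 0.01, 0.02, 0.03, 0.04, 0.05; largest i with p_(i) <= thr is 2
        rej = benjamini_hochberg([0.001, 0.008, 0.039, 0.041, 0.2], q=0.05)
        assert rej.tolist() == [True, True, False, False, False]


class TestPermutationCorrect:
    def test_deterministic_given_seed(self, rng):
        maps = null_maps(rng, n=12, effect=None)
        a = permutation_correct(maps, n_perm=100, voxel_p=0.01, seed=5)
        b = permutation_correct(maps, n_perm=100, voxel_p=0.01, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert np.array_equal(a.labels, b.labels)

    def test_corrected_at_least_uncorrected(self, rng):
        maps = null_maps(rng, n=15)
        cr = permutation_correct(maps, n_perm=150, voxel_p=0.05, seed=2)
        if len(cr.table):
            assert (cr.table.p_corrected >= cr.table.p_uncorrected - 1e-12).all()

    def test_corrected_p_monotone_in_cluster_statistic(self, rng):
        effect = np.zeros(GRID)
        effect[1:3, 1:3, 1:3] = 1.5  # small cluster
        effect[6:10, 6:10, 1:5] = 1.5  # large cluster
        maps = null_maps(rng, n=20, effect=effect)
        cr = permutation_correct(maps, n_perm=150, voxel_p=0.01, seed=3,
                                 cluster_stat="size")
        tab = cr.table.sort_values("size", ascending=False)
        assert tab.p_corrected.is_monotonic_increasing

    def test_planted_effect_reaches_minimum_p(self, rng):
        hits = 0
        for rep in range(10):
            effect = np.zeros(GRID)
            effect[4:8, 4:8, 2:4] = 2.0  # ~2 SD shift over 32 voxels, n=20
            maps = null_maps(rng, n=20, effect=effect)
            cr = permutation_correct(maps, n_perm=150, voxel_p=0.001, seed=rep)
            if len(cr.table) and cr.table.p_corrected.min() <= 1.0 / 151 + 1e-12:
                hits += 1
        assert hits >= 8

    def test_regression_mode_detects_covariate_effect(self, rng):
        from neurosync.types import SecondLevelModel, TraitTable

        n = 30
        score = rng.standard_normal(n)
        z = (score - score.mean()) / score.std(ddof=1)
        mask = np.ones(GRID, bool)
        maps = []
        for j in range(n):
            d = rng.standard_normal(GRID)
            d[4:8, 4:8, 2:4] += 1.5 * z[j]  # covariate-linked region
            maps.append(StatMap(d, "beta", mask))
        df = pd.DataFrame({"score": score},
                          index=[f"sub-{j:02d}" for j in range(n)])
        df.index.name = "subject_id"
        cr = permutation_correct(
            maps,
            model=SecondLevelModel(["score"], "score"),
            traits=TraitTable(df),
            n_perm=150,
            voxel_p=0.001,
            seed=4,
            tail="positive",
        )
        assert len(cr.table) >= 1
        assert cr.table.p_corrected.min() <= 0.05

    def test_resolution_error(self, rng):
        maps = null_maps(rng, n=10)
        with pytest.raises(ResolutionError):
            permutation_correct(maps, n_perm=100, voxel_p=0.01, seed=0, alpha=0.001)
        with pytest.raises(InvalidArgumentError):
            permutation_correct(maps, n_perm=50, voxel_p=0.01, seed=0)

    def test_fdr_mode_adds_columns(self, rng):
        maps = null_maps(rng, n=15)
        cr = permutation_correct(maps, n_perm=120, voxel_p=0.05, seed=9, fdr=True)
        if len(cr.table):
            assert "p_fdr" in cr.table.columns
            assert (cr.table.p_fdr >= cr.table.p_uncorrected - 1e-12).all()


def cluster_result_from_mask(mask_bool, tail, p=0.01):
    labels = mask_bool.astype(int)
    if mask_bool.any():
        table = pd.DataFrame(
            [{"label": 1, "size": int(mask_bool.sum()), "mass": 1.0,
              "peak_x": 0, "peak_y": 0, "peak_z": 0, "peak_stat": 5.0,
              "p_uncorrected": p, "p_corrected": p}]
        )
    else:
        table = pd.DataFrame(
            columns=["label", "size", "mass", "peak_x", "peak_y", "peak_z",
                     "peak_stat", "p_uncorrected", "p_corrected"]
        )
    return ClusterResult(table, labels, tail, 3.0)


class TestQuadrantOverlay:
    def make_masks(self):
        empty = np.zeros(GRID, bool)
        gp = empty.copy()
        gp[0:4, 0:4, 0:2] = True
        ip = empty.copy()
        ip[0:2, 0:2, 0:2] = True
        inn = empty.copy()
        inn[2:4, 2:4, 0:2] = True
        return gp, ip, inn, empty

    def test_sign_pair_labels_require_conjunction(self):
        gp, ip, inn, empty = self.make_masks()
        q = quadrant_overlay(
            cluster_result_from_mask(gp, "positive"),
            cluster_result_from_mask(empty, "negative"),
            cluster_result_from_mask(ip, "positive"),
            cluster_result_from_mask(inn, "negative"),
        )
        assert (q.labels[ip & gp] == 1).all()  # GLM+ISPS+
        assert (q.labels[inn & gp] == 2).all()  # GLM+ISPS-
        only_glm = gp & ~ip & ~inn
        assert (q.labels[only_glm] == 0).all()  # one-sided membership -> none

    def test_nonsignificant_clusters_excluded(self):
        gp, ip, _, empty = self.make_masks()
        q = quadrant_overlay(
            cluster_result_from_mask(gp, "positive", p=0.4),  # not significant
            cluster_result_from_mask(empty, "negative"),
            cluster_result_from_mask(ip, "positive"),
            cluster_result_from_mask(empty, "negative"),
            alpha=0.05,
        )
        assert (q.labels == 0).all()

    def test_grid_mismatch_rejected(self):
        gp, ip, inn, empty = self.make_masks()
        other = np.zeros((4, 4, 4), bool)
        with pytest.raises(InvalidArgumentError):
            quadrant_overlay(
                cluster_result_from_mask(gp, "positive"),
                cluster_result_from_mask(empty, "negative"),
                cluster_result_from_mask(other, "positive"),
                cluster_result_from_mask(other, "negative"),
            )

    def test_counts_partition_bound(self):
        gp, ip, inn, empty = self.make_masks()
        q = quadrant_overlay(
            cluster_result_from_mask(gp, "positive"),
            cluster_result_from_mask(empty, "negative"),
            cluster_result_from_mask(ip, "positive"),
            cluster_result_from_mask(inn, "negative"),
        )
        assert sum(q.counts().values()) <= np.prod(GRID)
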