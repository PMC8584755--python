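"""Brownian-motion fits, dAIC, spatial null and Wilcoxon tests."""

import warnings

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import expevo
from expevo.containers import GeneAnnotation
from expevo.errors import DegenerateFitWarning, UnrootedTreeWarning, ValidationError
from expevo.shifts import BMContext, delta_aic_histogram
from expevo.synthetic import ShiftSpec, default_tree, simulate_expression

from _oracles import (
    grid_max_lnl,
    mann_whitney_exact_two_sided,
    median_draw_distribution,
    pathwalk_bm_covariance,
    random_binary_tree,
)


class TestBMCovariance:
    def test_star_tree_unit_branches_is_identity(self):
        star = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
        with pytest.warns(UnrootedTreeWarning):
            labels, C = expevo.bm_covariance(star)
        assert np.allclose(C, np.eye(4))

    def test_three_taxon_read_off_paths(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
        labels, C = expevo.bm_covariance(tree)
        idx = {lab: i for i, lab in enumerate(labels)}
        assert C[idx["A"], idx["B"]] == pytest.approx(1.0)
        assert C[idx["A"], idx["A"]] == pytest.approx(2.0)
        assert C[idx["A"], idx["C"]] == pytest.approx(0.0)

    def test_random_trees_match_pathwalk_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            tree = random_binary_tree(rng, 9)
            labels, C = expevo.bm_covariance(tree)
            olabels, oC = pathwalk_bm_covariance(tree)
            order = [labels.index(lab) for lab in olabels]
            assert np.abs(C[np.ix_(order, order)] - oC).max() < 1e-12


class TestFits:
    def test_star_tree_reduces_to_iid_gaussian_ml(self):
        star = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnrootedTreeWarning)
            ctx = BMContext.from_tree(star)
        fit = expevo.fit_bm(ctx, dict(zip(ctx.labels, [0.0, 0.0, 4.0, 4.0])))
        assert fit.mu == pytest.approx(2.0)
        assert fit.sigma2 == pytest.approx(4.0)
        n = 4
        assert fit.log_likelihood == pytest.approx(
            -(n / 2) * np.log(2 * np.pi * fit.sigma2) - n / 2
        )

    def test_shift_coefficient_zero_when_focal_equals_others_mean(self):
        star = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnrootedTreeWarning)
            ctx = BMContext.from_tree(star)
        x = [2.0, 1.0, 2.0, 3.0]  # focal A equals mean of B, C, D
        fit0 = expevo.fit_bm(ctx, x)
        fit1 = expevo.fit_shift(ctx, x, "A")
        assert fit1.delta == pytest.approx(0.0, abs=1e-12)
        assert fit1.mu == pytest.approx(2.0)
        assert fit1.log_likelihood == pytest.approx(fit0.log_likelihood)
        assert expevo.delta_aic(fit0, fit1).delta_aic == -2.0

    def test_lnl_matches_grid_search_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(3, 6))
            tree = random_binary_tree(rng, n)
            ctx = BMContext.from_tree(tree)
            x = rng.normal(0.0, 2.0, n)
            fit0 = expevo.fit_bm(ctx, x)
            fit1 = expevo.fit_shift(ctx, x, ctx.labels[0])
            g0 = grid_max_lnl(ctx.C, x, focal_index=None)
            g1 = grid_max_lnl(ctx.C, x, focal_index=0)
            assert fit0.log_likelihood >= g0 - 1e-9
            assert abs(fit0.log_likelihood - g0) < 1e-6
            assert fit1.log_likelihood >= g1 - 1e-9
            assert abs(fit1.log_likelihood - g1) < 1e-6

    def test_constant_trait_floors_variance_with_warning(self, ctx9):
        with pytest.warns(DegenerateFitWarning):
            fit = expevo.fit_bm(ctx9, np.full(9, 3.0))
        assert fit.sigma2 == pytest.approx(1e-9)
        assert fit.degenerate

    def test_injected_shift_recovered_within_three_se(self, tree9, ctx9):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            matrix, _ = simulate_expression(
                tree9, 1, sigma2_range=(0.1, 0.1), noise_sd=0.0, seed=7000 + rep,
                shifts=ShiftSpec("pig", 1.0, 5.0),
            )
            fit = expevo.fit_shift(ctx9, matrix.values.iloc[0], "pig")
            hits += abs(fit.delta - 5.0) <= 3.0 * fit.se_delta
        assert hits >= 0.9 * n_rep  # nominal coverage ~99.7%


class TestDeltaAIC:
    def test_nesting_bound_holds_on_null_genes(self, tree9, ctx9):
        matrix, _ = simulate_expression(tree9, 200, noise_sd=0.0, seed=9)
        result = expevo.genomewide_delta_aic(matrix, tree9, focal_species="pig")
        assert (result.table["delta_aic"] >= -2.0).all()

    def test_single_gene_matrix_yields_single_record(self, tree9):
        matrix, _ = simulate_expression(tree9, 1, seed=2)
        result = expevo.genomewide_delta_aic(matrix, tree9, focal_species="pig")
        assert len(result.table) == 1
        rec = result.table.iloc[0]
        assert rec["delta_aic"] == pytest.approx(
            2 * (rec["lnl1"] - rec["lnl0"]) - 2
        )

    def test_degenerate_genes_collected_not_fatal(self, tree9):
        matrix, _ = simulate_expression(tree9, 10, seed=4)
        values = matrix.values.copy()
        values.iloc[0] = 5.0  # constant gene
        from expevo.containers import ExpressionMatrix
        result = expevo.genomewide_delta_aic(
            ExpressionMatrix(values, scale="log2"), tree9, focal_species="pig"
        )
        assert result.degenerate_genes == [values.index[0]]
        assert len(result.table) == 9  # input count minus flagged degenerates

    def test_shifted_genes_have_larger_median_delta_aic(self, tree9):
        shifted, _ = simulate_expression(
            tree9, 300, sigma2_range=(0.2, 0.6), noise_sd=0.1, seed=21,
            shifts=ShiftSpec("pig", 1.0, 2.0),
        )
        null, _ = simulate_expression(tree9, 300, sigma2_range=(0.2, 0.6),
                                      noise_sd=0.1, seed=22)
        d_shift = expevo.genomewide_delta_aic(shifted, tree9, "pig").table["delta_aic"]
        d_null = expevo.genomewide_delta_aic(null, tree9, "pig").table["delta_aic"]
        assert d_shift.median() > d_null.median()

    def test_histogram_counts_cover_all_records(self):
        hist = delta_aic_histogram([-2.0, -1.0, 0.0, 1.0, 5.0], bins=4)
        assert hist["count"].sum() == 5


class TestSpatialNeighbors:
    @pytest.fixture()
    def annotation(self):
        return GeneAnnotation(pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4", "g5", "far"],
                "chrom": ["chr1"] * 5 + ["chr2"],
                "start": [0, 2000, 5000, 9000, 20000, 100],
                "end": [1000, 3000, 6000, 10000, 21000, 1100],
            }
        ))

    def test_window_zero_is_empty_for_disjoint_intervals(self, annotation):
        assert expevo.spatial_neighbors(annotation, "g3", window_bp=0) == []

    def test_window_query_half_open_boundary(self, annotation):
        # g3 spans [5000, 6000); +/-3000 reaches [2000, 9000): the boundary
        # start at 9000 (g4) is excluded, one more base pulls it in
        assert expevo.spatial_neighbors(annotation, "g3", window_bp=3000) == ["g2"]
        assert expevo.spatial_neighbors(annotation, "g3", window_bp=3001) == ["g2", "g4"]

    def test_n_nearest_matches_sort_oracle(self, annotation):
        got = expevo.spatial_neighbors(annotation, "g1", n_nearest=3)
        mids = {"g2": 2500, "g3": 5500, "g4": 9500, "g5": 20500}
        expected = sorted(sorted(mids, key=lambda g: abs(mids[g] - 500))[:3],
                          key=lambda g: mids[g])
        assert got == expected

    def test_focal_absent_rejected(self, annotation):
        with pytest.raises(ValidationError):
            expevo.spatial_neighbors(annotation, "nope")


class TestResamplingNull:
    def test_identical_pool_gives_identical_medians(self):
        null = expevo.resampled_median_null(np.full(20, 1.5), draw_size=5,
                                            n_iter=100, seed=1)
        assert np.allclose(null.medians, 1.5)

    def test_exhaustive_draw_equals_pool_median(self):
        pool = np.array([3.0, -1.0, 0.5, 2.0, 7.0])
        null = expevo.resampled_median_null(pool, draw_size=5, n_iter=50, seed=2)
        assert np.allclose(null.medians, np.median(pool))

    def test_seed_determinism(self):
        pool = np.arange(30.0)
        a = expevo.resampled_median_null(pool, 7, n_iter=200, seed=5)
        b = expevo.resampled_median_null(pool, 7, n_iter=200, seed=5)
        assert np.array_equal(a.medians, b.medians)

    def test_matches_enumeration_on_five_gene_pool(self):
        pool = [-2.0, -1.0, 0.0, 1.0, 2.0]
        exact = median_draw_distribution(pool, 3)
        null = expevo.resampled_median_null(pool, 3, n_iter=4000, seed=11)
        for outcome, prob in exact.items():
            emp = float(np.mean(null.medians == outcome))
            assert emp == pytest.approx(prob, abs=0.03)

    def test_insufficient_pool_rejected(self):
        with pytest.raises(ValidationError):
            expevo.resampled_median_null([1.0, 2.0], draw_size=3)


class TestWilcoxon:
    def test_small_sample_exact_p_one_third(self):
        res = expevo.wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0 / 3.0)

    def test_identical_samples_give_p_one_on_normal_path(self):
        res = expevo.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.method == "normal"
        assert res.p_value == 1.0

    @pytest.mark.parametrize("na,nb", [(2, 3), (4, 4), (5, 3), (8, 8), (1, 8)])
    def test_exact_path_matches_full_enumeration(self, na, nb, rng):
        a = rng.permutation(np.arange(na + nb, dtype=float))[:na]
        b = np.setdiff1d(np.arange(na + nb, dtype=float), a)
        res = expevo.wilcoxon_rank_sum(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(mann_whitney_exact_two_sided(a, b))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=10, unique=True),
           st.lists(st.floats(-50, 50), min_size=2, max_size=10, unique=True))
    def test_swapping_samples_preserves_two_sided_p(self, a, b):
        if set(a) & set(b):
            return
        ab = expevo.wilcoxon_rank_sum(a, b)
        ba = expevo.wilcoxon_rank_sum(b, a)
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            expevo.wilcoxon_rank_sum([], [1.0])


class TestShiftReport:
    def _null(self, medians, seed=0):
        medians = np.asarray(medians, dtype=float)
        return expevo.shifts.ResamplingNull(
            medians=medians, draw_size=3, n_iter=len(medians), seed=seed,
            pool_size=50, focal_gene="focal",
        )

    def test_focal_below_every_null_median_has_percentile_zero(self):
        report = expevo.shift_report(-5.0, [-4.0, -3.0], self._null([0.0, 1.0, 2.0]))
        assert report.percentile_vs_null_medians == 0.0

    def test_empty_neighbor_set_degrades_with_warning(self):
        with pytest.warns(UserWarning, match="empty neighbor set"):
            report = expevo.shift_report(0.0, [], self._null([1.0, -1.0]))
        assert report.neighbor_vs_null_wilcoxon is None
        assert 0.0 <= report.percentile_vs_null_medians <= 100.0

    def test_percentiles_invariant_to_value_order(self):
        medians = [3.0, -1.0, 2.0, 0.0]
        a = expevo.shift_report(1.0, [0.5], self._null(medians))
        b = expevo.shift_report(1.0, [0.5], self._null(medians[::-1]))
        assert a.percentile_vs_null_medians == b.percentile_vs_null_medians

    def test_low_shift_neighbors_detected_against_shifted_pool(self, tree9):
        detections = 0
        n_runs = 20
        for run in range(n_runs):
            neigh, _ = simulate_expression(tree9, 30, sigma2_range=(0.2, 0.6),
                                           noise_sd=0.1, seed=3000 + run)
            pool, _ = simulate_expression(
                tree9, 120, sigma2_range=(0.2, 0.6), noise_sd=0.1,
                seed=4000 + run, shifts=ShiftSpec("pig", 1.0, 2.0),
            )
            d_n = expevo.genomewide_delta_aic(neigh, tree9, "pig").table["delta_aic"]
            d_p = expevo.genomewide_delta_aic(pool, tree9, "pig").table["delta_aic"]
            null = expevo.resampled_median_null(d_p.to_numpy(), draw_size=len(d_n),
                                                n_iter=300, seed=run)
            report = expevo.shift_report(float(d_n.iloc[0]), d_n.to_numpy(), null)
            detections += report.neighbor_vs_null_wilcoxon.p_value < 0.05
        assert detections >= 0.9 * n_runs
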