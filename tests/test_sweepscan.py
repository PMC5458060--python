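"""Composite-likelihood scan: likelihood contracts, weighting, region calls."""
import math

import numpy as np
import pytest

from popsweep import sweepscan
from popsweep.popstats import WindowSpec, WindowTrack
from popsweep.sweepscan import (CLRTrack, GeneticMap, SweepModel, call_sweeps,
                                clr_at_gridpoint, escape_probability,
                                estimate_drift_variance,
                                interpolate_genetic_position, null_loglik,
                                scan_chromosome, sweep_loglik,
                                tabulate_windows, _prepare_snps)

from _oracles import dense_null_marginal


class TestGeneticMap:
    def test_midpoint_between_anchors(self):
        gm = GeneticMap({"chr1": (np.array([0.0, 1e6]), np.array([0.0, 1.0]))})
        assert interpolate_genetic_position(500_000, "chr1", gm) == pytest.approx(0.005)

    def test_anchor_value_returned_exactly(self):
        gm = GeneticMap({"chr1": (np.array([100.0, 1e6]), np.array([0.1, 1.0]))})
        assert interpolate_genetic_position(100, "chr1", gm) == pytest.approx(0.001)

    def test_fallback_rate_without_map(self):
        assert interpolate_genetic_position(250_000) == pytest.approx(0.0025)

    def test_decreasing_cm_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap({"chr1": (np.array([0.0, 100.0]), np.array([1.0, 0.5]))})

    def test_extrapolation_beyond_anchors(self):
        gm = GeneticMap({"chr1": (np.array([1e6, 2e6]), np.array([1.0, 2.0]))})
        assert interpolate_genetic_position(3e6, "chr1", gm) == pytest.approx(0.03)


class TestDriftVariance:
    def test_no_drift_hits_floor(self):
        p = np.random.default_rng(0).uniform(0.1, 0.9, 1_000)
        n = np.full(1_000, 10_000_000)
        x = np.round(p * n).astype(int)
        assert estimate_drift_variance(p, x, n) == pytest.approx(1e-6, abs=1e-4)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 1_000)
        n = np.full(1_000, 60)
        x = rng.binomial(n, p)
        a = estimate_drift_variance(p, x, n)
        b = estimate_drift_variance(1 - p, n - x, n)
        assert a == pytest.approx(b, rel=1e-12)

    def test_balding_nichols_recovery(self):
        rng = np.random.default_rng(2)
        F = 0.1
        p0 = rng.uniform(0.05, 0.95, 20_000)
        p1 = rng.beta(p0 * (1 - F) / F, (1 - p0) * (1 - F) / F)
        n = np.full(20_000, 60)
        x = rng.binomial(n, p1)
        assert abs(estimate_drift_variance(p0, x, n) - F) < 0.02

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            estimate_drift_variance(np.full(100, 0.5), np.full(100, 5), np.full(100, 10))


class TestNullLikelihood:
    def test_normalises_over_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p0, om = rng.uniform(0.05, 0.95), rng.uniform(0.005, 0.5)
            n = int(rng.integers(2, 50))
            total = sum(math.exp(null_loglik(x, n, p0, om)) for x in range(n + 1))
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_omega_is_binomial(self):
        from scipy.stats import binom
        for x, n, p0 in [(5, 10, 0.5), (7, 20, 0.37), (0, 12, 0.8)]:
            assert null_loglik(x, n, p0, 1e-8) == pytest.approx(
                binom.logpmf(x, n, p0), abs=1e-6)

    def test_matches_dense_grid_refinement(self):
        dense = dense_null_marginal(5, 10, 0.5, 0.1, k=100_000)
        assert null_loglik(5, 10, 0.5, 0.1) == pytest.approx(dense, abs=1e-5)
        # refining the latent grid converges on the brute-force value
        assert null_loglik(5, 10, 0.5, 0.1, n_latent=8_192) == pytest.approx(dense, abs=1e-7)
        # 512 -> 4096 refinement moves the log-likelihood by < 1e-4
        assert abs(null_loglik(5, 10, 0.5, 0.1, n_latent=4_096)
                   - null_loglik(5, 10, 0.5, 0.1)) < 1e-4

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            null_loglik(5, 10, 0.5, 0.0)
        with pytest.raises(ValueError):
            null_loglik(11, 10, 0.5, 0.1)
        with pytest.raises(ValueError):
            null_loglik(5, 10, 1.0, 0.1)


class TestEscapeProbability:
    def test_zero_distance_fully_hitchhikes(self):
        assert escape_probability(0.0, 0.01, 1e4) == 0.0

    def test_far_away_equals_null(self):
        assert escape_probability(1e6, 0.01, 1e4) == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        expected = 1 - math.exp(-1e-4 * math.log(200) / 0.01)
        assert escape_probability(1e-4, 0.01, 1e4) == pytest.approx(expected, rel=1e-12)

    def test_weak_selection_collapses_to_null(self):
        assert escape_probability(1e-4, 1e-6, 1e4) == 1.0


class TestSweepLikelihood:
    def test_c_one_nests_null_exactly(self):
        for x, n, p0, om in [(5, 10, 0.5, 0.1), (52, 52, 0.88, 0.28), (0, 30, 0.2, 0.05)]:
            assert abs(sweep_loglik(x, n, p0, om, 1.0) - null_loglik(x, n, p0, om)) < 1e-12

    def test_normalises_over_counts(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p0, om, c = rng.uniform(0.05, 0.95), rng.uniform(0.005, 0.5), rng.uniform(0, 1)
            n = int(rng.integers(2, 50))
            total = sum(math.exp(sweep_loglik(x, n, p0, om, c)) for x in range(n + 1))
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_complete_sweep_fixation_mass_near_p0(self):
        # c=0: the tracked allele fixes with probability ~p0
        lik = math.exp(sweep_loglik(20, 20, 0.9, 0.1, 0.0))
        assert lik == pytest.approx(0.9, abs=0.02)
        assert lik > math.exp(null_loglik(20, 20, 0.9, 0.1))


def build_snp_data(bp, p0, x, n, model, omega, ref_dosage=None, seed=0):
    bp = np.asarray(bp, dtype=np.int64)
    gpos = np.asarray(interpolate_genetic_position(bp.astype(float)))
    if ref_dosage is None:
        rng = np.random.default_rng(seed)
        ref_dosage = rng.integers(0, 3, size=(len(bp), 8)).astype(np.int8)
    return _prepare_snps(bp, gpos, np.asarray(p0, float), np.asarray(x),
                         np.asarray(n), ref_dosage, model, omega)


class TestClrGridpoint:
    def test_uncorrelated_snps_have_unit_weights(self):
        model = SweepModel()
        rng = np.random.default_rng(5)
        bp = np.arange(10) * 2_000 + 100_000
        snps = build_snp_data(bp, rng.uniform(0.2, 0.8, 10), rng.integers(0, 30, 10),
                              np.full(10, 30), model, 0.1)
        w = sweepscan._weights(snps, 0, 10)
        if all(len(v) == 0 for v in snps.corr_neighbors):
            np.testing.assert_array_equal(w, np.ones(10))

    def test_duplicating_snps_leaves_clr_unchanged(self):
        model = SweepModel()
        rng = np.random.default_rng(6)
        bp = np.sort(rng.choice(np.arange(100_000, 140_000), 20, replace=False))
        p0 = rng.uniform(0.2, 0.8, 20)
        x = rng.integers(0, 31, 20)
        n = np.full(20, 30)
        ref = rng.integers(0, 3, size=(20, 8)).astype(np.int8)
        single = build_snp_data(bp, p0, x, n, model, 0.1, ref)
        # duplicate every SNP 1 bp apart with identical reference genotypes
        bp2 = np.sort(np.concatenate([bp, bp + 1]))
        order = np.argsort(np.concatenate([bp, bp + 1]), kind="stable")
        dup = lambda a: np.concatenate([a, a])[order]
        double = build_snp_data(bp2, dup(p0), dup(x), dup(n), model, 0.1,
                                np.concatenate([ref, ref])[order])
        g = 120_000.0
        c1, _, _ = clr_at_gridpoint(g, single, model, 0.1)
        c2, _, _ = clr_at_gridpoint(g, double, model, 0.1)
        assert c2 == pytest.approx(c1, abs=1e-6)

    def test_clr_non_negative(self):
        model = SweepModel()
        rng = np.random.default_rng(7)
        for seed in range(5):
            bp = np.sort(rng.choice(np.arange(100_000, 160_000), 40, replace=False))
            p0 = rng.uniform(0.1, 0.9, 40)
            n = np.full(40, 30)
            x = rng.binomial(n, p0)
            snps = build_snp_data(bp, p0, x, n, model, 0.15, seed=seed)
            clr, _, _ = clr_at_gridpoint(130_000.0, snps, model, 0.15)
            assert clr >= -1e-9

    def test_global_allele_relabel_invariance(self):
        model = SweepModel()
        rng = np.random.default_rng(8)
        bp = np.sort(rng.choice(np.arange(100_000, 150_000), 30, replace=False))
        p0 = rng.uniform(0.1, 0.9, 30)
        n = np.full(30, 30)
        x = rng.binomial(n, np.clip(p0 + 0.3, 0, 1))
        ref = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        a = build_snp_data(bp, p0, x, n, model, 0.2, ref)
        b = build_snp_data(bp, 1 - p0, n - x, n, model, 0.2, (2 - ref).astype(np.int8))
        ca, _, _ = clr_at_gridpoint(125_000.0, a, model, 0.2)
        cb, _, _ = clr_at_gridpoint(125_000.0, b, model, 0.2)
        assert cb == pytest.approx(ca, abs=1e-6)

    def test_empty_window_undefined(self):
        model = SweepModel()
        snps = build_snp_data([100_000], [0.5], [10], [20], model, 0.1)
        clr, s, k = clr_at_gridpoint(90_000_000.0, snps, model, 0.1)
        assert math.isnan(clr) and k == 0

    def test_planted_contrast_beats_neutral(self):
        # swept SNPs (objective near fixation) versus matched neutral SNPs
        model = SweepModel()
        rng = np.random.default_rng(9)
        bp = np.sort(rng.choice(np.arange(100_000, 150_000), 60, replace=False))
        p0 = rng.uniform(0.2, 0.8, 60)
        n = np.full(60, 60)
        x_neutral = rng.binomial(n, p0)
        x_swept = rng.binomial(n, 0.95 + 0.05 * p0)
        neutral = build_snp_data(bp, p0, x_neutral, n, model, 0.1)
        swept = build_snp_data(bp, p0, x_swept, n, model, 0.1)
        c_neutral, _, _ = clr_at_gridpoint(125_000.0, neutral, model, 0.1)
        c_swept, _, _ = clr_at_gridpoint(125_000.0, swept, model, 0.1)
        assert c_swept > max(c_neutral, 10.0)


class TestTabulation:
    def mk_track(self, bp, clr):
        return CLRTrack(chrom=np.array(["chr1"] * len(bp), dtype=object),
                        bp=np.asarray(bp, dtype=np.int64),
                        clr=np.asarray(clr, dtype=float),
                        s_hat=np.full(len(bp), np.nan),
                        n_snps=np.ones(len(bp), dtype=np.int64))

    def test_toy_enumeration(self):
        track = self.mk_track([2_000, 7_000, 12_000], [1.0, 3.0, 2.0])
        win = tabulate_windows(track, 10_000, chrom_lengths={"chr1": 20_000})
        assert win.value.tolist() == [3.0, 2.0]

    def test_single_point_window(self):
        track = self.mk_track([2_000], [1.5])
        win = tabulate_windows(track, 10_000, chrom_lengths={"chr1": 10_000})
        assert win.value.tolist() == [1.5]

    def test_empty_window_undefined(self):
        track = self.mk_track([2_000], [1.5])
        win = tabulate_windows(track, 10_000, chrom_lengths={"chr1": 30_000})
        assert math.isnan(win.value[1]) and math.isnan(win.value[2])


def window_track(values, chrom="chr1", size=10_000):
    values = np.asarray(values, dtype=float)
    return WindowTrack(
        chrom=np.array([chrom] * len(values), dtype=object),
        start=np.arange(len(values), dtype=np.int64) * size,
        value=values,
        n_sites=np.ones(len(values), dtype=np.int64),
        spec=WindowSpec(size, size),
    )


class TestCallSweeps:
    def test_three_hundred_window_enumeration(self):
        # scores 1..300; top 3% threshold = order statistic at rank 291 ->
        # windows 291..300 merge into one region with score 300 that also
        # clears the top-1% level
        clr = window_track(np.arange(1, 301))
        ratio = window_track(np.linspace(0.5, 2.0, 300))  # high where CLR high
        regions = call_sweeps(clr, ratio)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.score) == (290 * 10_000, 300 * 10_000, 300.0)

    def test_vacuous_pi_filter_drops_nothing(self):
        clr = window_track(np.arange(1, 301))
        low_ratio = window_track(np.linspace(2.0, 0.5, 300))  # low where CLR high
        with_filter = call_sweeps(clr, low_ratio, pi_top=0.5)
        without = call_sweeps(clr, low_ratio, pi_top=1.0)
        assert len(without) >= len(with_filter)
        assert len(without) == 1

    def test_pi_ratio_filter_excludes_low_ratio_regions(self):
        clr = window_track(np.arange(1, 301))
        low_ratio = window_track(np.linspace(2.0, 0.5, 300))
        assert call_sweeps(clr, low_ratio, pi_top=0.5) == []

    def test_all_undefined_ratio_rejected(self):
        clr = window_track(np.arange(1, 301))
        bad = window_track(np.full(300, np.nan))
        with pytest.raises(ValueError):
            call_sweeps(clr, bad)


class TestScanChromosome:
    def test_track_has_expected_grid_and_bounds(self):
        model = SweepModel(grid_bp=1_000)
        rng = np.random.default_rng(10)
        bp = np.sort(rng.choice(np.arange(1, 200_000), 300, replace=False)).astype(np.int64)
        p0 = rng.uniform(0.1, 0.9, 300)
        n = np.full(300, 30)
        x = rng.binomial(n, p0)
        ref = rng.integers(0, 3, size=(300, 8)).astype(np.int8)
        gpos = np.asarray(interpolate_genetic_position(bp.astype(float)))
        track = scan_chromosome("chr1", bp, gpos, p0, x, n, ref, model, 0.1, 200_000)
        assert len(track.bp) == 200
        defined = ~np.isnan(track.clr)
        assert defined.any()
        assert np.all(track.clr[defined] >= -1e-9)
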