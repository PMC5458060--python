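"""Diversity, Weir-Cockerham FST, windows and region calling."""
import numpy as np
import pytest

from popsweep import popstats, variants
from popsweep.popstats import (Region, WindowSpec, WindowTrack,
                               fst_site_components, genes_in_regions,
                               merge_regions, pi_ratio, site_pi,
                               top_quantile_regions, windowed_fst, windowed_pi)
from popsweep.variants import MISSING, GenotypeMatrix, SampleTable

from _oracles import brute_force_window_pi, wc84_components


def make_matrix(dosage, pos=None, chrom="chr1"):
    dosage = np.asarray(dosage, dtype=np.int8)
    S, N = dosage.shape
    return GenotypeMatrix(
        chrom=np.array([chrom] * S, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, S + 1) * 50, dtype=np.int64),
        ref=np.array(["A"] * S, dtype=object),
        alt=np.array(["G"] * S, dtype=object),
        dosage=dosage,
        samples=[f"s{i}" for i in range(N)],
    )


def two_pop_table(n1, n2):
    pops = {f"s{i}": variants.WILD for i in range(n1)}
    pops.update({f"s{i}": variants.CULTIVATED for i in range(n1, n1 + n2)})
    return SampleTable(pops)


class TestSitePi:
    def test_monomorphic_is_zero(self):
        assert site_pi(np.array([0, 0, 0])) == 0.0
        assert site_pi(np.array([2, 2])) == 0.0

    def test_two_heterozygotes(self):
        # c1=2 of n=4 alleles: pi = 2*2/C(4,2) = 2/3
        assert site_pi(np.array([1, 1])) == pytest.approx(2 / 3)

    def test_balanced_counts_maximise(self):
        n = 10  # 5 diploids
        vals = [site_pi(np.array([2] * k + [0] * (5 - k))) for k in range(6)]
        assert np.argmax(vals) in (2, 3)  # c1 = 4 or 6 of 10 brackets n/2

    def test_too_few_alleles_undefined(self):
        assert np.isnan(site_pi(np.array([MISSING, MISSING])))
        # a single genotyped diploid already contributes two alleles
        assert site_pi(np.array([MISSING, MISSING, 1])) == pytest.approx(1.0)


class TestWindowedPi:
    def test_single_snp_per_bp_value(self):
        m = make_matrix(np.array([[1, 1]]), pos=[5_000])
        t = two_pop_table(2, 0)
        track = windowed_pi(m, t, variants.WILD, WindowSpec(10_000, 10_000),
                            chrom_lengths={"chr1": 10_000})
        assert track.value[0] == pytest.approx((2 / 3) / 10_000)

    def test_empty_window_is_zero(self):
        m = make_matrix(np.array([[1, 1]]), pos=[5_000])
        t = two_pop_table(2, 0)
        track = windowed_pi(m, t, variants.WILD, WindowSpec(10_000, 10_000),
                            chrom_lengths={"chr1": 30_000})
        assert track.value[1] == 0.0 and track.value[2] == 0.0

    def test_doubling_step_halves_window_count(self):
        m = make_matrix(np.ones((5, 2)), pos=[100, 200, 300, 400, 500])
        t = two_pop_table(2, 0)
        n1 = len(windowed_pi(m, t, variants.WILD, WindowSpec(10_000, 1_000),
                             chrom_lengths={"chr1": 100_000}).start)
        n2 = len(windowed_pi(m, t, variants.WILD, WindowSpec(10_000, 2_000),
                             chrom_lengths={"chr1": 100_000}).start)
        assert abs(n1 - 2 * n2) <= 1

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(0)
        for trial in range(200):
            S = rng.integers(2, 50)
            N = rng.integers(2, 10)
            d = rng.integers(-1, 3, size=(S, N)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 2_001), size=S, replace=False))
            m = make_matrix(d, pos=pos)
            t = two_pop_table(N, 0)
            spec = WindowSpec(1_000, 500)
            track = windowed_pi(m, t, variants.WILD, spec, min_genotyped=0.0,
                                chrom_lengths={"chr1": 2_000})
            ok = np.array([site_pi(row) == site_pi(row) for row in d])  # >=2 alleles
            for w, start in enumerate(track.start):
                expected = brute_force_window_pi(d, pos, int(start), spec.size,
                                                 min_genotyped_mask=ok)
                assert track.value[w] == pytest.approx(expected, abs=1e-12)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(5)
        d = rng.integers(-1, 3, size=(40, 6)).astype(np.int8)
        m1 = make_matrix(d)
        flip = rng.random(40) < 0.5
        d2 = d.copy()
        d2[flip] = np.where(d2[flip] == MISSING, MISSING, 2 - d2[flip])
        m2 = make_matrix(d2)
        t = two_pop_table(6, 0)
        a = windowed_pi(m1, t, variants.WILD, chrom_lengths={"chr1": 3_000})
        b = windowed_pi(m2, t, variants.WILD, chrom_lengths={"chr1": 3_000})
        np.testing.assert_allclose(a.value, b.value, atol=1e-15)


class TestPiRatio:
    def test_equal_tracks_give_one(self):
        spec = WindowSpec(10_000, 10_000)
        mk = lambda v: WindowTrack(np.array(["chr1"], dtype=object), np.array([0]),
                                   np.array([v]), np.array([1]), spec)
        assert pi_ratio(mk(3e-4), mk(3e-4)).value[0] == pytest.approx(1.0)

    def test_zero_denominator_flagged_undefined(self):
        spec = WindowSpec(10_000, 10_000)
        mk = lambda v: WindowTrack(np.array(["chr1"], dtype=object), np.array([0]),
                                   np.array([v]), np.array([1]), spec)
        assert np.isnan(pi_ratio(mk(3e-4), mk(0.0)).value[0])

    def test_grid_mismatch_rejected(self):
        a = WindowTrack(np.array(["chr1"], dtype=object), np.array([0]),
                        np.array([1.0]), np.array([1]), WindowSpec(10_000, 10_000))
        b = WindowTrack(np.array(["chr1"], dtype=object), np.array([0]),
                        np.array([1.0]), np.array([1]), WindowSpec(10_000, 5_000))
        with pytest.raises(ValueError):
            pi_ratio(a, b)


class TestFst:
    def test_both_fixed_same_allele(self):
        a, b, c = fst_site_components(np.array([0, 0, 0]), np.array([0, 0, 0, 0]))
        assert (a, b, c) == (0.0, 0.0, 0.0)

    def test_opposite_fixation_gives_one(self):
        a, b, c = fst_site_components(np.array([0, 0, 0, 0]), np.array([2, 2, 2, 2]))
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_toy_table_against_wc84_transcription(self):
        d1 = np.array([0] * 6 + [1] * 2, dtype=np.int8)  # 6 AA, 2 Aa
        d2 = np.array([0] * 1 + [1] * 3 + [2] * 4, dtype=np.int8)  # 1 AA, 3 Aa, 4 aa
        got = fst_site_components(d1, d2)
        expected = wc84_components(d1, d2)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_random_tables_against_transcription(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n1, n2 = rng.integers(2, 10, size=2)
            d1 = rng.integers(-1, 3, size=n1).astype(np.int8)
            d2 = rng.integers(-1, 3, size=n2).astype(np.int8)
            if (d1 != MISSING).sum() < 2 or (d2 != MISSING).sum() < 2:
                continue
            got = fst_site_components(d1, d2)
            expected = wc84_components(d1, d2)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_single_site_window_equals_site_ratio(self):
        d = np.array([[0, 0, 2, 2, 1, 1]], dtype=np.int8)
        m = make_matrix(d, pos=[500])
        t = two_pop_table(2, 4)
        track = windowed_fst(m, t, (variants.WILD, variants.CULTIVATED),
                             WindowSpec(1_000, 1_000), chrom_lengths={"chr1": 1_000})
        a, b, c = fst_site_components(d[0, :2], d[0, 2:])
        assert track.value[0] == pytest.approx(a / (a + b + c))

    def test_monomorphic_window_undefined(self):
        d = np.zeros((3, 6), dtype=np.int8)
        m = make_matrix(d, pos=[100, 200, 300])
        t = two_pop_table(3, 3)
        track = windowed_fst(m, t, (variants.WILD, variants.CULTIVATED),
                             WindowSpec(1_000, 1_000), chrom_lengths={"chr1": 1_000})
        assert np.isnan(track.value[0])

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(50, 8)).astype(np.int8)
        flip = rng.random(50) < 0.5
        d2 = d.copy()
        d2[flip] = 2 - d2[flip]
        t = two_pop_table(4, 4)
        a = windowed_fst(make_matrix(d), t, (variants.WILD, variants.CULTIVATED),
                         chrom_lengths={"chr1": 3_000})
        b = windowed_fst(make_matrix(d2), t, (variants.WILD, variants.CULTIVATED),
                         chrom_lengths={"chr1": 3_000})
        np.testing.assert_allclose(a.value, b.value, atol=1e-12)


def track_from_values(values, size=10_000, step=None, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    step = step or size
    return WindowTrack(
        chrom=np.array([chrom] * len(values), dtype=object),
        start=np.arange(len(values), dtype=np.int64) * step,
        value=values,
        n_sites=np.ones(len(values), dtype=np.int64),
        spec=WindowSpec(size, step),
    )


class TestRegionCalling:
    def test_two_hundred_window_enumeration(self):
        # values 1..200, top 1%: threshold = order stat at ceil(0.99*200)=198,
        # ties included -> windows 198..200 merge into one region, score 200
        track = track_from_values(np.arange(1, 201))
        regions = top_quantile_regions(track, 0.01)
        assert len(regions) == 1
        r = regions[0]
        assert r.score == 200.0
        assert r.end == 200 * 10_000
        assert r.n_windows == 3

    def test_zero_fraction_gives_empty(self):
        track = track_from_values(np.arange(1, 201))
        assert top_quantile_regions(track, 0.0) == []

    def test_constant_track_empty_under_spike_guard(self):
        track = track_from_values(np.full(300, 7.0))
        assert top_quantile_regions(track, 0.01) == []

    def test_merging_idempotent(self):
        track = track_from_values(np.arange(1, 201))
        regions = top_quantile_regions(track, 0.05)
        assert merge_regions(regions) == regions

    def test_regions_sorted_disjoint_cover_thresholded_windows(self):
        rng = np.random.default_rng(3)
        track = track_from_values(rng.random(500))
        regions = top_quantile_regions(track, 0.05)
        for r1, r2 in zip(regions, regions[1:]):
            assert r1.end < r2.start or r1.chrom != r2.chrom
        covered = sum(r.n_windows for r in regions)
        thr = popstats.quantile_threshold(track.value, 0.05)
        assert covered == int((track.value >= thr).sum())

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            top_quantile_regions(track_from_values([1.0, 2.0]), 0.01)


class TestGenesInRegions:
    def test_overlap_rules(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t100\t200\t.\t+\t.\tID=inside\n"
            "chr1\tx\tgene\t950\t1050\t.\t+\t.\tID=edge\n"
            "chr1\tx\tgene\t5000\t6000\t.\t+\t.\tID=outside\n"
        )
        regions = [Region("chr1", 50, 1_000, 1.0)]
        genes = genes_in_regions(regions, gff)
        assert genes == [["inside", "edge"]]
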