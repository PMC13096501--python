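"""Coverage-erosion scoring, shuffled null, and enrichment statistics."""

import math

import numpy as np
import pytest

from rdcnv import (
    BinnedTrack,
    ChromSizes,
    GenomicInterval,
    build_genome,
    compute_log2_ratio,
    erosion_table,
    gen_coverage_pair,
    hypergeom_rdc_enrichment,
    lad_association_test,
    shuffle_regions,
)
from rdcnv.erosion import ShuffleNull


def _const_track(sizes, value, kind="raw_count", bin_size=1000):
    t = BinnedTrack(bin_size, sizes, kind)
    for chrom in sizes:
        t.values[chrom][:] = value
    return t


class TestLog2Ratio:
    def test_identical_tracks_give_zero(self, small_sizes):
        t = _const_track(small_sizes, 42)
        ratio = compute_log2_ratio(t, t.copy())
        for chrom in small_sizes:
            np.testing.assert_allclose(ratio.values[chrom], 0.0)

    def test_halved_depth_bin_is_minus_one(self, small_sizes):
        # equal genome-wide depth, one bin at half coverage
        control = _const_track(small_sizes, 100)
        treat = _const_track(small_sizes, 100)
        treat.values["chr1"][3] = 50.0
        treat.values["chr1"][4] = 150.0  # keeps mean depth equal
        ratio = compute_log2_ratio(treat, control)
        assert ratio.values["chr1"][3] == pytest.approx(-1.0, abs=0.02)

    def test_mismatched_grids_error(self, small_sizes):
        other = ChromSizes({"chr1": 100_000})
        with pytest.raises(ValueError):
            compute_log2_ratio(
                _const_track(small_sizes, 10), _const_track(other, 10)
            )

    def test_missing_bins_propagate(self, small_sizes):
        treat = _const_track(small_sizes, 10)
        control = _const_track(small_sizes, 10)
        treat.values["chr1"][0] = np.nan
        ratio = compute_log2_ratio(treat, control)
        assert math.isnan(ratio.values["chr1"][0])

    def test_planted_deletion_expectation(self, genome):
        # subclonal het deletion at clone fraction 0.8: E[log2 ratio]
        # ~= log2(1 - f/2) = log2(0.6), estimated over >= 200 bins
        dels = [
            (GenomicInterval("chr1", 5_000_000, 6_000_000), 0.8),
            (GenomicInterval("chr2", 10_000_000, 11_000_000), 0.8),
            (GenomicInterval("chr3", 20_000_000, 21_000_000), 0.8),
        ]
        treat, control, _ = gen_coverage_pair(genome, dels, mean_depth=30, seed=5)
        ratio = compute_log2_ratio(treat, control)
        inside = np.concatenate(
            [
                ratio.values[iv.chrom][iv.start // 10_000 : iv.end // 10_000]
                for iv, _ in dels
            ]
        )
        assert inside.size >= 200
        assert np.mean(inside) == pytest.approx(math.log2(0.6), abs=0.05)


class TestShuffleRegions:
    @pytest.fixture()
    def regions(self, genome):
        return genome.rdcs

    def test_count_and_length_multiset_preserved(self, genome, regions):
        null = shuffle_regions(regions, genome.chrom_sizes, n_sets=10, seed=1)
        assert len(null.regions) == 10 * len(regions)
        want = sorted(iv.length for iv in regions)
        for s in null.sets:
            assert sorted(iv.length for iv in s) == want

    def test_ten_sets_of_152_regions_give_1520(self, genome):
        # 152 regions x 10 sets = 1520 size-matched random regions
        rng = np.random.default_rng(2)
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 10_000)
            for s in rng.integers(0, 50_000_000, size=152)
        ]
        null = shuffle_regions(regions, genome.chrom_sizes, n_sets=10, seed=3)
        assert len(null.regions) == 1520

    def test_exclusion_respected(self, genome, regions):
        null = shuffle_regions(
            regions, genome.chrom_sizes, n_sets=5, exclude=regions, seed=4
        )
        for shuffled in null.regions:
            assert not any(shuffled.overlaps(r) for r in regions)

    def test_deterministic_given_seed(self, genome, regions):
        a = shuffle_regions(regions, genome.chrom_sizes, n_sets=2, seed=9)
        b = shuffle_regions(regions, genome.chrom_sizes, n_sets=2, seed=9)
        assert [(i.chrom, i.start) for i in a.regions] == [
            (i.chrom, i.start) for i in b.regions
        ]
        c = shuffle_regions(regions, genome.chrom_sizes, n_sets=2, seed=10)
        assert [(i.chrom, i.start) for i in a.regions] != [
            (i.chrom, i.start) for i in c.regions
        ]

    def test_dense_exclude_raises(self):
        sizes = ChromSizes({"chr1": 1000})
        exclude = [GenomicInterval("chr1", 0, 1000)]
        with pytest.raises(RuntimeError):
            shuffle_regions(
                [GenomicInterval("chr1", 0, 100)],
                sizes,
                n_sets=1,
                exclude=exclude,
                seed=1,
                max_attempts=50,
            )

    def test_null_mean_converges_to_track_mean(self, genome):
        # law of large numbers: pooled null mean ~ genome-wide track mean
        treat, control, _ = gen_coverage_pair(genome, [], mean_depth=30, seed=6)
        ratio = compute_log2_ratio(treat, control)
        null = shuffle_regions(genome.rdcs, genome.chrom_sizes, n_sets=10, seed=7)
        erosion_table(ratio, genome.rdcs, null)
        se = null.sigma0 / math.sqrt(len(null.region_means))
        assert abs(null.mu0 - ratio.genome_mean()) <= 2 * se + 1e-3


class TestErosionTable:
    def _toy_setup(self):
        sizes = ChromSizes({"chr1": 20_000})
        track = BinnedTrack(1000, sizes, "log2_ratio")
        # null regions over bins 0-9 with values mean 0, sd 0.1
        null_vals = np.array([-0.15, -0.1, -0.05, 0.0, 0.0, 0.0, 0.0, 0.05, 0.1, 0.15])
        track.values["chr1"][:10] = null_vals
        track.values["chr1"][10] = -0.35
        track.values["chr1"][11] = 0.0
        null = ShuffleNull(
            sets=[[GenomicInterval("chr1", b * 1000, (b + 1) * 1000) for b in range(10)]],
            seed=None,
        )
        rdcs = [
            GenomicInterval("chr1", 10_000, 11_000, name="hit"),
            GenomicInterval("chr1", 11_000, 12_000, name="calm"),
        ]
        return track, rdcs, null

    def test_deviation_arithmetic_and_flagging(self):
        track, rdcs, null = self._toy_setup()
        table = erosion_table(track, rdcs, null)
        sigma0 = np.std(null.region_means, ddof=1)
        row = table.set_index("name").loc["hit"]
        assert row["sd_deviation"] == pytest.approx(-0.35 / sigma0)
        assert row["sd_deviation"] < -3
        assert bool(row["flag_3sd"])
        assert not bool(table.set_index("name").loc["calm"]["flag_3sd"])

    def test_ranks_are_permutation_sorted_by_mean(self):
        track, rdcs, null = self._toy_setup()
        table = erosion_table(track, rdcs, null)
        assert sorted(table["rank"]) == list(range(1, len(rdcs) + 1))
        assert table["mean_log2"].is_monotonic_decreasing

    def test_no_flags_when_means_equal_null_mean(self):
        track, rdcs, null = self._toy_setup()
        table = erosion_table(track, [rdcs[1]], null)
        assert not table["flag_3sd"].any()

    def test_degenerate_null_errors(self, small_sizes):
        track = _const_track(small_sizes, 0.0, kind="log2_ratio")
        null = ShuffleNull(
            sets=[[GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 2000, 3000)]],
            seed=None,
        )
        with pytest.raises(ValueError, match="degenerate"):
            erosion_table(track, [GenomicInterval("chr1", 0, 1000)], null)

    def test_deviations_invariant_under_constant_shift(self, genome):
        treat, control, _ = gen_coverage_pair(
            genome, [(genome.rdcs[0], 0.8)], mean_depth=30, seed=8
        )
        ratio = compute_log2_ratio(treat, control)
        null = shuffle_regions(
            genome.rdcs, genome.chrom_sizes, n_sets=5, exclude=genome.rdcs, seed=9
        )
        t1 = erosion_table(ratio, genome.rdcs, null)
        shifted = ratio.copy()
        for chrom in shifted.values:
            shifted.values[chrom] += 0.7
        null2 = shuffle_regions(
            genome.rdcs, genome.chrom_sizes, n_sets=5, exclude=genome.rdcs, seed=9
        )
        t2 = erosion_table(shifted, genome.rdcs, null2)
        np.testing.assert_allclose(
            t1["sd_deviation"].to_numpy(), t2["sd_deviation"].to_numpy(), atol=1e-9
        )

    def test_planted_deletions_flagged_exactly(self, genome):
        dels = [(genome.rdcs[i], 0.8) for i in range(5)]
        treat, control, _ = gen_coverage_pair(genome, dels, mean_depth=30, seed=10)
        ratio = compute_log2_ratio(treat, control)
        null = shuffle_regions(
            genome.rdcs, genome.chrom_sizes, n_sets=10, exclude=genome.rdcs, seed=11
        )
        table = erosion_table(ratio, genome.rdcs, null)
        flagged = set(table.loc[table["flag_3sd"], "name"])
        assert flagged == {iv.name for iv, _ in dels}


class TestHypergeom:
    def test_all_six_cnvs_in_rdc_genes(self):
        # all six recurrent CNVs in RDC genes, population ~35,771 genes
        p = hypergeom_rdc_enrichment(35771, 152, 6, 6)
        assert p == pytest.approx(5.33e-15, rel=5e-3)

    def test_certain_outcome(self):
        assert hypergeom_rdc_enrichment(100, 0, 7, 0) == 1.0

    def test_small_case_closed_form(self):
        assert hypergeom_rdc_enrichment(10, 5, 2, 2) == pytest.approx(
            math.comb(5, 2) / math.comb(10, 2)
        )

    def test_matches_exhaustive_enumeration(self):
        # upper tail by direct enumeration for all small populations
        rng = np.random.default_rng(12)
        for _ in range(50):
            n_pop = int(rng.integers(2, 26))
            n_succ = int(rng.integers(0, n_pop + 1))
            n_draw = int(rng.integers(1, n_pop + 1))
            k = int(rng.integers(0, min(n_succ, n_draw) + 1))
            expected = sum(
                math.comb(n_succ, i) * math.comb(n_pop - n_succ, n_draw - i)
                for i in range(k, min(n_succ, n_draw) + 1)
                if n_draw - i <= n_pop - n_succ
            ) / math.comb(n_pop, n_draw)
            assert hypergeom_rdc_enrichment(
                n_pop, n_succ, n_draw, k
            ) == pytest.approx(expected, rel=1e-9)

    def test_invalid_ordering_errors(self):
        with pytest.raises(ValueError):
            hypergeom_rdc_enrichment(10, 5, 3, 4)


class TestLadAssociation:
    def test_cnv_lad_contingency_table(self):
        # CNV RDCs in/out of LADs vs CNV-free late RDCs in/out
        _stat, p = lad_association_test([[5, 1], [17, 40]])
        assert round(p, 3) == 0.009

    def test_homogeneous_table(self):
        stat, p = lad_association_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            t = rng.integers(1, 50, size=(2, 2)).astype(float)
            row = t.sum(axis=1, keepdims=True)
            col = t.sum(axis=0, keepdims=True)
            expected_counts = row @ col / t.sum()
            oracle = ((t - expected_counts) ** 2 / expected_counts).sum()
            stat, _ = lad_association_test(t)
            assert stat == pytest.approx(oracle, rel=1e-9)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            lad_association_test([[0, 0], [3, 4]])
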