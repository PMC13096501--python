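"""Junction metrics: microhomology, bait length, JPTM, spectra and tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdcnv import (
    GenomicInterval,
    add_junction_metrics,
    bait_length,
    binwise_group_test,
    build_genome,
    gen_junction_table,
    jptm,
    mh_spectrum,
    microhomology,
    paired_rdc_density_test,
    parse_tlx,
    write_tlx,
)
from rdcnv.junctions import (
    INTERCHROMOSOMAL,
    INTRA_DISTAL,
    INTRA_NEAR_BAIT,
    classify_junctions,
)


def tlx_frame(rows):
    cols = [
        "Library", "B_Rname", "B_Strand", "B_Rstart", "B_Rend", "B_Qend",
        "PrimStartCo", "Rname", "Junction", "Strand", "Qstart",
    ]
    return pd.DataFrame(rows, columns=cols)


BASE_ROW = ("lib1", "chr1", "+", 1000, 1050, 51, 1000, "chr2", 5_000_000, "+", 52)


class TestMicrohomology:
    @pytest.mark.parametrize(
        "qstart_offset,expected",
        [(1, 0), (-1, 2), (4, -3), (0, 1), (-9, 10)],
    )
    def test_identity_cases(self, qstart_offset, expected):
        b_qend = 60
        assert microhomology(b_qend + qstart_offset, b_qend) == expected

    def test_vectorised(self):
        mh = microhomology(np.array([61, 59, 64]), np.array([60, 60, 60]))
        np.testing.assert_array_equal(mh, [0, 2, -3])


class TestBaitLength:
    def test_plus_strand(self):
        assert bait_length(100, 120, 101, "+") == 20

    def test_minus_strand(self):
        assert bait_length(181, 250, 200, "-") == 20

    def test_invalid_flagged_nan(self):
        assert np.isnan(bait_length(90, 100, 120, "+"))

    def test_bad_strand_errors(self):
        with pytest.raises(ValueError):
            bait_length(1, 10, 5, "x")


class TestTlxIO:
    def test_parse_well_formed(self, tmp_path):
        p = tmp_path / "a.tlx"
        write_tlx(tlx_frame([BASE_ROW] * 3), p)
        df = parse_tlx(p)
        assert len(df) == 3

    def test_invalid_rows_dropped(self, tmp_path):
        bad = list(BASE_ROW)
        bad[3], bad[4] = 2000, 1000  # B_Rstart > B_Rend
        p = tmp_path / "b.tlx"
        write_tlx(tlx_frame([BASE_ROW, tuple(bad)]), p)
        df = parse_tlx(p)
        assert len(df) == 1

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "c.tlx"
        tlx_frame([BASE_ROW]).drop(columns=["Qstart"]).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="Qstart"):
            parse_tlx(p)

    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        g = build_genome(seed=3)
        table, _ = gen_junction_table(
            g, ("chr1", 30_000_000, "+"), n_junctions_per_library=50,
            n_libraries=2, seed=int(rng.integers(2**31)),
        )
        p = tmp_path / "rt.tlx"
        write_tlx(table, p)
        back = parse_tlx(p)
        pd.testing.assert_frame_equal(back, table)


class TestClassification:
    def test_one_mb_rule_flips(self):
        near = tlx_frame([BASE_ROW])
        near["Rname"] = "chr1"
        near["Junction"] = 30_000_000 + 900_000
        far = near.copy()
        far["Junction"] = 30_000_000 + 1_100_000
        inter = near.copy()
        inter["Rname"] = "chr2"
        assert classify_junctions(near, "chr1", 30_000_000)[0] == INTRA_NEAR_BAIT
        assert classify_junctions(far, "chr1", 30_000_000)[0] == INTRA_DISTAL
        assert classify_junctions(inter, "chr1", 30_000_000)[0] == INTERCHROMOSOMAL


class TestJptm:
    def test_direct_formula(self):
        assert jptm(50, 10_000, 2_000_000) == pytest.approx(2.5)

    def test_zero_count(self):
        assert jptm(0, 100, 1_000_000) == 0.0

    @pytest.mark.parametrize("count,total,length", [(1, 0, 10), (1, 10, 0)])
    def test_degenerate_inputs_error(self, count, total, length):
        with pytest.raises(ValueError):
            jptm(count, total, length)

    def test_union_equals_length_weighted_mean(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=8)
        lengths = rng.integers(100_000, 3_000_000, size=8).astype(float)
        total = 10_000
        union = jptm(counts.sum(), total, lengths.sum())
        weighted = float(
            np.sum([jptm(c, total, l) * l for c, l in zip(counts, lengths)])
            / lengths.sum()
        )
        assert union == pytest.approx(weighted, rel=1e-12)


class TestMhSpectrum:
    def test_point_mass_at_zero(self):
        rows = []
        for _ in range(20):
            r = list(BASE_ROW)
            r[10] = r[5] + 1  # Qstart = B_Qend + 1 -> MH 0
            rows.append(tuple(r))
        per_lib, summary = mh_spectrum(tlx_frame(rows))
        assert per_lib.loc["lib1", 0] == 1.0
        assert per_lib.loc["lib1", list(range(1, 11))].sum() == 0.0

    def test_frequencies_sum_to_one_per_library(self):
        g = build_genome(seed=4)
        table, _ = gen_junction_table(
            g, ("chr1", 30_000_000, "+"), n_junctions_per_library=500,
            n_libraries=3, seed=5,
        )
        per_lib, _ = mh_spectrum(table)
        np.testing.assert_allclose(per_lib.sum(axis=1).to_numpy(), 1.0)

    def test_partition_of_all_junctions(self):
        g = build_genome(seed=6)
        table, _ = gen_junction_table(
            g, ("chr1", 30_000_000, "+"), n_junctions_per_library=2000,
            n_libraries=1, seed=7,
        )
        mh = add_junction_metrics(table)["MH"]
        assert ((mh >= 0) & (mh <= 10)).sum() + (mh < 0).sum() + (
            mh > 10
        ).sum() == len(table)

    def test_peak_recovery_from_generator(self):
        g = build_genome(seed=8)
        table, truth = gen_junction_table(
            g, ("chr1", 30_000_000, "+"), n_junctions_per_library=5000,
            n_libraries=2, seed=9,
        )
        _, summary = mh_spectrum(table)
        assert summary["mean"].idxmax() == 2
        probs = truth.params["mh_probs"]
        in_range_mass = sum(v for k, v in probs.items() if 0 <= k <= 10)
        assert summary.loc[2, "mean"] == pytest.approx(
            probs[2] / in_range_mass, abs=0.03
        )


class TestBinwiseGroupTest:
    def _freq_matrix(self, rng, n_lib=4, shift_bin=None, shift=0.0):
        base = rng.normal(0.1, 0.01, size=(n_lib, 11))
        if shift_bin is not None:
            base[:, shift_bin] += shift
        return pd.DataFrame(base, columns=list(range(11)))

    def test_identical_conditions_no_flags(self):
        rng = np.random.default_rng(10)
        a = self._freq_matrix(rng)
        table = binwise_group_test(a, a.copy())
        assert not table["significant"].any()

    def test_single_shifted_bin_flagged(self):
        rng = np.random.default_rng(11)
        a = self._freq_matrix(rng)
        b = self._freq_matrix(rng, shift_bin=2, shift=0.1)  # 10 SDs
        table = binwise_group_test(a, b).set_index("bin")
        assert bool(table.loc[2, "significant"])
        assert not table.drop(index=2)["significant"].any()

    def test_bh_adjustment_monotone_in_p_rank(self):
        rng = np.random.default_rng(12)
        a = self._freq_matrix(rng)
        b = self._freq_matrix(rng, shift_bin=5, shift=0.05)
        table = binwise_group_test(a, b).sort_values("p")
        assert table["q"].is_monotonic_increasing

    def test_too_few_libraries_errors(self):
        rng = np.random.default_rng(13)
        a = self._freq_matrix(rng, n_lib=1)
        with pytest.raises(ValueError):
            binwise_group_test(a, a)


class TestPairedDensityTest:
    def test_identical_conditions_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = paired_rdc_density_test(a, a)
        assert (t, p) == (0.0, 1.0)

    def test_uniform_shift_highly_significant(self):
        rng = np.random.default_rng(14)
        a = rng.uniform(1, 3, size=40)
        b = a - 0.5 + rng.normal(0, 0.01, size=40)
        _, p = paired_rdc_density_test(a, b)
        assert p < 1e-3

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=25)
        b = rng.normal(0.3, size=25)
        t, p = paired_rdc_density_test(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), len(d) - 1)
        assert t == pytest.approx(t_oracle, rel=1e-12)
        assert p == pytest.approx(p_oracle, rel=1e-12)


class TestBaitShortening:
    def test_shift_recovered_between_conditions(self):
        g = build_genome(seed=16)
        bait = ("chr1", 30_000_000, "+")
        cond_a, _ = gen_junction_table(
            g, bait, n_junctions_per_library=3000, n_libraries=3, seed=17
        )
        cond_b, _ = gen_junction_table(
            g, bait, n_junctions_per_library=3000, n_libraries=3,
            bait_shorten_bp=15, seed=18,
        )
        blen_a = add_junction_metrics(cond_a).groupby("Library")["Blen"].mean()
        blen_b = add_junction_metrics(cond_b).groupby("Library")["Blen"].mean()
        assert blen_a.mean() - blen_b.mean() == pytest.approx(15, abs=2)
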