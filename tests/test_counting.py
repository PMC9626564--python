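"""Read filtering, count normalization and coverage statistics."""

import numpy as np
import pandas as pd
import pytest

from fragcal import (
    AlignedRead,
    BiasModel,
    count_and_normalize,
    count_ratio,
    coverage_profile,
    filter_reads,
    length_concordance,
    load_alignments,
    simulate_library,
    threshold_summary,
)
from fragcal.counting import MalformedInputError
from fragcal.digest import inventory_frame

from conftest import FLAT_ENDS, make_fragment, truth_count_table


def primary(read_id, fragment_id, length, start=0):
    return AlignedRead(read_id, fragment_id, length, "primary", start, start + length)


def inv_of(*fragments):
    return inventory_frame(list(fragments))


class TestLoadAlignments:
    def test_sam_round_trip_matches_truth(self, tmp_path, flat_library):
        library, fragments = flat_library
        path = tmp_path / "lib.sam"
        library.to_sam(path)
        reads = load_alignments(path, inventory_frame(fragments))
        assert len(reads) == len(library.reads) + int(library.truth["n_chimeric"].sum())
        by_type = pd.Series([r.alignment_type for r in reads]).value_counts()
        assert by_type.get("supplementary", 0) == int(library.truth["n_chimeric"].sum())

    def test_empty_sam_body(self, tmp_path):
        path = tmp_path / "empty.sam"
        path.write_text("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:f1\tLN:100\n")
        assert load_alignments(path) == []

    def test_unknown_reference_goes_to_unassigned(self, tmp_path):
        path = tmp_path / "lib.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:mystery\tLN:100\n"
            "r1\t0\tmystery\t1\t60\t50M\t*\t0\t0\t*\t*\n"
        )
        inv = inv_of(make_fragment("f1", 100))
        with pytest.warns(UserWarning, match="unassigned"):
            reads = load_alignments(path, inv)
        assert reads[0].fragment_id == "unassigned"


class TestFilterReads:
    def test_supplementary_removes_whole_read(self):
        reads = [
            primary("r1", "f1", 100),
            primary("r2", "f1", 100),
            AlignedRead("r2", "f2", 100, "supplementary", 0, 40),
        ]
        kept = filter_reads(reads)
        assert [r.read_id for r in kept] == ["r1"]

    def test_secondary_and_unmapped_never_counted(self):
        reads = [
            primary("r1", "f1", 100),
            AlignedRead("r1", "f2", 100, "secondary", 0, 90),
            AlignedRead("r3", None, 80, "unmapped"),
        ]
        kept = filter_reads(reads)
        assert [(r.read_id, r.fragment_id) for r in kept] == [("r1", "f1")]

    def test_all_supplementary_means_zero_counts(self):
        reads = [AlignedRead("r1", "f1", 50, "supplementary", 0, 50)]
        assert filter_reads(reads) == []

    def test_two_primaries_is_malformed(self):
        reads = [primary("r1", "f1", 100), primary("r1", "f2", 100)]
        with pytest.raises(MalformedInputError, match="r1"):
            filter_reads(reads)

    def test_filtering_is_a_projection(self, tmp_path, flat_library):
        library, fragments = flat_library
        path = tmp_path / "lib.sam"
        library.to_sam(path)
        reads = load_alignments(path, inventory_frame(fragments))
        once = filter_reads(reads)
        assert filter_reads(once) == once

    def test_chimera_filter_matches_simulation_truth(self, tmp_path, xmn_digest):
        _, fragments = xmn_digest
        bias = BiasModel(length_efficiency="flat", end_efficiency_3p=dict(FLAT_ENDS),
                         incomplete_digest_rate=0.05)
        library = simulate_library(fragments, bias, 20_000, seed=17)
        path = tmp_path / "chim.sam"
        library.to_sam(path)
        kept = filter_reads(load_alignments(path, inventory_frame(fragments)))
        truth_kept = int((library.truth["n_molecules"] - library.truth["n_chimeric"]).sum())
        assert len(kept) == truth_kept


class TestCountAndNormalize:
    def test_fractions_of_simple_counts(self):
        frags = [make_fragment(f"f{i}", 100, seed=i) for i in range(3)]
        reads = [primary("r1", "f0", 100), primary("r2", "f1", 100),
                 primary("r3", "f2", 100), primary("r4", "f2", 100)]
        table = count_and_normalize(reads, inv_of(*frags))
        assert list(table["freq_pct"]) == [25.0, 25.0, 50.0]

    def test_rpm_rpkm_arithmetic(self):
        # c=10 of 1e4 total on a 1 kb fragment: rpm = rpkm = 1000
        frags = [make_fragment("a", 1000, seed=1), make_fragment("b", 500, seed=2)]
        reads = [primary(f"r{i}", "a", 1000) for i in range(10)]
        reads += [primary(f"s{i}", "b", 500) for i in range(9_990)]
        table = count_and_normalize(reads, inv_of(*frags)).set_index("fragment_id")
        assert table.loc["a", "rpm"] == pytest.approx(1000.0)
        assert table.loc["a", "rpkm"] == pytest.approx(1000.0)

    def test_normalization_invariants(self, flat_library):
        library, fragments = flat_library
        table = truth_count_table(library, fragments)
        assert table["freq_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert table["rpm"].sum() == pytest.approx(1e6, rel=1e-12)
        assert np.allclose(table["rpkm"] * table["length"] / 1000.0, table["rpm"])

    def test_zero_count_fragments_are_retained(self):
        frags = [make_fragment("hit", 100, seed=1), make_fragment("miss", 100, seed=2)]
        table = count_and_normalize([primary("r1", "hit", 100)], inv_of(*frags))
        row = table.set_index("fragment_id").loc["miss"]
        assert row["count"] == 0 and row["freq_pct"] == 0.0

    def test_zero_total_reads_is_an_error(self):
        with pytest.raises(ValueError, match="normalization undefined"):
            count_and_normalize([], inv_of(make_fragment("f", 100)))

    def test_equimolar_unbiased_frequencies_within_binomial_noise(self, flat_library):
        library, fragments = flat_library
        table = truth_count_table(library, fragments)
        n = int(table["count"].sum())
        weights = library.truth["sampling_prob"].to_numpy()
        expected = 100.0 * weights
        sd = 100.0 * np.sqrt(weights * (1 - weights) / n)
        assert np.all(np.abs(table["freq_pct"].to_numpy() - expected) < 4 * sd)

    def test_matches_naive_recount_of_truth(self, tmp_path, flat_library):
        library, fragments = flat_library
        path = tmp_path / "lib.sam"
        library.to_sam(path)
        inv = inventory_frame(fragments)
        kept = filter_reads(load_alignments(path, inv))
        table = count_and_normalize(kept, inv).set_index("fragment_id")
        naive = {}
        for read in library.reads:  # no chimeras/shear in this fixture
            naive[read.fragment_id] = naive.get(read.fragment_id, 0) + 1
        for fid, expected in naive.items():
            assert table.loc[fid, "count"] == expected


class TestLengthConcordance:
    def test_intact_reads_match_expected_length(self):
        frags = [make_fragment("f", 500, seed=1)]
        reads = [primary(f"r{i}", "f", 500) for i in range(5)]
        table = count_and_normalize(reads, inv_of(*frags))
        conc = length_concordance(table)
        assert conc.loc[0, "mean_obs_len"] == 500
        assert conc.loc[0, "median_obs_len"] == 500
        assert not conc.loc[0, "shear_suspect"]

    def test_single_read_mean_equals_median(self):
        frags = [make_fragment("f", 300, seed=1)]
        table = count_and_normalize([primary("r", "f", 300)], inv_of(*frags))
        conc = length_concordance(table)
        assert conc.loc[0, "mean_obs_len"] == conc.loc[0, "median_obs_len"] == 300

    def test_sheared_mean_plateaus_while_median_tracks_short_lengths(self):
        lengths = [2_000, 5_000, 10_000, 20_000, 40_000]
        frags = [make_fragment(f"f{L}", L, start=i * 50_000, seed=i)
                 for i, L in enumerate(lengths)]
        bias = BiasModel(length_efficiency="flat", end_efficiency_3p=dict(FLAT_ENDS),
                         shear_rate=1e-4)
        library = simulate_library(frags, bias, 25_000, seed=5)
        reads = [AlignedRead(r.read_id, r.fragment_id, r.end - r.start, "primary",
                             r.start, r.end) for r in library.reads]
        table = count_and_normalize(reads, inv_of(*frags))
        conc = length_concordance(table).set_index("fragment_id")
        means = [conc.loc[f"f{L}", "mean_obs_len"] for L in lengths]
        assert all(a < b for a, b in zip(means, means[1:]))  # monotone
        # plateau: doubling L from 20 kb to 40 kb gains little, and the
        # plateau sits near 1/shear_rate = 10 kb
        assert means[-1] / means[-2] < 1.35
        assert 5_000 < means[-1] < 11_000
        assert conc.loc["f2000", "median_obs_len"] == 2_000
        assert conc.loc["f40000", "shear_suspect"]


class TestCoverageProfile:
    def test_full_span_read_gives_flat_profile(self):
        frags = [make_fragment("f", 1000, seed=1)]
        reads = [primary("r", "f", 1000)]
        prof = coverage_profile(reads, inv_of(*frags), n_bins=10)
        assert np.allclose(prof["depth_norm"], 1.0)

    def test_two_half_reads_give_flat_profile(self):
        frags = [make_fragment("f", 1000, seed=1)]
        reads = [AlignedRead("r1", "f", 500, "primary", 0, 500),
                 AlignedRead("r2", "f", 500, "primary", 500, 1000)]
        prof = coverage_profile(reads, inv_of(*frags), n_bins=10)
        assert np.allclose(prof["depth_norm"], prof["depth_norm"].iloc[0])

    def test_zero_coverage_fragment_is_all_zero(self):
        frags = [make_fragment("a", 100, seed=1), make_fragment("b", 100, seed=2)]
        prof = coverage_profile([primary("r", "a", 100)], inv_of(*frags), n_bins=5)
        b = prof[prof["fragment_id"] == "b"]
        assert (b["depth_norm"] == 0).all()

    def test_sheared_long_fragment_dips_in_the_middle(self):
        frag = make_fragment("long", 25_000, seed=3)
        bias = BiasModel(length_efficiency="short_prep",
                         end_efficiency_3p=dict(FLAT_ENDS), shear_rate=1e-4)
        library = simulate_library([frag], bias, 30_000, seed=6)
        reads = [AlignedRead(r.read_id, r.fragment_id, r.end - r.start, "primary",
                             r.start, r.end) for r in library.reads]
        prof = coverage_profile(reads, inv_of(frag), n_bins=20)
        depth = prof["depth"].to_numpy()
        center = depth[8:12].mean()
        ends = (depth[0] + depth[-1]) / 2.0
        assert center < 0.9 * ends


class TestThresholdSummary:
    def test_all_fragments_above_all_thresholds(self):
        frags = [make_fragment(f"f{i}", 100 + i, seed=i) for i in range(3)]
        reads = [primary("r1", "f0", 100)] * 0 + [
            primary(f"a{i}", "f0", 100) for i in range(50)
        ] + [primary(f"b{i}", "f1", 101) for i in range(49)] + [primary("c", "f2", 102)]
        table = count_and_normalize(reads, inv_of(*frags))
        summary = threshold_summary(table)
        assert summary["n_above"] == {0.001: 3, 0.01: 3, 0.1: 3}
        assert summary["top_k_truncated"]

    def test_single_hit_library(self):
        frags = [make_fragment(f"f{i}", 100 + 10 * i, seed=i) for i in range(25)]
        table = count_and_normalize([primary("r", "f4", 140)], inv_of(*frags))
        summary = threshold_summary(table)
        assert summary["n_above"] == {0.001: 1, 0.01: 1, 0.1: 1}
        # the lone hit tops the ranking; remaining top-20 slots break frequency
        # ties (all zero) toward longer fragments
        assert summary["top_k"] == 20 and not summary["top_k_truncated"]
        assert summary["top_k_length_range"][1] == 340

    def test_summary_equals_brute_force_recount(self, flat_library):
        library, fragments = flat_library
        table = truth_count_table(library, fragments)
        summary = threshold_summary(table)
        freqs = table["freq_pct"].to_numpy()
        for t, n in summary["n_above"].items():
            assert n == int((freqs > t).sum())
        top = table.sort_values(["freq_pct", "length"], ascending=False).head(20)
        assert summary["top_k_median_length"] == top["length"].median()


class TestCountRatio:
    def _tables(self, counts_a, counts_b):
        frags = [make_fragment(f"f{i}", 500 + 100 * i, seed=i) for i in range(len(counts_a))]
        inv = inv_of(*frags)
        reads_a = [primary(f"a{i}.{j}", f"f{i}", 100) for i, c in enumerate(counts_a)
                   for j in range(c)]
        reads_b = [primary(f"b{i}.{j}", f"f{i}", 100) for i, c in enumerate(counts_b)
                   for j in range(c)]
        return count_and_normalize(reads_a, inv), count_and_normalize(reads_b, inv)

    def test_identical_tables_give_unit_ratios(self):
        ta, tb = self._tables([5, 3, 2], [5, 3, 2])
        assert np.allclose(count_ratio(ta, tb)["ratio"], 1.0)

    def test_uniform_scaling_cancels(self):
        ta, tb = self._tables([10, 6, 4], [5, 3, 2])
        assert np.allclose(count_ratio(ta, tb)["ratio"], 1.0)

    def test_zero_denominator_is_undefined_not_error(self):
        ta, tb = self._tables([5, 3, 2], [5, 3, 0])
        ratios = count_ratio(ta, tb)
        assert ratios["ratio"].isna().sum() == 1
        assert ratios.attrs["n_undefined"] == 1

    def test_disjoint_inventories_fatal(self):
        ta, _ = self._tables([1, 1], [1, 1])
        tb = ta.copy()
        tb["fragment_id"] = ["x1", "x2"]
        with pytest.raises(ValueError, match="share no fragments"):
            count_ratio(ta, tb)

    def test_injected_length_dependent_ratio_is_recovered(self, xmn_digest):
        _, fragments = xmn_digest
        r_of = lambda L: 1.0 + L / 20_000.0
        bias_a = BiasModel(length_efficiency=lambda L: r_of(L),
                           end_efficiency_3p=dict(FLAT_ENDS))
        bias_b = BiasModel(length_efficiency="flat", end_efficiency_3p=dict(FLAT_ENDS))
        ta = truth_count_table(simulate_library(fragments, bias_a, 300_000, seed=21), fragments)
        tb = truth_count_table(simulate_library(fragments, bias_b, 300_000, seed=22), fragments)
        ratios = count_ratio(ta, tb, bin_width=2000)
        binned = ratios.attrs["binned"]
        binned = binned[binned["n"] >= 5]
        mid = (binned["bin_lo"] + binned["bin_hi"]) / 2.0
        # within-sample normalization rescales r(L) by a constant
        expected = r_of(mid)
        scale = (binned["mean_ratio"] / expected).mean()
        assert np.all(np.abs(binned["mean_ratio"] / (scale * expected) - 1.0) < 0.10)
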