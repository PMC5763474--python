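"""Putative selection, bias statistics, window scan and cluster calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pirnakit import core
from pirnakit.align import AlignmentRecord, WeightedPlacement, assign_weights
from pirnakit.core import (
    call_clusters,
    cluster_summary,
    first_base_bias,
    length_histogram,
    poisson_window_test,
    select_putative,
    window_scan,
)
from pirnakit.preprocess import UniqueTag


def _placement(pos, weight=1.0, strand="+", chrom="chr1", length=30):
    if strand == "+":
        start, end = pos, pos + length
    else:
        start, end = pos - length + 1, pos + 1
    return WeightedPlacement("A" * length, chrom, start, end, strand, weight)


def brute_force_windows(placements, window, step, last_start):
    """Oracle: per-window membership by direct scan over every placement."""
    counts = {}
    for s in range(0, last_start + 1, step):
        counts[s] = sum(p.weight for p in placements if s <= p.five_prime < s + window)
    return counts


class TestSelectPutative:
    def _tags_with_placements(self, lengths):
        tags, placements = [], {}
        for i, n in enumerate(lengths):
            seq = ("ACGT" * 12)[:n]
            tag = UniqueTag(seq, {"s1": 1})
            tags.append(tag)
            placements[seq] = [WeightedPlacement(seq, "chr1", 0, n, "+", 1.0)]
        return tags, placements

    def test_size_bounds_24_to_35_inclusive(self):
        tags, placements = self._tags_with_placements([23, 24, 35, 36])
        kept = select_putative(tags, placements)
        assert sorted(p.length for p in kept) == [24, 35]

    def test_unmapped_tag_is_excluded_regardless_of_length(self):
        tag = UniqueTag("A" * 30, {"s1": 1})
        assert select_putative([tag], {}) == []

    def test_per_sample_putative_totals_sum_to_pipeline_total(self):
        totals = [332457, 26912, 474028, 918545, 691568, 662523]
        tags, placements = [], {}
        for i, n in enumerate(totals):
            seq = "ACGTACGTACGTACGTACGTACGTA" + "ACGT"[i % 4] * (i + 1)
            seq = seq[:25 + (i % 10)]
            tag = UniqueTag(seq + "G" * i, {f"s{i + 1}": n})
            # keep length within [24, 35]
            tag = UniqueTag(("ACGT" * 9)[:24 + i], {f"s{i + 1}": n})
            tags.append(tag)
            placements[tag.sequence] = [
                WeightedPlacement(tag.sequence, "chr1", 0, len(tag.sequence), "+", 1.0)]
        kept = select_putative(tags, placements)
        assert sum(p.tag.total_count for p in kept) == 3_106_033

    def test_inverted_bounds_raise(self):
        with pytest.raises(ValueError):
            select_putative([], {}, 35, 24)


class TestFirstBaseBias:
    def test_all_t_gives_fraction_one(self):
        tags = [UniqueTag("T" * 25, {"s": 1}) for _ in range(3)]
        bias = first_base_bias(list({t.sequence: t for t in tags}.values()))
        assert bias["T"] == 1.0

    def test_redundant_weighting_forced_arithmetic(self):
        tags = [UniqueTag("TAA", {"s": 2}), UniqueTag("GAA", {"s": 1})]
        bias = first_base_bias(tags, weighting="redundant")
        assert bias["T"] == pytest.approx(2 / 3)
        assert sum(bias.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unique_weighting_ignores_counts(self):
        tags = [UniqueTag("TAA", {"s": 99}), UniqueTag("GAA", {"s": 1})]
        assert first_base_bias(tags, weighting="unique")["T"] == pytest.approx(0.5)

    def test_empty_input_raises_rather_than_nan(self):
        with pytest.raises(ValueError):
            first_base_bias([])

    def test_simulated_u1_bias_recovered_within_three_sd(self, small_dataset):
        spec, _, _, _, origin = small_dataset
        pirna_like = origin[origin.origin.isin(["cluster", "repeat"])]
        bias = first_base_bias(list(pirna_like.insert_seq))
        sd = np.sqrt(0.75 * 0.25 / len(pirna_like))
        assert abs(bias["T"] - spec.u1_probability) <= 3 * sd


class TestLengthHistogram:
    def test_single_tag(self):
        assert length_histogram([UniqueTag("A" * 22, {"s": 1})]) == {22: 1}

    def test_empty_gives_all_zero_over_requested_range(self):
        hist = length_histogram([], min_len=18, max_len=20)
        assert hist == {18: 0, 19: 0, 20: 0}

    def test_simulated_mixture_modes_are_22_and_29(self, small_dataset):
        _, _, _, _, origin = small_dataset
        hist = length_histogram(list(origin.insert_seq))
        short = {k: v for k, v in hist.items() if k <= 25}
        long = {k: v for k, v in hist.items() if k > 25}
        assert max(short, key=short.get) == 22
        assert max(long, key=long.get) == 29


class TestWindowScan:
    def test_single_placement_rpkm_closed_form(self):
        windows = window_scan([_placement(1000)], 2000, 400, library_total=1e6)
        covering = windows[windows.fractional_count > 0]
        # rpkm = 1 / (2 kb) / (1 M/1e6) = 0.5
        assert np.allclose(covering.rpkm, 0.5)

    def test_placement_counted_in_exactly_the_covering_windows(self):
        windows = window_scan([_placement(1000)], 2000, 400)
        covered = set(windows[windows.fractional_count > 0]["start"])
        assert covered == {0, 400, 800}  # starts <= 1000 and > 1000 - 2000

    def test_minus_strand_five_prime_is_the_right_end(self):
        p = _placement(2399, strand="-")
        windows = window_scan([p], 2000, 400, chrom_lengths={"chr1": 4000})
        covered = set(windows[windows.fractional_count > 0]["start"])
        assert covered == {400, 800, 1200, 1600, 2000}

    def test_no_placements_means_all_windows_zero(self):
        windows = window_scan([], 2000, 400, chrom_lengths={"chr1": 10_000})
        assert len(windows) == 25 and (windows.fractional_count == 0).all()

    def test_bad_step_or_window_raises(self):
        with pytest.raises(ValueError):
            window_scan([], 2000, 0)
        with pytest.raises(ValueError):
            window_scan([], 200, 400)

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            placements = [
                _placement(int(pos), weight=float(w), strand=s)
                for pos, w, s in zip(
                    rng.integers(30, 80_000, size=60),
                    rng.random(60) + 0.1,
                    rng.choice(["+", "-"], size=60),
                )
            ]
            windows = window_scan(placements, 2000, 400)
            oracle = brute_force_windows(placements, 2000, 400,
                                         int(windows.start.max()))
            got = dict(zip(windows.start, windows.fractional_count))
            assert set(got) == set(oracle)
            for s in oracle:
                assert got[s] == pytest.approx(oracle[s], abs=1e-9)
            lib = sum(p.weight for p in placements)
            expected_rpkm = windows.fractional_count / 2.0 / (lib / 1e6)
            assert np.allclose(windows.rpkm, expected_rpkm)

    def test_five_prime_counting_conserves_weight_on_nonoverlapping_phase(self):
        rng = np.random.default_rng(8)
        placements = [_placement(int(p)) for p in rng.integers(0, 50_000, 500)]
        windows = window_scan(placements, 2000, 2000,
                              chrom_lengths={"chr1": 52_000})
        assert windows.fractional_count.sum() == pytest.approx(500)


class TestCallClusters:
    def test_adjacent_significant_windows_merge(self):
        placements = [_placement(p) for p in (100, 500, 900, 1300, 2200)]
        windows = window_scan(placements, 2000, 400, library_total=5)
        clusters = call_clusters(windows, placements, rpkm_cutoff=1.0)
        assert len(clusters) == 1
        assert clusters.start.iloc[0] == 0 and clusters.end.iloc[0] >= 2400

    def test_two_distant_windows_stay_separate(self):
        placements = [_placement(100), _placement(8100)]
        windows = window_scan(placements, 2000, 400, library_total=2)
        clusters = call_clusters(windows, placements, rpkm_cutoff=1.0)
        assert len(clusters) == 2

    def test_merge_example_intervals(self):
        windows = pd.DataFrame({
            "chrom": "chr1", "start": [0, 400], "length": 2000,
            "fractional_count": [5.0, 5.0], "rpkm": [10.0, 10.0]})
        windows.attrs["window"] = 2000
        clusters = call_clusters(windows, [_placement(100)], rpkm_cutoff=1.0)
        assert (clusters.start.iloc[0], clusters.end.iloc[0]) == (0, 2400)

    def test_cluster_count_recomputed_without_double_counting(self):
        placements = [_placement(p) for p in (100, 500, 900, 1300)]
        windows = window_scan(placements, 2000, 400, library_total=4)
        clusters = call_clusters(windows, placements, rpkm_cutoff=1.0)
        # 4 placements, each counted once despite 5x overlapping windows
        assert clusters.fractional_count.sum() == pytest.approx(4.0)

    def test_strand_call_thresholds(self):
        plus_heavy = [_placement(100 + i, strand="+") for i in range(9)]
        plus_heavy += [_placement(300, strand="-")]
        windows = window_scan(plus_heavy, 2000, 400, library_total=10)
        clusters = call_clusters(windows, plus_heavy, rpkm_cutoff=0.0001)
        assert clusters.strand_call.iloc[0] == "plus"
        mixed = [_placement(100 + i, strand="+" if i % 2 else "-") for i in range(10)]
        windows = window_scan(mixed, 2000, 400, library_total=10)
        clusters = call_clusters(windows, mixed, rpkm_cutoff=0.0001)
        assert clusters.strand_call.iloc[0] == "dual"

    def test_lowering_cutoff_never_shrinks_covered_length(self):
        rng = np.random.default_rng(9)
        placements = [_placement(int(p)) for p in rng.integers(0, 60_000, 300)]
        windows = window_scan(placements, 2000, 400)
        covered = []
        for cutoff in (50.0, 20.0, 5.0, 1.0, 0.1):
            clusters = call_clusters(windows, placements, rpkm_cutoff=cutoff)
            covered.append(int((clusters.end - clusters.start).sum()))
        assert covered == sorted(covered)

    def test_merging_is_idempotent_under_reordering(self):
        rng = np.random.default_rng(10)
        placements = [_placement(int(p)) for p in rng.integers(0, 30_000, 100)]
        windows = window_scan(placements, 2000, 400)
        shuffled = windows.sample(frac=1.0, random_state=1)
        shuffled.attrs.update(windows.attrs)
        a = call_clusters(windows, placements, 1.0)
        b = call_clusters(shuffled, placements, 1.0)
        pd.testing.assert_frame_equal(a, b)


class TestPoissonWindowTest:
    def _windows(self, counts, library_total, window=2000):
        df = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(len(counts)) * window,
            "length": window, "fractional_count": counts, "rpkm": 0.0})
        df.attrs.update(window=window, library_total=library_total)
        return df

    def test_zero_observation_gives_p_of_one(self):
        out = poisson_window_test(self._windows([0.0], 100.0), 10_000)
        assert out.pvalue.iloc[0] == 1.0

    def test_tail_probability_matches_poisson_oracle(self):
        # lambda = 1 (library 50, window 2000, genome 100k); observed 5
        out = poisson_window_test(self._windows([5.0], 50.0), 100_000)
        expected = 1 - sps.poisson.cdf(4, 1.0)
        assert out.pvalue.iloc[0] == pytest.approx(expected, rel=1e-9)
        assert out.pvalue.iloc[0] == pytest.approx(0.0036598, abs=1e-6)

    def test_fractional_counts_round_up(self):
        out = poisson_window_test(self._windows([4.2], 50.0), 100_000)
        expected = sps.poisson.sf(4, 1.0)
        assert out.pvalue.iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_bh_adjustment_is_monotone_and_bounded(self):
        counts = [0.0, 1.0, 2.0, 5.0, 9.0, 3.0]
        out = poisson_window_test(self._windows(counts, 300.0), 100_000)
        assert ((out.qvalue >= out.pvalue - 1e-12) & (out.qvalue <= 1.0)).all()

    def test_zero_genome_length_raises(self):
        with pytest.raises(ValueError):
            poisson_window_test(self._windows([1.0], 10.0), 0)


class TestClusterSummary:
    def test_all_placements_inside_one_cluster_gives_fraction_one(self):
        placements = [_placement(p) for p in (100, 500, 900)]
        clusters = pd.DataFrame({
            "cluster_id": ["c1"], "chrom": ["chr1"], "start": [0], "end": [2400],
            "n_windows": [2], "fractional_count": [3.0], "max_rpkm": [10.0],
            "plus_fraction": [1.0], "strand_call": ["plus"]})
        stats = cluster_summary(clusters, placements)
        assert stats["in_cluster_weight_fraction"] == pytest.approx(1.0)

    def test_total_length_arithmetic(self):
        clusters = pd.DataFrame({
            "cluster_id": ["c1", "c2"], "chrom": ["chr1", "chr1"],
            "start": [0, 8000], "end": [2400, 10_000],
            "n_windows": [2, 1], "fractional_count": [1.0, 1.0],
            "max_rpkm": [5.0, 5.0], "plus_fraction": [1.0, 1.0],
            "strand_call": ["plus", "plus"]})
        stats = cluster_summary(clusters, [_placement(100)], library_total=1.0)
        assert stats["total_length"] == 4400
        assert (stats["min_length"], stats["max_length"]) == (2000, 2400)
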