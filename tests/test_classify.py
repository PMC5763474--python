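"""TE-/gene-type categorization and strand-aware composition tables."""

import numpy as np
import pytest

from pirnakit import classify
from pirnakit._util import revcomp
from pirnakit.align import WeightedPlacement
from pirnakit.classify import annotation_coverage, categorize, category_totals, te_composition
from pirnakit.core import PutativePiRNA
from pirnakit.features import GeneFeature, RepeatFeature
from pirnakit.preprocess import UniqueTag


def _putative(seq, chrom, start, strand="+", count=1, weight=1.0):
    tag = UniqueTag(seq, {"s1": count})
    placement = WeightedPlacement(seq, chrom, start, start + len(seq), strand, weight)
    return PutativePiRNA(tag, [placement])


L1 = RepeatFeature("chr1", 1000, 2000, "-", "L1_Art#1", repeat_class="LINE", family="L1")
TIGGER = RepeatFeature("chr1", 5000, 5400, "+", "Tigger#1",
                       repeat_class="DNA", family="TcMar-Tigger")
GENE = GeneFeature("chr1", 10_000, 12_000, "+", "gene1", gene_id="gene1")


class TestCategorize:
    def test_plus_read_inside_minus_l1_is_te_antisense(self):
        df = categorize([_putative("A" * 30, "chr1", 1100, "+")], [L1], [GENE])
        assert df.category.iloc[0] == "te_antisense"
        assert df.matched_feature.iloc[0] == "L1_Art#1"

    def test_sense_gene_read(self):
        df = categorize([_putative("A" * 30, "chr1", 10_500, "+")], [L1], [GENE])
        assert df.category.iloc[0] == "gene_sense"

    def test_no_overlap_is_intergenic(self):
        df = categorize([_putative("A" * 30, "chr1", 50_000)], [L1], [GENE])
        assert df.category.iloc[0] == "intergenic"

    def test_te_takes_precedence_over_gene_by_default(self):
        overlapping_gene = GeneFeature("chr1", 900, 2100, "-", "g2", gene_id="g2")
        df = categorize([_putative("A" * 30, "chr1", 1100, "-")], [L1],
                        [overlapping_gene])
        assert df.category.iloc[0] == "te_sense"

    def test_best_placement_decides_for_multimappers(self):
        tag = UniqueTag("A" * 30, {"s1": 5})
        heavy = WeightedPlacement(tag.sequence, "chr1", 1100, 1130, "+", 0.9)
        light = WeightedPlacement(tag.sequence, "chr1", 10_500, 10_530, "+", 0.1)
        df = categorize([PutativePiRNA(tag, [light, heavy])], [L1], [GENE])
        assert df.category.iloc[0] == "te_antisense"

    def test_published_sense_antisense_counts_sum_to_type_totals(self):
        """76/113 gene and 590/374 TE sense/antisense add to 189 and 964."""
        putative = []
        plan = [("gene_sense", 76, GENE.start + 100, "+"),
                ("gene_antisense", 113, GENE.start + 100, "-"),
                ("te_sense", 590, TIGGER.start + 10, "+"),
                ("te_antisense", 374, TIGGER.start + 10, "-")]
        for label, n, pos, strand in plan:
            for i in range(n):
                seq = ("ACGT" * 9)[:24 + (i % 12)]
                putative.append(_putative(seq, "chr1", pos + (i % 50), strand))
        df = categorize(putative, [TIGGER], [GENE])
        totals = category_totals(df)
        assert totals.loc["gene", "sense"] == 76
        assert totals.loc["gene", "antisense"] == 113
        assert totals.loc["te", "sense"] == 590
        assert totals.loc["te", "antisense"] == 374
        assert totals.loc["gene", "total"] == 189
        assert totals.loc["te", "total"] == 964

    def test_crosstab_matches_brute_force_loop(self):
        rng = np.random.default_rng(12)
        putative = []
        for i in range(200):
            pos = int(rng.integers(0, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            putative.append(_putative(("ACGT" * 9)[:24 + (i % 12)], "chr1", pos,
                                      strand, count=int(rng.integers(1, 5))))
        df = categorize(putative, [L1, TIGGER], [GENE])
        brute = {"gene": 0, "te": 0, "intergenic": 0}
        for p in putative:
            pl = p.placements[0]
            ov_te = max(
                max(0, min(f.end, pl.end) - max(f.start, pl.start))
                for f in (L1, TIGGER))
            ov_gene = max(0, min(GENE.end, pl.end) - max(GENE.start, pl.start))
            if ov_te >= 0.5 * p.length:
                brute["te"] += 1
            elif ov_gene >= 0.5 * p.length:
                brute["gene"] += 1
            else:
                brute["intergenic"] += 1
        totals = category_totals(df)
        assert totals.loc["te", "total"] == brute["te"]
        assert totals.loc["gene", "total"] == brute["gene"]
        assert totals.loc["intergenic", "total"] == brute["intergenic"]
        weighted = category_totals(df, weighted=True)
        assert weighted["total"].sum() == sum(p.tag.total_count for p in putative)

    def test_categories_partition_the_putative_set(self):
        rng = np.random.default_rng(13)
        putative = [_putative(("ACGT" * 9)[:24 + (i % 12)], "chr1",
                              int(rng.integers(0, 30_000))) for i in range(150)]
        df = categorize(putative, [L1, TIGGER], [GENE])
        totals = category_totals(df)
        assert totals["total"].sum() == len(putative)

    def test_orientation_flip_swaps_sense_and_antisense(self):
        rng = np.random.default_rng(14)
        putative = [
            _putative(("ACGT" * 9)[:24 + (i % 12)], "chr1",
                      int(rng.integers(900, 2000)),
                      "+" if rng.random() < 0.5 else "-")
            for i in range(60)
        ]
        flipped_features = [RepeatFeature(L1.chrom, L1.start, L1.end,
                                          "+", L1.name, repeat_class="LINE",
                                          family="L1")]
        flipped_putative = []
        for p in putative:
            pl = p.placements[0]
            flip = "-" if pl.strand == "+" else "+"
            flipped_putative.append(
                PutativePiRNA(p.tag, [WeightedPlacement(
                    pl.tag, pl.chrom, pl.start, pl.end, flip, pl.weight)]))
        a = category_totals(categorize(putative, [L1], []))
        b = category_totals(categorize(flipped_putative, flipped_features, []))
        assert a.loc["te", "sense"] == b.loc["te", "sense"]
        assert a.loc["te", "antisense"] == b.loc["te", "antisense"]

    def test_raising_overlap_fraction_only_moves_tags_to_intergenic(self):
        rng = np.random.default_rng(15)
        putative = [_putative(("ACGT" * 9)[:24 + (i % 12)], "chr1",
                              int(rng.integers(900, 2100))) for i in range(80)]
        previous = None
        for frac in (0.2, 0.5, 0.8, 1.0):
            totals = category_totals(categorize(putative, [L1], [], frac))
            inter = totals.loc["intergenic", "total"]
            if previous is not None:
                assert inter >= previous
            previous = inter


class TestTeComposition:
    def test_all_antisense_to_one_copy(self):
        placements = [WeightedPlacement("A" * 30, "chr1", 1100 + i, 1130 + i, "+", 1.0)
                      for i in range(10)]  # L1 is minus strand -> antisense
        table = te_composition(placements, [L1], level="name")
        assert table.loc[0, "name"] == "L1_Art#1"
        assert table.loc[0, "antisense"] == pytest.approx(10.0)
        assert table.loc[0, "sense"] == 0.0

    def test_no_repeat_overlap_gives_empty_table_and_full_remainder(self):
        placements = [WeightedPlacement("A" * 30, "chr1", 50_000, 50_030, "+", 1.0)]
        table = te_composition(placements, [L1])
        assert len(table) == 0
        assert table.attrs["remainder_fraction"] == pytest.approx(1.0)

    def test_planted_antisense_tigger_dominates(self, small_dataset):
        """Repeat-derived reads planted ~90% antisense show up that way."""
        spec, genome, truth, reads, origin = small_dataset
        rep = origin[origin.origin == "repeat"]
        placements = [
            WeightedPlacement(r.insert_seq, r.chrom, r.start, r.end, r.strand, 1.0)
            for r in rep.itertuples(index=False)
        ]
        table = te_composition(placements, truth.repeat_copies, level="class")
        table = table.set_index("class")
        anti_share = table["antisense"].sum() / table["total"].sum()
        sd = np.sqrt(0.9 * 0.1 / len(rep))
        assert abs(anti_share - spec.repeat_antisense_fraction) <= 4 * sd

    def test_unknown_level_raises(self):
        with pytest.raises(ValueError):
            te_composition([], [L1], level="order")


class TestAnnotationCoverage:
    def test_merged_interval_arithmetic(self):
        repeats = [
            RepeatFeature("chr1", 0, 100, "+", "a", repeat_class="LINE", family="L1"),
            RepeatFeature("chr1", 50, 150, "+", "b", repeat_class="LINE", family="L1"),
            RepeatFeature("chr1", 300, 350, "+", "c", repeat_class="SINE", family="MIR"),
        ]
        table = annotation_coverage(repeats, {"chr1": 1000}).set_index("class")
        assert table.loc["LINE", "bp"] == 150  # [0,150) merged
        assert table.loc["SINE", "fraction_of_genome"] == pytest.approx(0.05)
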