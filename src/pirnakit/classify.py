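"""Strand-aware TE-type / gene-type categorization of putative piRNAs.

Each tag is judged at its best placement (highest weight; ties broken by the
leftmost genomic coordinate) so the categories partition the tag set even for
multimappers: overlap of at least ``min_overlap_fraction`` of the tag with a
repeat makes it TE-type, otherwise with a gene makes it gene-type, otherwise
it is intergenic. Repeats take precedence over genes by default, matching the
convention that repeat-derived piRNAs are the dominant population. Sense means
the placement strand equals the feature strand; antisense TE piRNAs are the
silencing-competent orientation.

The weight-based composition table (:func:`te_composition`) instead uses every
placement, splitting each repeat group's weight into sense and antisense
shares the way TE-composition bar charts are drawn.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .align import WeightedPlacement
from .core import PutativePiRNA
from .features import (
    FeatureIndex,
    GeneFeature,
    GenomicFeature,
    RepeatFeature,
    check_chroms,
    overlap_length,
)

CATEGORIES = ("gene_sense", "gene_antisense", "te_sense", "te_antisense", "intergenic")


def best_placement(placements: Sequence[WeightedPlacement]) -> WeightedPlacement:
    """Highest-weight placement; ties resolve to the leftmost coordinate."""
    return min(placements, key=lambda p: (-p.weight, p.chrom, p.start, p.strand))


def _best_feature(index: FeatureIndex, placement: WeightedPlacement,
                  needed: float) -> Optional[GenomicFeature]:
    best, best_ov = None, 0
    for feat in index.overlapping(placement.chrom, placement.start, placement.end):
        ov = overlap_length(feat, placement.start, placement.end)
        if ov >= needed and ov > best_ov:
            best, best_ov = feat, ov
    return best


def categorize(
    putative: Sequence[PutativePiRNA],
    repeats: Iterable[RepeatFeature],
    genes: Iterable[GeneFeature],
    min_overlap_fraction: float = 0.5,
    genome_chroms: Optional[Iterable[str]] = None,
    precedence: Tuple[str, str] = ("te", "gene"),
) -> pd.DataFrame:
    """Assign exactly one category per tag; returns one row per putative tag.

    Columns: sequence, length, category, matched_feature, count (redundant
    reads), weight (total placement weight). Use :func:`category_totals` for
    the type x orientation cross-tab.
    """
    repeats, genes = list(repeats), list(genes)
    if genome_chroms is not None:
        check_chroms(list(repeats) + list(genes), genome_chroms)
    indexes = {"te": FeatureIndex(repeats), "gene": FeatureIndex(genes)}
    rows = []
    for p in putative:
        placement = best_placement(p.placements)
        needed = min_overlap_fraction * p.length
        category, matched = "intergenic", None
        for kind in precedence:
            feat = _best_feature(indexes[kind], placement, needed)
            if feat is not None:
                orientation = "sense" if placement.strand == feat.strand else "antisense"
                category, matched = f"{kind}_{orientation}", feat.name
                break
        rows.append(
            (p.tag.sequence, p.length, category, matched, p.tag.total_count,
             sum(pl.weight for pl in p.placements))
        )
    return pd.DataFrame(
        rows, columns=["sequence", "length", "category", "matched_feature",
                       "count", "weight"],
    )


def category_totals(categories: pd.DataFrame, weighted: bool = False) -> pd.DataFrame:
    """Type x orientation cross-tab with row/column margins.

    ``weighted=False`` counts unique tags; ``weighted=True`` sums redundant
    read counts (both views are reported because either convention appears in
    published piRNA catalogs).
    """
    rows = ["gene", "te", "intergenic"]
    table = pd.DataFrame(0.0, index=rows, columns=["sense", "antisense", "total"])
    for row in categories.itertuples(index=False):
        value = row.count if weighted else 1
        if row.category == "intergenic":
            table.loc["intergenic", "total"] += value
        else:
            kind, orientation = row.category.split("_")
            table.loc[kind, orientation] += value
            table.loc[kind, "total"] += value
    if not weighted:
        table = table.astype(int)
    return table


# ---------------------------------------------------------------------------
# TE composition

_LEVELS = {"class": "repeat_class", "family": "family", "name": "name"}


def te_composition(
    placements: Sequence[WeightedPlacement],
    repeats: Iterable[RepeatFeature],
    level: str = "class",
    min_overlap_fraction: float = 0.5,
    library_total: Optional[float] = None,
) -> pd.DataFrame:
    """Weight per repeat group split by orientation, sorted by total weight.

    Each placement contributes its weight to the group of the repeat it
    overlaps best (>= min_overlap_fraction of the placement); placements
    overlapping no repeat accumulate into the intergenic remainder, reported
    in the frame's ``attrs["remainder_fraction"]``. Fractions are of
    ``library_total`` (default: total placement weight), so they sum to at
    most 1.
    """
    if level not in _LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {sorted(_LEVELS)}")
    attr = _LEVELS[level]
    index = FeatureIndex(list(repeats))
    if library_total is None:
        library_total = sum(p.weight for p in placements)
    groups: Dict[str, Dict[str, float]] = {}
    assigned = 0.0
    for p in placements:
        needed = min_overlap_fraction * (p.end - p.start)
        feat = _best_feature(index, p, needed)
        if feat is None:
            continue
        orientation = "sense" if p.strand == feat.strand else "antisense"
        group = groups.setdefault(getattr(feat, attr), {"sense": 0.0, "antisense": 0.0})
        group[orientation] += p.weight
        assigned += p.weight
    table = pd.DataFrame(
        [
            (name, g["sense"], g["antisense"], g["sense"] + g["antisense"])
            for name, g in groups.items()
        ],
        columns=[level, "sense", "antisense", "total"],
    ).sort_values("total", ascending=False, ignore_index=True)
    if library_total > 0:
        table["fraction_of_library"] = table["total"] / library_total
        table.attrs["remainder_fraction"] = 1.0 - assigned / library_total
    else:
        table["fraction_of_library"] = 0.0
        table.attrs["remainder_fraction"] = 1.0
    return table


def annotation_coverage(
    repeats: Iterable[RepeatFeature],
    genome_lengths: Mapping[str, int],
    level: str = "class",
) -> pd.DataFrame:
    """Genome bp covered per repeat group (intervals merged within a group).

    This recomputes the genome-composition percentages (e.g. the LINE share of
    the assembly) from the repeat annotation actually supplied, rather than
    asserting any particular genome's values.
    """
    if level not in _LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {sorted(_LEVELS)}")
    attr = _LEVELS[level]
    genome_total = sum(genome_lengths.values())
    by_group: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    for feat in repeats:
        by_group.setdefault(getattr(feat, attr), {}).setdefault(feat.chrom, []).append(
            (feat.start, feat.end)
        )
    rows = []
    for name, per_chrom in by_group.items():
        covered = 0
        for intervals in per_chrom.values():
            intervals.sort()
            cur_start, cur_end = intervals[0]
            for start, end in intervals[1:]:
                if start > cur_end:
                    covered += cur_end - cur_start
                    cur_start, cur_end = start, end
                else:
                    cur_end = max(cur_end, end)
            covered += cur_end - cur_start
        rows.append((name, covered, covered / genome_total if genome_total else 0.0))
    return pd.DataFrame(
        rows, columns=[level, "bp", "fraction_of_genome"]
    ).sort_values("bp", ascending=False, ignore_index=True)
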