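"""Strand-aware genomic annotation intervals and an interval index over them.

All coordinates are 0-based half-open, strands are "+"/"-". These records back
both the known-small-RNA subtraction (rRNA/tRNA/snRNA/snoRNA/miRNA loci) and
the sense/antisense TE- and gene-type classification of putative piRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

from intervaltree import IntervalTree

#: closed vocabulary of known structural/small RNA classes, in subtraction
#: priority order (a tag overlapping several classes takes the first)
NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "other")

#: RepeatMasker top-level repeat classes
REPEAT_CLASSES = (
    "LINE",
    "SINE",
    "LTR",
    "DNA",
    "Satellite",
    "Simple_repeat",
    "Low_complexity",
    "Small_RNA",
    "Unknown",
)


@dataclass(frozen=True)
class GenomicFeature:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    name: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"feature {self.name}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.name}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NcRNAFeature(GenomicFeature):
    rna_class: str = "other"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.rna_class not in NCRNA_CLASSES:
            raise ValueError(
                f"feature {self.name}: rna_class {self.rna_class!r} not in {NCRNA_CLASSES}"
            )


@dataclass(frozen=True)
class RepeatFeature(GenomicFeature):
    repeat_class: str = "Unknown"
    family: str = "Unknown"


@dataclass(frozen=True)
class GeneFeature(GenomicFeature):
    gene_id: str = ""
    biotype: str = "protein_coding"


class FeatureIndex:
    """Chromosome-keyed interval tree over a feature set for overlap queries."""

    def __init__(self, features: Iterable[GenomicFeature]):
        self.features: List[GenomicFeature] = list(features)
        self._trees: Dict[str, IntervalTree] = {}
        for feat in self.features:
            self._trees.setdefault(feat.chrom, IntervalTree()).addi(
                feat.start, feat.end, feat
            )

    def overlapping(self, chrom: str, start: int, end: int) -> List[GenomicFeature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def chroms(self) -> Sequence[str]:
        return sorted(self._trees)

    def __len__(self) -> int:
        return len(self.features)


def check_chroms(features: Iterable[GenomicFeature], genome_chroms: Iterable[str]) -> None:
    """Raise if any feature sits on a chromosome absent from the genome.

    The error lists the offending features so a mismatched annotation build is
    diagnosable from the message alone.
    """
    known = set(genome_chroms)
    bad = [f for f in features if f.chrom not in known]
    if bad:
        names = ", ".join(f"{f.name}@{f.chrom}" for f in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(f"annotation chromosomes absent from genome: {names}{more}")


def overlap_length(feat: GenomicFeature, start: int, end: int) -> int:
    """Length of the intersection of [start, end) with the feature interval."""
    return max(0, min(feat.end, end) - max(feat.start, start))
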