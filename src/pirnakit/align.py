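"""Genomic placements for tags and fractional multimapper weights.

Two routes produce :class:`AlignmentRecord` sets: a built-in exact-match
mapper (seed-and-verify over a k-mer index of the genome, both strands) for
self-contained runs, and ingestion of external SAM/BAM/BED alignments from a
conventional short-read aligner. Either way, a tag reported at n positions
gets weight count/n (count-weighted mode) or 1/n (unique-tag mode) at each —
so a read mapping to 10 positions contributes 0.1 reads at each position and
per-tag totals are conserved exactly.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from ._util import revcomp
from .preprocess import UniqueTag


@dataclass(frozen=True)
class AlignmentRecord:
    tag: str          # the tag sequence, as read off the genome's + strand for "+"
    chrom: str
    start: int        # 0-based
    end: int          # half-open; end - start == len(tag)
    strand: str
    mismatches: int = 0
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.tag):
            raise ValueError(
                f"alignment span {self.end - self.start} != tag length {len(self.tag)}"
            )
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")


@dataclass(frozen=True)
class WeightedPlacement:
    tag: str
    chrom: str
    start: int
    end: int
    strand: str
    weight: float

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


# ---------------------------------------------------------------------------
# built-in exact-match mapper


class GenomeIndex:
    """k-mer seed index over the + strand of a genome for exact matching."""

    def __init__(self, genome: Mapping[str, str], k: int = 12):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("genome is empty")
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.k = k
        self._seeds: Dict[str, List[tuple]] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._seeds[seq[i:i + k]].append((chrom, i))

    def occurrences(self, query: str) -> List[tuple]:
        """All (chrom, start) exact occurrences of ``query`` on the + strand."""
        if len(query) < self.k:
            # fall back to a direct scan for queries shorter than the seed
            hits = []
            for chrom, seq in self.genome.items():
                pos = seq.find(query)
                while pos != -1:
                    hits.append((chrom, pos))
                    pos = seq.find(query, pos + 1)
            return hits
        hits = []
        for chrom, i in self._seeds.get(query[: self.k], ()):
            if self.genome[chrom][i: i + len(query)] == query:
                hits.append((chrom, i))
        return hits


def exact_match_map(
    tags: Iterable[Union[UniqueTag, str]],
    genome: Union[Mapping[str, str], GenomeIndex],
    max_hits_cap: Optional[int] = None,
    k: int = 12,
) -> Dict[str, List[AlignmentRecord]]:
    """Map tags to all exact genomic occurrences on both strands.

    Returns {tag_sequence: [AlignmentRecord, ...]}; tags with no occurrence
    map to an empty list (unmapped), as do tags whose hit count exceeds
    ``max_hits_cap`` (default: no cap).
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, k=k)
    results: Dict[str, List[AlignmentRecord]] = {}
    for tag in tags:
        seq = tag.sequence if isinstance(tag, UniqueTag) else tag
        if seq in results:
            continue
        fwd = index.occurrences(seq)
        rev = index.occurrences(revcomp(seq))
        hits = [(chrom, pos, "+") for chrom, pos in fwd]
        hits += [(chrom, pos, "-") for chrom, pos in rev]
        if max_hits_cap is not None and len(hits) > max_hits_cap:
            results[seq] = []
            continue
        n = len(hits)
        results[seq] = [
            AlignmentRecord(seq, chrom, pos, pos + len(seq), strand, 0, n)
            for chrom, pos, strand in sorted(hits)
        ]
    return results


# ---------------------------------------------------------------------------
# external alignment ingestion


def load_alignments(
    path,
    tags: Optional[Mapping[str, str]] = None,
    max_mismatches: int = 1,
) -> Dict[str, List[AlignmentRecord]]:
    """Load SAM/BAM or BED6 alignments, recomputing n_hits per query.

    ``tags`` optionally maps query names to tag sequences (for BED files whose
    name column is an identifier, or SAM records lacking SEQ); query names that
    are themselves sequences need no mapping. Queries that cannot be resolved
    to a known tag are skipped with a warning. n_hits is always recounted from
    the records that survive the mismatch filter, never trusted from file tags.
    """
    path = str(path)
    if path.endswith((".sam", ".bam")):
        raw = _load_sam(path, tags)
    elif path.endswith((".bed", ".bed.gz")):
        raw = _load_bed(path, tags)
    else:
        raise ValueError(f"unrecognized alignment format: {path}")
    results: Dict[str, List[AlignmentRecord]] = defaultdict(list)
    for seq, chrom, start, end, strand, nm in raw:
        if nm > max_mismatches:
            continue
        results[seq].append((chrom, start, end, strand, nm))
    out: Dict[str, List[AlignmentRecord]] = {}
    for seq, hits in results.items():
        n = len(hits)
        out[seq] = [
            AlignmentRecord(seq, chrom, start, end, strand, nm, n)
            for chrom, start, end, strand, nm in sorted(hits)
        ]
    return out


def _load_sam(path: str, tags: Optional[Mapping[str, str]]):
    mode = "rb" if path.endswith(".bam") else "r"
    rows = []
    skipped = 0
    valid_seqs = set(tags.values()) if tags is not None else None
    # first pass: primary sequences per query name (secondary records carry '*')
    primary_seq: Dict[str, str] = {}
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        records = list(fh)
    for rec in records:
        if rec.is_unmapped or rec.query_sequence is None:
            continue
        # SEQ is reported on the reference + strand; recover the tag as read
        seq = revcomp(rec.query_sequence) if rec.is_reverse else rec.query_sequence
        primary_seq.setdefault(rec.query_name, seq)
    for rec in records:
        if rec.is_unmapped:
            continue
        qname = rec.query_name
        if rec.query_sequence is not None:
            seq = revcomp(rec.query_sequence) if rec.is_reverse else rec.query_sequence
        elif qname in primary_seq:
            seq = primary_seq[qname]
        elif tags and qname in tags:
            seq = tags[qname]
        else:
            skipped += 1
            continue
        if valid_seqs is not None and seq not in valid_seqs and qname not in tags:
            skipped += 1
            continue
        nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
        strand = "-" if rec.is_reverse else "+"
        rows.append((seq, rec.reference_name, rec.reference_start, rec.reference_end,
                     strand, int(nm)))
    if skipped:
        warnings.warn(f"skipped {skipped} alignment records with unresolvable queries")
    return rows


def _load_bed(path: str, tags: Optional[Mapping[str, str]]):
    rows = []
    skipped = 0
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            start, end = int(start), int(end)
            if tags is not None and name in tags:
                seq = tags[name]
            elif set(name) <= set("ACGTN"):
                seq = name
            else:
                skipped += 1
                continue
            rows.append((seq, chrom, start, end, strand, 0))
    if skipped:
        warnings.warn(f"skipped {skipped} BED records with unresolvable names")
    return rows


# ---------------------------------------------------------------------------
# fractional weighting


def assign_weights(
    alignments: Mapping[str, Sequence[AlignmentRecord]],
    tag_counts: Optional[Mapping[str, int]] = None,
    mode: str = "count-weighted",
) -> List[WeightedPlacement]:
    """Fractional multimapper weighting: weight = count/n_hits or 1/n_hits.

    A tag placed at 10 positions therefore receives 0.1 (unique-tag mode) at
    each position, and per-tag weight sums equal the tag count (resp. 1).
    """
    if mode not in ("count-weighted", "unique-tag"):
        raise ValueError(f"unknown weighting mode {mode!r}")
    placements: List[WeightedPlacement] = []
    for seq, hits in alignments.items():
        if not hits:
            raise ValueError(
                f"tag {seq[:20]!r} has no placements; unmapped tags must be "
                "excluded before weighting"
            )
        n = len(hits)
        numerator = 1.0
        if mode == "count-weighted":
            if tag_counts is None:
                raise ValueError("count-weighted mode requires tag_counts")
            numerator = float(tag_counts[seq])
        w = numerator / n
        placements.extend(
            WeightedPlacement(seq, h.chrom, h.start, h.end, h.strand, w) for h in hits
        )
    return placements


def placements_frame(placements: Iterable[WeightedPlacement]) -> pd.DataFrame:
    """Tabulate placements with a strand-aware ``five_prime`` column."""
    rows = [
        (p.tag, p.chrom, p.start, p.end, p.strand, p.weight, p.five_prime)
        for p in placements
    ]
    return pd.DataFrame(
        rows, columns=["tag", "chrom", "start", "end", "strand", "weight", "five_prime"]
    )


def write_placements_bed(placements: Iterable[WeightedPlacement], path) -> None:
    """BED6+1: name = tag sequence, score 0, extra column = weight."""
    with open(path, "w") as handle:
        for p in sorted(placements, key=lambda p: (p.chrom, p.start, p.strand, p.tag)):
            handle.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.tag}\t0\t{p.strand}\t{p.weight:.6g}\n"
            )


def write_alignments_bed(alignments: Mapping[str, Sequence[AlignmentRecord]], path) -> None:
    """BED6 with the tag sequence in the name column (round-trippable)."""
    with open(path, "w") as handle:
        for seq in sorted(alignments):
            for rec in alignments[seq]:
                handle.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.tag}\t0\t{rec.strand}\n"
                )
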