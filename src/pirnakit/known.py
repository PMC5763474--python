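"""Subtraction of known non-piRNA small RNAs (rRNA, tRNA, snRNA, snoRNA, miRNA).

Instead of a database homology search, a tag is attributed to a known RNA when
any of its genomic placements overlaps an annotated ncRNA locus over at least
``min_overlap_fraction`` of the tag's length, on either strand (structural RNA
fragments arise from both). Optionally, an exact substring match against a
reference ncRNA FASTA catches tags from loci missing in the annotation. Ties
across classes resolve by the fixed priority rRNA > tRNA > snRNA > snoRNA >
miRNA > other.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._util import revcomp
from .align import AlignmentRecord
from .features import FeatureIndex, NcRNAFeature, NCRNA_CLASSES, check_chroms, overlap_length
from .preprocess import UniqueTag

UNANNOTATED = "unannotated"

_PRIORITY = {cls: i for i, cls in enumerate(NCRNA_CLASSES)}


def classify_known(
    tags: Sequence[UniqueTag],
    alignments: Mapping[str, Sequence[AlignmentRecord]],
    ncrna: Iterable[NcRNAFeature],
    genome_chroms: Optional[Iterable[str]] = None,
    min_overlap_fraction: float = 0.8,
    ncrna_seqs: Optional[Mapping[str, str]] = None,
    ncrna_seq_classes: Optional[Mapping[str, str]] = None,
) -> Dict[str, str]:
    """Map each tag sequence to an ncRNA class or ``"unannotated"``.

    ``ncrna_seqs`` is an optional {name: sequence} reference; a tag matching a
    reference sequence (or its reverse complement) as an exact substring is
    classed via ``ncrna_seq_classes`` (name -> class, default "other").
    """
    ncrna = list(ncrna)
    if genome_chroms is not None:
        check_chroms(ncrna, genome_chroms)
    index = FeatureIndex(ncrna)
    result: Dict[str, str] = {}
    for tag in tags:
        seq = tag.sequence
        hit_classes = set()
        for rec in alignments.get(seq, ()):  # unmapped tags have no placements
            needed = min_overlap_fraction * len(seq)
            for feat in index.overlapping(rec.chrom, rec.start, rec.end):
                if overlap_length(feat, rec.start, rec.end) >= needed:
                    hit_classes.add(feat.rna_class)
        if not hit_classes and ncrna_seqs:
            rc = revcomp(seq)
            for name, ref in ncrna_seqs.items():
                if seq in ref or rc in ref:
                    cls = (ncrna_seq_classes or {}).get(name, "other")
                    hit_classes.add(cls)
                    break
        if hit_classes:
            result[seq] = min(hit_classes, key=lambda c: _PRIORITY.get(c, len(_PRIORITY)))
        else:
            result[seq] = UNANNOTATED
    return result


def remove_known(
    tags: Sequence[UniqueTag],
    classification: Mapping[str, str],
) -> Tuple[List[UniqueTag], pd.DataFrame]:
    """Partition tags into kept (unannotated) and removed-by-class.

    Returns (kept_tags, composition) where composition has one row per class
    plus "unannotated", and per-sample ``total``/``unique`` column pairs with a
    grand "Total" pair — mirroring the per-stage accounting table layout.
    Kept + removed equals the input exactly, in totals and uniques.
    """
    samples = sorted({s for t in tags for s in t.counts})
    kept: List[UniqueTag] = []
    rows: Dict[str, Dict[str, int]] = {}
    for tag in tags:
        cls = classification.get(tag.sequence, UNANNOTATED)
        if cls == UNANNOTATED:
            kept.append(tag)
        row = rows.setdefault(cls, {})
        for smp, n in tag.counts.items():
            row[(smp, "total")] = row.get((smp, "total"), 0) + n
            row[(smp, "unique")] = row.get((smp, "unique"), 0) + 1
        row[("Total", "total")] = row.get(("Total", "total"), 0) + tag.total_count
        row[("Total", "unique")] = row.get(("Total", "unique"), 0) + 1
    order = [c for c in NCRNA_CLASSES if c in rows] + (
        [UNANNOTATED] if UNANNOTATED in rows else []
    )
    columns = pd.MultiIndex.from_tuples(
        [(s, k) for s in samples + ["Total"] for k in ("total", "unique")]
    )
    table = pd.DataFrame(
        [[rows[c].get(col, 0) for col in columns] for c in order],
        index=order,
        columns=columns,
        dtype=int,
    )
    return kept, table
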