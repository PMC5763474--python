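"""Readers/writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython, SAM/BAM through pysam. BED6 (+extra
columns) and the RepeatMasker ``.out`` dialect are simple enough that they are
parsed directly; all coordinates are converted to 0-based half-open on the way
in and back to each format's native convention on the way out.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import GeneFeature, GenomicFeature, NcRNAFeature, RepeatFeature

# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> Dict[str, str]:
    """Read a (possibly gzipped) FASTA into an ordered {name: sequence} dict."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(seqs: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fastq(path) -> Iterator[Tuple[str, str, str]]:
    """Yield (read_id, sequence, quality_string) from FASTQ (gz-transparent)."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq).upper(), quals


def write_fastq(records: Iterable[Tuple[str, str, str]], path) -> None:
    """Write (read_id, sequence, quality_string) triples as FASTQ."""
    with _open_text(path, "wt") as handle:
        for read_id, seq, qual in records:
            handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BED

_FEATURE_KINDS = {"ncrna": NcRNAFeature, "repeat": RepeatFeature, "gene": GeneFeature}


def read_bed_features(path, kind: str = "gene") -> List[GenomicFeature]:
    """Read BED6(+extras) into features.

    kind="ncrna" expects the RNA class in column 7; kind="repeat" expects
    class and family in columns 7-8; kind="gene" takes biotype from column 7
    when present.
    """
    if kind not in _FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}")
    feats: List[GenomicFeature] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"BED6 line with {len(cols)} columns: {line!r}")
            chrom, start, end, name, _score, strand = cols[:6]
            start, end = int(start), int(end)
            if kind == "ncrna":
                if len(cols) < 7:
                    raise ValueError(f"ncRNA BED needs the class in column 7: {line!r}")
                feats.append(NcRNAFeature(chrom, start, end, strand, name, rna_class=cols[6]))
            elif kind == "repeat":
                if len(cols) < 8:
                    raise ValueError(f"repeat BED needs class/family in columns 7-8: {line!r}")
                feats.append(
                    RepeatFeature(chrom, start, end, strand, name,
                                  repeat_class=cols[6], family=cols[7])
                )
            else:
                biotype = cols[6] if len(cols) > 6 else "protein_coding"
                feats.append(
                    GeneFeature(chrom, start, end, strand, name, gene_id=name, biotype=biotype)
                )
    return feats


def write_bed_features(features: Iterable[GenomicFeature], path) -> None:
    """Write features as BED6 plus kind-specific extra columns."""
    with open(path, "w") as handle:
        for f in features:
            cols = [f.chrom, str(f.start), str(f.end), f.name, "0", f.strand]
            if isinstance(f, NcRNAFeature):
                cols.append(f.rna_class)
            elif isinstance(f, RepeatFeature):
                cols.extend([f.repeat_class, f.family])
            elif isinstance(f, GeneFeature):
                cols.append(f.biotype)
            handle.write("\t".join(cols) + "\n")


def read_gff3_features(path, kind: str = "gene") -> List[GenomicFeature]:
    """Minimal GFF3 reader: 1-based inclusive -> 0-based half-open.

    For kind="ncrna" the RNA class is taken from the ``biotype=`` attribute if
    present, otherwise from the ``type`` column. Names come from ``ID=`` or
    ``Name=``.
    """
    feats: List[GenomicFeature] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"GFF3 line with {len(cols)} columns: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols[:9]
            attr = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attr[k.strip()] = v.strip()
            name = attr.get("ID") or attr.get("Name") or ftype
            start0, end0 = int(start) - 1, int(end)
            if kind == "ncrna":
                feats.append(
                    NcRNAFeature(chrom, start0, end0, strand, name,
                                 rna_class=attr.get("biotype", ftype))
                )
            else:
                feats.append(
                    GeneFeature(chrom, start0, end0, strand, name,
                                gene_id=attr.get("gene_id", name),
                                biotype=attr.get("biotype", ftype))
                )
    return feats


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path) -> List[RepeatFeature]:
    """Parse RepeatMasker .out (1-based inclusive, strand '+'/'C')."""
    feats: List[RepeatFeature] = []
    with _open_text(path) as handle:
        for line in handle:
            parts = line.split()
            if len(parts) < 14 or not parts[0].replace(".", "").isdigit():
                continue  # header / blank lines
            chrom = parts[4]
            start = int(parts[5]) - 1
            end = int(parts[6])
            strand = "-" if parts[8] == "C" else "+"
            name = parts[9]
            cls_fam = parts[10]
            repeat_class, _, family = cls_fam.partition("/")
            feats.append(
                RepeatFeature(chrom, start, end, strand, name,
                              repeat_class=repeat_class, family=family or repeat_class)
            )
    return feats


def write_repeatmasker_out(features: Iterable[RepeatFeature], path) -> None:
    with open(path, "w") as handle:
        handle.write(_RM_HEADER)
        for i, f in enumerate(features, start=1):
            strand = "C" if f.strand == "-" else "+"
            cls_fam = f.repeat_class if f.family == f.repeat_class else f"{f.repeat_class}/{f.family}"
            handle.write(
                f"{1000:5d} {0.0:5.1f} {0.0:4.1f} {0.0:4.1f}  {f.chrom:<10s} "
                f"{f.start + 1:7d} {f.end:7d} (0)  {strand}  {f.name:<15s} "
                f"{cls_fam:<20s} {1:6d} {f.length:5d} (0) {i:5d}\n"
            )
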