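"""Ground-truthed toy data: genome with planted repeats/clusters, and reads.

The generator inverts the statistical signatures the pipeline is meant to
detect, so every downstream stage has a fixture with known answers:

* a random genome partitioned into chromosomes, with repeat families planted
  as near-identical copies (identical at mutation rate 0, so reads drawn from
  them are genuine multimappers), piRNA cluster intervals, a small ncRNA
  annotation (one rRNA/tRNA/snoRNA/miRNA locus) and a few gene intervals, all
  pairwise non-overlapping;
* reads with a bimodal length distribution (miRNA-sized ~22 nt and
  piRNA-sized ~29 nt components), a 5' uridine bias of ``u1_probability`` on
  piRNA-like reads, a 3' sequencing adapter on every read, and an origin label
  (cluster / repeat / background / ncRNA) per read.

The 5' bias is planted by rejection-sampling the start position so the
genomic base under the read's 5' end is T exactly with probability
``u1_probability`` — reads stay exact genomic substrings and the expected
5'-T fraction equals the parameter itself.

Everything is driven by one integer seed; identical spec + seed reproduce
byte-identical FASTA/FASTQ/BED outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from ._util import revcomp
from .features import GeneFeature, GenomicFeature, NcRNAFeature, RepeatFeature
from . import io as _io

BASES = np.array(list("ACGT"))

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class RepeatPlan:
    """One repeat family to plant: k copies of a shared master sequence."""

    repeat_class: str
    family: str
    name: str
    copy_number: int
    length: int
    strand_mode: str = "random"  # plus | minus | random
    mutation_rate: float = 0.0


@dataclass
class LengthMixture:
    """Two-component discrete read-length mixture (rounded truncated normals).

    Means 22 (miRNA-sized) and 29 (piRNA-sized) with sd 1.5 reproduce the
    bimodal shape with peaks at 22 nt and >28 nt; ``weight_long`` is the
    probability of the piRNA-sized component for reads not tied to a planted
    origin.
    """

    mean_short: float = 22.0
    mean_long: float = 29.0
    sd: float = 1.5
    weight_long: float = 0.6

    def draw(self, rng: np.random.Generator, component: str, size: int,
             lo: int = 18, hi: int = 44) -> np.ndarray:
        if component == "mixed":
            longs = rng.random(size) < self.weight_long
            means = np.where(longs, self.mean_long, self.mean_short)
        elif component == "short":
            means = np.full(size, self.mean_short)
        elif component == "long":
            means = np.full(size, self.mean_long)
        else:
            raise ValueError(f"unknown component {component!r}")
        lengths = np.rint(rng.normal(means, self.sd)).astype(int)
        return np.clip(lengths, lo, hi)


def _default_repeat_plan() -> List[RepeatPlan]:
    return [
        RepeatPlan("LINE", "L1", "L1_Art", 10, 600, "random", 0.0),
        RepeatPlan("SINE", "MIR", "MIR", 8, 200, "random", 0.0),
        RepeatPlan("DNA", "TcMar-Tigger", "Tigger", 6, 300, "plus", 0.0),
    ]


@dataclass
class SyntheticSpec:
    """Study-condition parameters for the toy genome and read set."""

    genome_length: int = 600_000
    n_chromosomes: int = 2
    repeat_plan: List[RepeatPlan] = field(default_factory=_default_repeat_plan)
    n_clusters: int = 20
    cluster_length_range: Tuple[int, int] = (5000, 9000)
    cluster_min_gap: int = 5000  # keeps 2 kb-window cluster calls unambiguous
    cluster_strand_mode: str = "random"  # plus | minus | dual | random
    reads_per_cluster: int = 300
    reads_per_repeat_copy: int = 20
    repeat_antisense_fraction: float = 0.9
    background_reads: int = 1000
    ncrna_contaminant_fraction: float = 0.05
    u1_probability: float = 0.75
    length_mixture: LengthMixture = field(default_factory=LengthMixture)
    adapter_sequence: str = DEFAULT_ADAPTER
    read_length: int = 50
    quality_phred: int = 30
    n_genes: int = 4
    gene_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ncrna_contaminant_fraction", "u1_probability",
                     "repeat_antisense_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.cluster_length_range
        if self.n_clusters > 0:
            if lo < 2000 or hi * self.n_clusters > self.genome_length:
                raise ValueError(
                    "cluster_length_range must lie within "
                    f"[2000, genome_length/n_clusters]; got {self.cluster_length_range}"
                )
        if lo > hi:
            raise ValueError("cluster_length_range must be (low, high)")
        if self.cluster_strand_mode not in ("plus", "minus", "dual", "random"):
            raise ValueError(f"bad cluster_strand_mode {self.cluster_strand_mode!r}")


@dataclass
class GroundTruth:
    """What was planted where; the per-read origin table is built separately."""

    chrom_lengths: Dict[str, int]
    planted_clusters: List[GenomicFeature] = field(default_factory=list)
    repeat_copies: List[RepeatFeature] = field(default_factory=list)
    ncrna: List[NcRNAFeature] = field(default_factory=list)
    genes: List[GeneFeature] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome simulation


class _Packer:
    """Places non-overlapping intervals on chromosomes by rejection sampling."""

    def __init__(self, chrom_lengths: Dict[str, int], rng: np.random.Generator):
        self.chrom_lengths = chrom_lengths
        self.rng = rng
        self.occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_lengths}

    def place(self, length: int, label: str, max_tries: int = 2000,
              margin: int = 0) -> Tuple[str, int]:
        chroms = [c for c, L in self.chrom_lengths.items() if L >= length]
        if not chroms:
            raise ValueError(f"{label}: no chromosome can hold length {length}")
        for _ in range(max_tries):
            chrom = chroms[self.rng.integers(len(chroms))]
            start = int(self.rng.integers(0, self.chrom_lengths[chrom] - length + 1))
            end = start + length
            if all(end + margin <= s or start - margin >= e
                   for s, e in self.occupied[chrom]):
                self.occupied[chrom].append((start, end))
                return chrom, start
        raise ValueError(f"{label}: could not place a {length} bp interval "
                         "(genome too crowded)")


def simulate_genome(spec: SyntheticSpec) -> Tuple[Dict[str, str], GroundTruth]:
    """Random genome with planted repeats, clusters, ncRNA loci and genes.

    Raises if the total planted length exceeds the genome length (infeasible
    packing). Same spec + seed => identical genome and truth.
    """
    rng = np.random.default_rng(spec.seed)
    ncrna_plan = [("rRNA", 1500), ("tRNA", 75), ("snoRNA", 120), ("miRNA", 80)]
    planted = (
        sum(p.copy_number * p.length for p in spec.repeat_plan)
        + spec.n_clusters * spec.cluster_length_range[1]
        + sum(length for _, length in ncrna_plan)
        + spec.n_genes * spec.gene_length
    )
    if planted > spec.genome_length:
        raise ValueError(
            f"infeasible packing: planted length {planted} exceeds genome "
            f"length {spec.genome_length}"
        )
    per_chrom = spec.genome_length // spec.n_chromosomes
    chrom_lengths = {f"chr{i + 1}": per_chrom for i in range(spec.n_chromosomes)}
    genome = {
        chrom: rng.choice(BASES, size=length)
        for chrom, length in chrom_lengths.items()
    }
    truth = GroundTruth(chrom_lengths=chrom_lengths)
    packer = _Packer(chrom_lengths, rng)

    # clusters are the largest planted intervals; placing them first keeps
    # rejection-sampling feasible at higher occupancy
    for i in range(spec.n_clusters):
        lo, hi = spec.cluster_length_range
        length = int(rng.integers(lo, hi + 1))
        chrom, start = packer.place(length, f"cluster {i + 1}",
                                    margin=spec.cluster_min_gap)
        if spec.cluster_strand_mode == "random":
            strand = "+" if rng.random() < 0.5 else "-"
        elif spec.cluster_strand_mode == "minus":
            strand = "-"
        else:  # plus and dual both record "+"; dual reads draw either strand
            strand = "+"
        truth.planted_clusters.append(
            GenomicFeature(chrom, start, start + length, strand, f"planted_{i + 1}")
        )

    for plan in spec.repeat_plan:
        master = rng.choice(BASES, size=plan.length)
        for copy_idx in range(plan.copy_number):
            chrom, start = packer.place(plan.length, f"repeat {plan.name}")
            copy = master.copy()
            if plan.mutation_rate > 0:
                hits = rng.random(plan.length) < plan.mutation_rate
                copy[hits] = rng.choice(BASES, size=int(hits.sum()))
            if plan.strand_mode == "plus":
                strand = "+"
            elif plan.strand_mode == "minus":
                strand = "-"
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            written = copy if strand == "+" else np.array(
                list(revcomp("".join(copy)))
            )
            genome[chrom][start:start + plan.length] = written
            truth.repeat_copies.append(
                RepeatFeature(chrom, start, start + plan.length, strand,
                              f"{plan.name}#{copy_idx + 1}",
                              repeat_class=plan.repeat_class, family=plan.family)
            )

    for rna_class, length in ncrna_plan:
        chrom, start = packer.place(length, f"ncRNA {rna_class}")
        strand = "+" if rng.random() < 0.5 else "-"
        truth.ncrna.append(
            NcRNAFeature(chrom, start, start + length, strand,
                         f"{rna_class}_1", rna_class=rna_class)
        )

    for i in range(spec.n_genes):
        chrom, start = packer.place(spec.gene_length, f"gene {i + 1}")
        strand = "+" if rng.random() < 0.5 else "-"
        truth.genes.append(
            GeneFeature(chrom, start, start + spec.gene_length, strand,
                        f"gene{i + 1}", gene_id=f"gene{i + 1}")
        )

    return {chrom: "".join(arr) for chrom, arr in genome.items()}, truth


# ---------------------------------------------------------------------------
# read simulation

ORIGIN_COLUMNS = ["read_id", "origin", "origin_id", "chrom", "start", "end",
                  "strand", "insert_len", "insert_seq"]


def _draw_insert(rng: np.random.Generator, genome: Dict[str, str],
                 feat: GenomicFeature, length: int, strand: str,
                 u1: Optional[float]) -> Tuple[int, str]:
    """Start position and sequence of one insert inside ``feat``.

    With probability ``u1`` the genomic base under the read's 5' end is
    required to be T (on the read's strand), otherwise required to be non-T;
    ``u1=None`` leaves the 5' base unconstrained.
    """
    if feat.length < length:
        raise ValueError(
            f"{feat.name}: interval of {feat.length} bp shorter than read "
            f"length {length}"
        )
    seq = genome[feat.chrom]
    want_t = None if u1 is None else bool(rng.random() < u1)
    start = None
    for _ in range(200):
        cand = int(rng.integers(feat.start, feat.end - length + 1))
        if want_t is None:
            start = cand
            break
        base5 = seq[cand] if strand == "+" else revcomp(seq[cand + length - 1])
        if (base5 == "T") == want_t:
            start = cand
            break
    if start is None:  # pathological interval (e.g. no T at all); take any
        start = int(rng.integers(feat.start, feat.end - length + 1))
    insert = seq[start:start + length]
    if strand == "-":
        insert = revcomp(insert)
    return start, insert


def _resolve_strand(rng: np.random.Generator, feat: GenomicFeature, mode: str) -> str:
    if mode == "dual":
        return "+" if rng.random() < 0.5 else "-"
    return feat.strand


def simulate_reads(
    spec: SyntheticSpec,
    genome: Dict[str, str],
    truth: GroundTruth,
) -> Tuple[List[Tuple[str, str, str]], pd.DataFrame]:
    """Simulate adaptered reads; returns (FASTQ records, origin table).

    FASTQ records are (read_id, sequence, quality) with the 3' adapter
    appended to every insert and the result truncated to the sequencer read
    length; the origin table labels each read with exactly one origin
    (cluster | repeat | background | ncrna) and its true genomic interval.
    """
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from the genome
    mix = spec.length_mixture
    rows: List[tuple] = []

    for cluster in truth.planted_clusters:
        lengths = mix.draw(rng, "long", spec.reads_per_cluster)
        for length in lengths:
            strand = _resolve_strand(rng, cluster, spec.cluster_strand_mode)
            start, insert = _draw_insert(rng, genome, cluster, int(length), strand,
                                         spec.u1_probability)
            rows.append(("cluster", cluster.name, cluster.chrom, start,
                         start + int(length), strand, insert))

    for copy in truth.repeat_copies:
        lengths = mix.draw(rng, "long", spec.reads_per_repeat_copy,
                           hi=min(44, copy.length))
        for length in lengths:
            antisense = rng.random() < spec.repeat_antisense_fraction
            strand = {"+": "-", "-": "+"}[copy.strand] if antisense else copy.strand
            start, insert = _draw_insert(rng, genome, copy, int(length), strand,
                                         spec.u1_probability)
            rows.append(("repeat", copy.name, copy.chrom, start,
                         start + int(length), strand, insert))

    chroms = sorted(truth.chrom_lengths)
    lengths = mix.draw(rng, "mixed", spec.background_reads)
    for length in lengths:
        chrom = chroms[rng.integers(len(chroms))]
        strand = "+" if rng.random() < 0.5 else "-"
        whole = GenomicFeature(chrom, 0, truth.chrom_lengths[chrom], "+", "background")
        start, insert = _draw_insert(rng, genome, whole, int(length), strand, None)
        rows.append(("background", "background", chrom, start,
                     start + int(length), strand, insert))

    n_planned = len(rows)
    frac = spec.ncrna_contaminant_fraction
    n_contaminants = int(round(frac / (1 - frac) * n_planned)) if frac < 1 else 0
    if frac > 0 and not truth.ncrna:
        raise ValueError("ncrna_contaminant_fraction > 0 but no ncRNA loci planted")
    for _ in range(n_contaminants):
        locus = truth.ncrna[rng.integers(len(truth.ncrna))]
        length = int(mix.draw(rng, "short", 1, hi=min(44, locus.length))[0])
        start, insert = _draw_insert(rng, genome, locus, length, locus.strand, None)
        rows.append(("ncrna", locus.name, locus.chrom, start, start + length,
                     locus.strand, insert))

    qual = chr(spec.quality_phred + 33)
    fastq: List[Tuple[str, str, str]] = []
    origin_rows = []
    for i, (origin, origin_id, chrom, start, end, strand, insert) in enumerate(rows):
        read_id = f"read{i + 1}"
        seq = (insert + spec.adapter_sequence)[: spec.read_length]
        fastq.append((read_id, seq, qual * len(seq)))
        origin_rows.append((read_id, origin, origin_id, chrom, start, end, strand,
                            len(insert), insert))
    origin = pd.DataFrame(origin_rows, columns=ORIGIN_COLUMNS)
    return fastq, origin


# ---------------------------------------------------------------------------
# output bundle


def write_dataset(spec: SyntheticSpec, outdir) -> Dict[str, Path]:
    """Simulate and write the full fixture bundle; returns {artifact: path}.

    Files: genome FASTA, reads FASTQ, repeat annotation as RepeatMasker .out
    and BED6+2, ncRNA BED6+1 (class column), gene BED6+1, planted-cluster
    BED6, origin-table TSV, and a YAML echo of the spec.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(spec)
    reads, origin = simulate_reads(spec, genome, truth)
    paths = {
        "genome": outdir / "genome.fa",
        "reads": outdir / "reads.fastq",
        "repeats_out": outdir / "repeats.out",
        "repeats_bed": outdir / "repeats.bed",
        "ncrna_bed": outdir / "ncrna.bed",
        "genes_bed": outdir / "genes.bed",
        "clusters_bed": outdir / "clusters_truth.bed",
        "origin": outdir / "origin.tsv",
        "spec": outdir / "spec.yaml",
    }
    _io.write_fasta(genome, paths["genome"])
    _io.write_fastq(reads, paths["reads"])
    _io.write_repeatmasker_out(truth.repeat_copies, paths["repeats_out"])
    _io.write_bed_features(truth.repeat_copies, paths["repeats_bed"])
    _io.write_bed_features(truth.ncrna, paths["ncrna_bed"])
    _io.write_bed_features(truth.genes, paths["genes_bed"])
    with open(paths["clusters_bed"], "w") as handle:
        for c in truth.planted_clusters:
            handle.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.name}\t0\t{c.strand}\n")
    origin.to_csv(paths["origin"], sep="\t", index=False)
    with open(paths["spec"], "w") as handle:
        yaml.safe_dump(spec_to_dict(spec), handle, sort_keys=False)
    return paths


def spec_to_dict(spec: SyntheticSpec) -> dict:
    data = dataclasses.asdict(spec)
    data["cluster_length_range"] = list(spec.cluster_length_range)
    return data


def spec_from_dict(data: dict) -> SyntheticSpec:
    data = dict(data)
    if "repeat_plan" in data:
        data["repeat_plan"] = [
            p if isinstance(p, RepeatPlan) else RepeatPlan(**p)
            for p in data["repeat_plan"]
        ]
    if "length_mixture" in data and not isinstance(data["length_mixture"], LengthMixture):
        data["length_mixture"] = LengthMixture(**data["length_mixture"])
    if "cluster_length_range" in data:
        data["cluster_length_range"] = tuple(data["cluster_length_range"])
    return SyntheticSpec(**data)
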