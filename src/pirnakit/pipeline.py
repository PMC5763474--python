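"""Staged pipeline driver: simulate -> clean -> subtract -> map -> call -> classify.

A plain YAML-configurable orchestrator (no workflow engine): each stage is an
ordinary function from the library modules, every intermediate is exposed in
the returned :class:`PipelineResult`, and all outputs are deterministic given
the config (timestamps go only to the run log).
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import pandas as pd
import yaml

from . import align, classify, core, known, preprocess, report, synthetic
from . import io as _io

DEFAULT_CONFIG: dict = {
    "simulate": synthetic.spec_to_dict(synthetic.SyntheticSpec()),
    "inputs": {  # used instead of simulation when provided
        "genome": None,
        "fastq": {},          # sample -> path
        "ncrna_bed": None,
        "repeats": None,      # .out or .bed
        "genes_bed": None,
        "alignments": None,   # SAM/BAM/BED to ingest instead of built-in mapping
    },
    "preprocess": {
        "adapter": synthetic.DEFAULT_ADAPTER,
        "min_overlap": 3,
        "max_error_rate": 0.1,
        "min_len": 18,
        "max_len": 44,
        "max_n": 0,
    },
    "known": {"min_overlap_fraction": 0.8},
    "align": {"max_mismatches": 1, "max_hits_cap": None, "weighting": "count-weighted"},
    "pirna": {
        "min_len": 24,
        "max_len": 35,
        "window": 2000,
        "step": 400,
        "rpkm_cutoff": 1.0,
        "poisson": False,
        "qvalue_cutoff": 0.05,
    },
    "classify": {"min_overlap_fraction": 0.5, "level": "class"},
}


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path:
        with open(path) as handle:
            user = yaml.safe_load(handle) or {}
        _deep_update(config, user)
    if overrides:
        _deep_update(config, overrides)
    return config


def _deep_update(base: dict, extra: Mapping) -> None:
    for key, value in extra.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


@dataclass
class PipelineResult:
    config: dict
    genome: Dict[str, str]
    tags: List[preprocess.UniqueTag]
    kept_tags: List[preprocess.UniqueTag]
    known_composition: pd.DataFrame
    alignments: Dict[str, list]
    putative: List[core.PutativePiRNA]
    placements: list
    windows: pd.DataFrame
    clusters: pd.DataFrame
    cluster_stats: Dict[str, float]
    categories: pd.DataFrame
    te_table: pd.DataFrame
    summary: pd.DataFrame
    truth: Optional[synthetic.GroundTruth] = None
    origin: Optional[pd.DataFrame] = None


def run_pipeline(config: Optional[dict] = None, outdir: Optional[str] = None) -> PipelineResult:
    """Execute all stages; write the output bundle when ``outdir`` is given."""
    config = config or load_config()
    log: List[str] = []

    def note(msg: str) -> None:
        log.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    inputs = config.get("inputs") or {}
    truth = origin = None
    if inputs.get("genome") and inputs.get("fastq"):
        genome = _io.read_fasta(inputs["genome"])
        reads_by_sample = {
            sample: preprocess.load_fastq(path, sample)
            for sample, path in sorted(inputs["fastq"].items())
        }
        ncrna = _io.read_bed_features(inputs["ncrna_bed"], "ncrna") if inputs.get("ncrna_bed") else []
        repeats = _load_repeats(inputs.get("repeats"))
        genes = _io.read_bed_features(inputs["genes_bed"], "gene") if inputs.get("genes_bed") else []
        note(f"loaded {sum(map(len, reads_by_sample.values()))} reads from "
             f"{len(reads_by_sample)} sample(s)")
    else:
        spec = synthetic.spec_from_dict(config["simulate"])
        genome, truth = synthetic.simulate_genome(spec)
        fastq, origin = synthetic.simulate_reads(spec, genome, truth)
        reads_by_sample = {
            "sim": [preprocess.SmallRNARead(rid, seq, qual, "sim")
                    for rid, seq, qual in fastq]
        }
        ncrna, repeats, genes = truth.ncrna, truth.repeat_copies, truth.genes
        note(f"simulated {len(fastq)} reads (seed {spec.seed})")

    # --- clean reads ------------------------------------------------------
    pp = config["preprocess"]
    tags_per_sample = []
    stage_counts: List[report.SampleSummary] = []
    for sample, reads in reads_by_sample.items():
        trimmed, _ = preprocess.trim_reads(
            reads, pp["adapter"], pp["min_overlap"], pp["max_error_rate"]
        )
        filtered, _ = preprocess.filter_reads(
            trimmed, pp["min_len"], pp["max_len"], pp["max_n"]
        )
        tags_per_sample.append(preprocess.collapse_unique(filtered, sample))
    tags = preprocess.merge_tags(tags_per_sample)
    samples = sorted(reads_by_sample)
    for sample in samples:
        raw_reads = reads_by_sample[sample]
        stage_counts.append(report.SampleSummary(
            sample, "raw",
            len(raw_reads),
            len({r.sequence for r in raw_reads}),
        ))
    note(f"clean reads collapsed to {len(tags)} unique tags")

    # --- placements for all tags (needed for known-RNA subtraction) ------
    al = config["align"]
    if inputs.get("alignments"):
        alignments = align.load_alignments(
            inputs["alignments"],
            tags={t.sequence: t.sequence for t in tags},
            max_mismatches=al["max_mismatches"],
        )
        alignments = {t.sequence: alignments.get(t.sequence, []) for t in tags}
    else:
        alignments = align.exact_match_map(tags, genome, max_hits_cap=al["max_hits_cap"])
    note("mapped tags to the genome")

    # --- known small RNA subtraction --------------------------------------
    classification = known.classify_known(
        tags, alignments, ncrna, genome_chroms=genome.keys(),
        min_overlap_fraction=config["known"]["min_overlap_fraction"],
    )
    kept_tags, composition = known.remove_known(tags, classification)
    for sample in samples:
        stage_counts.append(report.SampleSummary(
            sample, "known_removed",
            sum(t.counts.get(sample, 0) for t in kept_tags),
            sum(1 for t in kept_tags if t.counts.get(sample, 0)),
        ))
    note(f"removed {len(tags) - len(kept_tags)} known-RNA tags")

    # --- mapped + putative selection --------------------------------------
    mapped_tags = [t for t in kept_tags if alignments.get(t.sequence)]
    for sample in samples:
        stage_counts.append(report.SampleSummary(
            sample, "genome_mapped",
            sum(t.counts.get(sample, 0) for t in mapped_tags),
            sum(1 for t in mapped_tags if t.counts.get(sample, 0)),
        ))
    pirna_cfg = config["pirna"]
    tag_counts = {t.sequence: t.total_count for t in tags}
    placements_by_tag = {
        seq: align.assign_weights({seq: hits}, tag_counts, al["weighting"])
        for seq, hits in alignments.items() if hits
    }
    putative = core.select_putative(
        mapped_tags, placements_by_tag, pirna_cfg["min_len"], pirna_cfg["max_len"]
    )
    for sample in samples:
        stage_counts.append(report.SampleSummary(
            sample, "putative_pirna",
            sum(p.tag.counts.get(sample, 0) for p in putative),
            sum(1 for p in putative if p.tag.counts.get(sample, 0)),
        ))
    note(f"selected {len(putative)} putative piRNA tags")

    # --- cluster calling ---------------------------------------------------
    placements = [pl for p in putative for pl in p.placements]
    chrom_lengths = {name: len(seq) for name, seq in genome.items()}
    windows = core.window_scan(
        placements, pirna_cfg["window"], pirna_cfg["step"], chrom_lengths=chrom_lengths
    )
    qcut = None
    if pirna_cfg.get("poisson"):
        windows = core.poisson_window_test(
            windows, core.effective_genome_length(genome)
        )
        qcut = pirna_cfg["qvalue_cutoff"]
    clusters = core.call_clusters(
        windows, placements, rpkm_cutoff=pirna_cfg["rpkm_cutoff"], qvalue_cutoff=qcut
    )
    core.assign_cluster_ids(putative, clusters)
    cluster_stats = core.cluster_summary(clusters, placements)
    note(f"called {len(clusters)} clusters")

    # --- classification ----------------------------------------------------
    cl = config["classify"]
    categories = classify.categorize(
        putative, repeats, genes, min_overlap_fraction=cl["min_overlap_fraction"],
        genome_chroms=genome.keys(),
    )
    te_table = classify.te_composition(placements, repeats, level=cl["level"])
    summary = report.build_summary(stage_counts)

    result = PipelineResult(
        config=config, genome=genome, tags=tags, kept_tags=kept_tags,
        known_composition=composition, alignments=alignments, putative=putative,
        placements=placements, windows=windows, clusters=clusters,
        cluster_stats=cluster_stats, categories=categories, te_table=te_table,
        summary=summary, truth=truth, origin=origin,
    )
    if outdir is not None:
        write_outputs(result, outdir, log)
    return result


def _load_repeats(path):
    if not path:
        return []
    if str(path).endswith(".out"):
        return _io.read_repeatmasker_out(path)
    return _io.read_bed_features(path, "repeat")


def write_outputs(result: PipelineResult, outdir, log: Optional[List[str]] = None) -> Dict[str, Path]:
    """Write the deterministic output bundle (timestamps only in run.log)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("summary", "summary.tsv"),
        ("known_composition", "known_composition.tsv"),
        ("clusters_bed", "clusters.bed"),
        ("clusters_tsv", "clusters.tsv"),
        ("candidates_fasta", "candidates.fasta"),
        ("candidates_tsv", "candidates.tsv"),
        ("categories", "categories.tsv"),
        ("te_composition", "te_composition.tsv"),
        ("length_histogram", "length_histogram.tsv"),
        ("first_base", "first_base.tsv"),
        ("config", "config.yaml"),
        ("log", "run.log"),
    ]}
    report.write_summary_tsv(result.summary, paths["summary"])
    flat = result.known_composition.copy()
    flat.columns = [f"{a}_{b}" for a, b in flat.columns]
    flat.index.name = "rna_class"
    flat.to_csv(paths["known_composition"], sep="\t")
    core.write_clusters_bed(result.clusters, paths["clusters_bed"])
    result.clusters.to_csv(paths["clusters_tsv"], sep="\t", index=False)

    candidates = [p for p in result.putative if p.cluster_id]
    _io.write_fasta(
        {f"{p.cluster_id}|cand{i + 1}_x{p.tag.total_count}": p.tag.sequence
         for i, p in enumerate(candidates)},
        paths["candidates_fasta"],
    )
    pd.DataFrame(
        [(p.tag.sequence, p.length, p.first_base, p.tag.total_count, p.cluster_id)
         for p in candidates],
        columns=["sequence", "length", "first_base", "count", "cluster_id"],
    ).to_csv(paths["candidates_tsv"], sep="\t", index=False)

    result.categories.to_csv(paths["categories"], sep="\t", index=False)
    result.te_table.to_csv(paths["te_composition"], sep="\t", index=False)

    items = result.putative if result.putative else result.tags
    hist = core.length_histogram(items) if items else {}
    pd.DataFrame(sorted(hist.items()), columns=["length", "count"]).to_csv(
        paths["length_histogram"], sep="\t", index=False
    )
    if items:
        bias = core.first_base_bias(items)
        pd.DataFrame(sorted(bias.items()), columns=["base", "fraction"]).to_csv(
            paths["first_base"], sep="\t", index=False
        )
    else:
        pd.DataFrame(columns=["base", "fraction"]).to_csv(
            paths["first_base"], sep="\t", index=False
        )
    with open(paths["config"], "w") as handle:
        yaml.safe_dump(result.config, handle, sort_keys=False)
    with open(paths["log"], "w") as handle:
        handle.write("\n".join(log or []) + "\n")
    return paths
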