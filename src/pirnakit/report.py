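"""Per-sample, per-stage read accounting and the summary table.

The summary mirrors the conventional small-RNA processing table: one row per
stage (raw reads, known small RNAs removed, mapped to the genome, putative
piRNAs), per-sample Total/Unique column pairs, and a grand Total pair that is
the row-wise sum. Percentages are rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from ._util import percentage

STAGES = ("raw", "known_removed", "genome_mapped", "putative_pirna")

STAGE_LABELS = {
    "raw": "Raw reads",
    "known_removed": "Remove known small RNAs",
    "genome_mapped": "Remove unmapped reads to the reference genome",
    "putative_pirna": "Putative piRNA",
}


@dataclass(frozen=True)
class SampleSummary:
    sample: str
    stage: str
    total_reads: int
    unique_tags: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")


def build_summary(summaries: Iterable[SampleSummary],
                  stages: Sequence[str] = STAGES) -> pd.DataFrame:
    """Stage x (sample, total/unique) table with a computed grand-Total pair.

    Every sample must report every stage (a missing stage raises, naming it),
    and within each sample totals and uniques must be non-increasing across
    successive stages — reads are only ever discarded.
    """
    by_key: Dict[tuple, SampleSummary] = {}
    samples: List[str] = []
    for s in summaries:
        by_key[(s.sample, s.stage)] = s
        if s.sample not in samples:
            samples.append(s.sample)
    for sample in samples:
        for stage in stages:
            if (sample, stage) not in by_key:
                raise ValueError(f"sample {sample!r} is missing stage {stage!r}")
    for sample in samples:
        for prev, cur in zip(stages, stages[1:]):
            a, b = by_key[(sample, prev)], by_key[(sample, cur)]
            if b.total_reads > a.total_reads or b.unique_tags > a.unique_tags:
                raise ValueError(
                    f"sample {sample!r}: counts increase from stage {prev!r} "
                    f"to {cur!r}"
                )
    columns = pd.MultiIndex.from_tuples(
        [(s, k) for s in list(samples) + ["Total"] for k in ("total", "unique")]
    )
    rows = []
    for stage in stages:
        row = []
        for sample in samples:
            s = by_key[(sample, stage)]
            row.extend([s.total_reads, s.unique_tags])
        row.append(sum(row[0::2]))
        row.append(sum(row[1:-1:2]))
        rows.append(row)
    return pd.DataFrame(rows, index=list(stages), columns=columns, dtype="int64")


def stage_percentages(summary: pd.DataFrame, reference_stage: str = "raw") -> pd.DataFrame:
    """Each stage's Total column as a percent of the reference stage (2 dp)."""
    ref_total = int(summary.loc[reference_stage, ("Total", "total")])
    ref_unique = int(summary.loc[reference_stage, ("Total", "unique")])
    rows = {
        stage: [
            percentage(int(summary.loc[stage, ("Total", "total")]), ref_total),
            percentage(int(summary.loc[stage, ("Total", "unique")]), ref_unique),
        ]
        for stage in summary.index
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["total_pct", "unique_pct"]
    )


def write_summary_tsv(summary: pd.DataFrame, path) -> None:
    flat = summary.copy()
    flat.columns = [f"{sample}_{kind}" for sample, kind in summary.columns]
    flat.index.name = "stage"
    flat.to_csv(path, sep="\t")
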