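"""Putative-piRNA selection, 5' base bias, and sliding-window cluster calling.

The cluster caller slides a ``window`` (default 2 kb) along each chromosome in
``step`` (default 400 bp) increments and scores each window by RPKM — reads
per kilobase of window per million mapped piRNA reads — where "reads" are the
fractional multimapper weights and a placement belongs to a window iff its
strand-aware 5' end falls inside it (so total weight is conserved across the
non-overlapping phase of the tiling). Windows at or above the RPKM cutoff that
overlap or abut are merged into maximal cluster regions; cluster read counts
are then recomputed once over the merged interval so overlapping member
windows never double-count.

A Poisson enrichment test is offered alongside the plain RPKM cutoff: under a
uniform null, a window's fractional count is Poisson with mean
lambda = library_total * window / effective_genome_length, and the one-sided
tail probability P(X >= ceil(observed)) is corrected across windows by
Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .align import WeightedPlacement, placements_frame
from .preprocess import UniqueTag

WINDOW_COLUMNS = ["chrom", "start", "length", "fractional_count", "rpkm"]


@dataclass
class PutativePiRNA:
    """A mapped tag inside the piRNA size range, with its weighted placements."""

    tag: UniqueTag
    placements: List[WeightedPlacement] = field(default_factory=list)
    cluster_id: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.tag.sequence)

    @property
    def first_base(self) -> str:
        return self.tag.sequence[0]


def select_putative(
    tags: Sequence[UniqueTag],
    placements_by_tag: Mapping[str, Sequence[WeightedPlacement]],
    min_len: int = 24,
    max_len: int = 35,
) -> List[PutativePiRNA]:
    """Keep mapped tags with min_len <= length <= max_len (24-35 nt default)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    out = []
    for tag in tags:
        hits = placements_by_tag.get(tag.sequence)
        if hits and min_len <= len(tag.sequence) <= max_len:
            out.append(PutativePiRNA(tag, list(hits)))
    return out


# ---------------------------------------------------------------------------
# composition statistics

Item = Union[UniqueTag, PutativePiRNA, str]


def _seq_weight(item: Item, weighting: str) -> tuple:
    if isinstance(item, PutativePiRNA):
        item = item.tag
    if isinstance(item, UniqueTag):
        return item.sequence, (item.total_count if weighting == "redundant" else 1)
    return item, 1


def first_base_bias(items: Sequence[Item], weighting: str = "redundant") -> Dict[str, float]:
    """Fractions of first (5') bases over {A, C, G, T, N}; U is reported as T.

    ``weighting="redundant"`` weighs each tag by its read count,
    ``"unique"`` counts each distinct sequence once.
    """
    if weighting not in ("redundant", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    counts = {b: 0.0 for b in "ACGTN"}
    total = 0.0
    for item in items:
        seq, w = _seq_weight(item, weighting)
        counts[seq[0]] += w
        total += w
    if total == 0:
        raise ValueError("first_base_bias on empty input")
    return {b: c / total for b, c in counts.items()}


def length_histogram(items: Sequence[Item], weighting: str = "redundant",
                     min_len: Optional[int] = None,
                     max_len: Optional[int] = None) -> Dict[int, float]:
    """Length histogram; bins cover [min_len, max_len] even where empty."""
    if weighting not in ("redundant", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    hist: Dict[int, float] = {}
    for item in items:
        seq, w = _seq_weight(item, weighting)
        hist[len(seq)] = hist.get(len(seq), 0) + w
    lo = min_len if min_len is not None else (min(hist) if hist else 0)
    hi = max_len if max_len is not None else (max(hist) if hist else -1)
    return {length: hist.get(length, 0) for length in range(lo, hi + 1)}


# ---------------------------------------------------------------------------
# sliding windows


def _as_frame(placements) -> pd.DataFrame:
    if isinstance(placements, pd.DataFrame):
        df = placements
        if "five_prime" not in df.columns:
            df = df.assign(
                five_prime=np.where(df["strand"] == "+", df["start"], df["end"] - 1)
            )
        return df
    return placements_frame(placements)


def window_scan(
    placements,
    window: int = 2000,
    step: int = 400,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    library_total: Optional[float] = None,
    count_mode: str = "five_prime",
) -> pd.DataFrame:
    """Tile windows along each chromosome and accumulate fractional counts.

    ``placements`` is a WeightedPlacement iterable or an equivalent DataFrame.
    Windows start at multiples of ``step`` from 0; without ``chrom_lengths``
    the tiling extends to the last window containing a placement 5' end. The
    default ``count_mode="five_prime"`` counts a placement in a window iff its
    strand-aware 5' end lies in [start, start + window); ``"overlap"`` counts
    it in every window its interval intersects (and then total weight is not
    conserved across overlapping windows).

    RPKM = fractional_count / (window/1000) / (library_total/1e6), with
    library_total defaulting to the total weight of the placements given.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if window < step:
        raise ValueError(f"window {window} smaller than step {step}")
    if count_mode not in ("five_prime", "overlap"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    df = _as_frame(placements)
    if library_total is None:
        library_total = float(df["weight"].sum())
    frames = []
    chroms = sorted(set(df["chrom"])) if chrom_lengths is None else sorted(chrom_lengths)
    for chrom in chroms:
        sub = df[df["chrom"] == chrom]
        if chrom_lengths is not None:
            last_start = max(0, (int(chrom_lengths[chrom]) - 1) // step * step)
        elif len(sub):
            last_start = int(sub["five_prime"].max()) // step * step
        else:
            continue
        n_windows = last_start // step + 1
        counts = np.zeros(n_windows)
        if len(sub):
            w = sub["weight"].to_numpy(float)
            if count_mode == "five_prime":
                pos = sub["five_prime"].to_numpy(np.int64)
                first = np.maximum(0, (pos - window) // step + 1)
                last = np.minimum(pos // step, n_windows - 1)
            else:
                starts = sub["start"].to_numpy(np.int64)
                ends = sub["end"].to_numpy(np.int64)
                first = np.maximum(0, (starts - window) // step + 1)
                last = np.minimum((ends - 1) // step, n_windows - 1)
            span = int((last - first).max()) + 1 if len(sub) else 0
            for j in range(span):
                idx = first + j
                ok = idx <= last
                np.add.at(counts, idx[ok], w[ok])
        starts = np.arange(n_windows, dtype=np.int64) * step
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "length": window,
                    "fractional_count": counts,
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=WINDOW_COLUMNS[:4])
    denom = (window / 1000.0) * (library_total / 1e6) if library_total > 0 else np.nan
    out["rpkm"] = out["fractional_count"] / denom if library_total > 0 else 0.0
    out.attrs.update(window=window, step=step, library_total=library_total)
    return out


# ---------------------------------------------------------------------------
# Poisson enrichment test


def poisson_window_test(
    windows: pd.DataFrame,
    effective_genome_length: int,
    library_total: Optional[float] = None,
) -> pd.DataFrame:
    """One-sided Poisson tail p-values per window with BH-adjusted q-values.

    Null mean: lambda = library_total * window_length / effective_genome_length.
    p = P(Poisson(lambda) >= ceil(observed fractional count)).
    """
    if effective_genome_length <= 0:
        raise ValueError("effective_genome_length must be positive")
    if library_total is None:
        library_total = windows.attrs.get("library_total")
    if not library_total or library_total <= 0:
        raise ValueError("library_total must be positive")
    out = windows.copy()
    lam = library_total * out["length"].to_numpy(float) / effective_genome_length
    observed = np.ceil(out["fractional_count"].to_numpy(float))
    # sf(k-1) == P(X >= k); observed == 0 gives sf(-1) == 1 as required
    out["pvalue"] = _stats.poisson.sf(observed - 1, lam)
    out["qvalue"] = _bh_adjust(out["pvalue"].to_numpy(float))
    return out


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    n = len(pvalues)
    if n == 0:
        return pvalues.copy()
    order = np.argsort(pvalues)
    ranked = pvalues[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# cluster calling

CLUSTER_COLUMNS = [
    "cluster_id", "chrom", "start", "end", "n_windows",
    "fractional_count", "max_rpkm", "plus_fraction", "strand_call",
]


def call_clusters(
    windows: pd.DataFrame,
    placements,
    rpkm_cutoff: float = 1.0,
    plus_threshold: float = 0.8,
    qvalue_cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Merge significant windows into maximal disjoint cluster regions.

    A window is significant if rpkm >= rpkm_cutoff (and, when
    ``qvalue_cutoff`` is given and the windows carry a Poisson ``qvalue``
    column, qvalue <= qvalue_cutoff as well). Significant windows that overlap
    or abut merge; each cluster's fractional count is recomputed over the
    merged interval from the placements' 5' ends, so no weight is counted
    twice. Strand call: "plus" if the + share of weight >= plus_threshold,
    "minus" if <= 1 - plus_threshold, else "dual".
    """
    window = windows.attrs.get("window", int(windows["length"].iloc[0]) if len(windows) else 2000)
    sig = windows[windows["rpkm"] >= rpkm_cutoff]
    if qvalue_cutoff is not None and "qvalue" in windows.columns:
        sig = sig[sig["qvalue"] <= qvalue_cutoff]
    df = _as_frame(placements)
    rows = []
    for chrom, group in sig.groupby("chrom", sort=True):
        starts = np.sort(group["start"].to_numpy(np.int64))
        if len(starts) == 0:
            continue
        run_start = prev = starts[0]
        runs = []
        count = 1
        for s in starts[1:]:
            if s <= prev + window:  # overlap or abut
                prev = s
                count += 1
            else:
                runs.append((run_start, prev + window, count))
                run_start = prev = s
                count = 1
        runs.append((run_start, prev + window, count))
        sub = df[df["chrom"] == chrom]
        fp = sub["five_prime"].to_numpy(np.int64)
        w = sub["weight"].to_numpy(float)
        plus = (sub["strand"] == "+").to_numpy()
        for start, end, n_win in runs:
            inside = (fp >= start) & (fp < end)
            total = float(w[inside].sum())
            plus_w = float(w[inside & plus].sum())
            plus_frac = plus_w / total if total > 0 else 0.5
            if plus_frac >= plus_threshold:
                strand_call = "plus"
            elif plus_frac <= 1 - plus_threshold:
                strand_call = "minus"
            else:
                strand_call = "dual"
            member = group[(group["start"] >= start) & (group["start"] < end)]
            rows.append(
                (chrom, start, end, n_win, total, float(member["rpkm"].max()),
                 plus_frac, strand_call)
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    out = pd.DataFrame(
        [(f"cluster_{i + 1}",) + r for i, r in enumerate(rows)], columns=CLUSTER_COLUMNS
    )
    out.attrs.update(window=window, library_total=windows.attrs.get("library_total"))
    return out


def assign_cluster_ids(putative: Sequence[PutativePiRNA], clusters: pd.DataFrame) -> None:
    """Label each putative piRNA with the cluster containing any placement 5' end.

    "Candidate" piRNAs are then the unique putative tags carrying a cluster id.
    """
    by_chrom: Dict[str, List[tuple]] = {}
    for row in clusters.itertuples(index=False):
        by_chrom.setdefault(row.chrom, []).append((row.start, row.end, row.cluster_id))
    for p in putative:
        p.cluster_id = None
        for pl in p.placements:
            for start, end, cid in by_chrom.get(pl.chrom, ()):
                if start <= pl.five_prime < end:
                    p.cluster_id = cid
                    break
            if p.cluster_id:
                break


def cluster_summary(
    clusters: pd.DataFrame,
    placements,
    library_total: Optional[float] = None,
) -> Dict[str, float]:
    """Cluster count, size range, and the in-cluster fraction of piRNA weight."""
    df = _as_frame(placements)
    if library_total is None:
        library_total = float(df["weight"].sum())
    in_cluster = 0.0
    for chrom, group in clusters.groupby("chrom"):
        sub = df[df["chrom"] == chrom]
        fp = sub["five_prime"].to_numpy(np.int64)
        w = sub["weight"].to_numpy(float)
        mask = np.zeros(len(sub), dtype=bool)
        for row in group.itertuples(index=False):
            mask |= (fp >= row.start) & (fp < row.end)
        in_cluster += float(w[mask].sum())
    lengths = (clusters["end"] - clusters["start"]) if len(clusters) else pd.Series(dtype=int)
    return {
        "n_clusters": int(len(clusters)),
        "min_length": int(lengths.min()) if len(clusters) else 0,
        "max_length": int(lengths.max()) if len(clusters) else 0,
        "total_length": int(lengths.sum()) if len(clusters) else 0,
        "in_cluster_weight_fraction": in_cluster / library_total if library_total else 0.0,
    }


def effective_genome_length(genome: Mapping[str, str]) -> int:
    """Total non-N genome length (the uniform-null denominator)."""
    return sum(len(seq) - seq.upper().count("N") for seq in genome.values())


def write_clusters_bed(clusters: pd.DataFrame, path) -> None:
    """BED6: score = round(10 * max_rpkm), strand '.', '+' or '-' per call."""
    strand_map = {"plus": "+", "minus": "-", "dual": "."}
    with open(path, "w") as handle:
        for row in clusters.itertuples(index=False):
            score = int(round(10 * row.max_rpkm))
            handle.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.cluster_id}\t{score}\t"
                f"{strand_map[row.strand_call]}\n"
            )
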