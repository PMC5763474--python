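"""Clean-reads stage: 3' adapter trimming, length/N filtering, tag collapsing.

Adapter matching is mismatch-tolerant but gapless: the leftmost read position
at which a prefix of the adapter aligns with at most ``max_error_rate``
mismatches (over at least ``min_overlap`` bases) marks the insert end, and the
suffix from that position onward is removed. This is a deliberate dialect
difference from gapped trimmers — adequate because the simulator introduces no
indels — and is idempotent, since the trimmed product no longer contains an
adapter prefix at any position that survived the first pass.

Collapsing identical sequences yields :class:`UniqueTag` records carrying
per-sample redundant counts, the unit of "Total/Unique" accounting used by the
summary table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from ._util import validate_dna
from . import io as _io


@dataclass
class SmallRNARead:
    read_id: str
    sequence: str
    qualities: Optional[str] = None
    sample: str = "sample"

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class UniqueTag:
    """A distinct small-RNA sequence with per-sample redundant read counts."""

    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class FilterStats:
    """Per-sample kept/discarded tallies for one filtering pass."""

    kept: Counter = field(default_factory=Counter)
    discarded: Counter = field(default_factory=Counter)

    def total_in(self, sample: str) -> int:
        return self.kept[sample] + self.discarded[sample]


def load_fastq(path, sample: str) -> List[SmallRNARead]:
    return [
        SmallRNARead(read_id, seq, qual, sample)
        for read_id, seq, qual in _io.read_fastq(path)
    ]


# ---------------------------------------------------------------------------
# adapter trimming


def find_adapter(sequence: str, adapter: str, min_overlap: int = 3,
                 max_error_rate: float = 0.1) -> int:
    """Return the leftmost adapter-start position in ``sequence``, or -1.

    A hit at position i aligns sequence[i:i+L] against adapter[:L] with
    L = min(len(sequence)-i, len(adapter)), requires L >= min_overlap, and
    tolerates at most floor(max_error_rate * L) mismatches (no indels).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    n = len(sequence)
    for i in range(0, n - min_overlap + 1):
        length = min(n - i, len(adapter))
        allowed = int(max_error_rate * length)
        mismatches = 0
        for a, b in zip(sequence[i:i + length], adapter[:length]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return i
    return -1


def trim_adapter(read: SmallRNARead, adapter: str, min_overlap: int = 3,
                 max_error_rate: float = 0.1) -> Optional[SmallRNARead]:
    """Strip the 3' adapter from one read; None means the read became empty.

    Reads with no adapter hit are returned unchanged (the permissive choice;
    callers that want to drop untrimmed reads can compare lengths).
    """
    validate_dna(read.sequence, f"read {read.read_id}")
    pos = find_adapter(read.sequence, adapter, min_overlap, max_error_rate)
    if pos < 0:
        return read
    if pos == 0:
        return None
    return SmallRNARead(
        read.read_id,
        read.sequence[:pos],
        read.qualities[:pos] if read.qualities is not None else None,
        read.sample,
    )


def trim_reads(reads: Iterable[SmallRNARead], adapter: str, min_overlap: int = 3,
               max_error_rate: float = 0.1,
               require_adapter: bool = False) -> Tuple[List[SmallRNARead], FilterStats]:
    """Trim a batch; ``require_adapter`` drops reads with no adapter hit."""
    stats = FilterStats()
    out: List[SmallRNARead] = []
    for read in reads:
        validate_dna(read.sequence, f"read {read.read_id}")
        pos = find_adapter(read.sequence, adapter, min_overlap, max_error_rate)
        if pos == 0 or (pos < 0 and require_adapter):
            stats.discarded[read.sample] += 1
            continue
        if pos > 0:
            read = SmallRNARead(
                read.read_id,
                read.sequence[:pos],
                read.qualities[:pos] if read.qualities is not None else None,
                read.sample,
            )
        out.append(read)
        stats.kept[read.sample] += 1
    return out, stats


# ---------------------------------------------------------------------------
# length / ambiguity filtering


def filter_reads(reads: Iterable[SmallRNARead], min_len: int = 18, max_len: int = 44,
                 max_n: int = 0,
                 min_mean_quality: Optional[float] = None
                 ) -> Tuple[List[SmallRNARead], FilterStats]:
    """Keep reads with min_len <= length <= max_len and <= max_n ambiguous bases.

    ``min_mean_quality`` optionally adds a mean-Phred floor (off by default).
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    stats = FilterStats()
    kept: List[SmallRNARead] = []
    for read in reads:
        ok = min_len <= len(read) <= max_len and read.sequence.count("N") <= max_n
        if ok and min_mean_quality is not None and read.qualities:
            mean_q = sum(ord(c) - 33 for c in read.qualities) / len(read.qualities)
            ok = mean_q >= min_mean_quality
        if ok:
            kept.append(read)
            stats.kept[read.sample] += 1
        else:
            stats.discarded[read.sample] += 1
    return kept, stats


# ---------------------------------------------------------------------------
# collapsing


def collapse_unique(reads: Iterable[SmallRNARead], sample: Optional[str] = None
                    ) -> List[UniqueTag]:
    """Collapse reads to unique tags with per-sample redundant counts.

    If ``sample`` is given it overrides each read's own sample label. Tags are
    returned in descending count then lexicographic order (deterministic).
    """
    counts: Counter = Counter()
    for read in reads:
        counts[(read.sequence, sample or read.sample)] += 1
    tags: Dict[str, UniqueTag] = {}
    for (seq, smp), n in counts.items():
        tag = tags.setdefault(seq, UniqueTag(seq))
        tag.counts[smp] = tag.counts.get(smp, 0) + n
    return sorted(tags.values(), key=lambda t: (-t.total_count, t.sequence))


def merge_tags(tag_sets: Iterable[List[UniqueTag]]) -> List[UniqueTag]:
    """Merge per-sample tag sets into one set keyed by sequence."""
    merged: Dict[str, UniqueTag] = {}
    for tags in tag_sets:
        for tag in tags:
            target = merged.setdefault(tag.sequence, UniqueTag(tag.sequence))
            for smp, n in tag.counts.items():
                target.counts[smp] = target.counts.get(smp, 0) + n
    return sorted(merged.values(), key=lambda t: (-t.total_count, t.sequence))


def write_collapsed_fasta(tags: Iterable[UniqueTag], path) -> None:
    """Collapsed-FASTA convention: ``>tag{serial}_x{count}`` headers."""
    _io.write_fasta(
        {f"tag{i}_x{t.total_count}": t.sequence for i, t in enumerate(tags, start=1)},
        path,
    )
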