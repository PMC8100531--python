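"""Raw-read cleaning: adapter trimming and the two-stage length/quality filter.

Small RNA libraries read through the insert into the 3′ adapter, so the
adapter prefix is trimmed from the 3′ end of each read first.  Reads are
then removed, in a fixed order so every read lands in exactly one bin, if
they are low quality (mean Phred below a threshold), poly-N (too many
ambiguous bases), outside the clean-read length window (stage 1, default
18–34 nt inclusive) or outside the piRNA-range window (stage 2, default
24–32 nt inclusive).  Stage-2 survivors are the piRNA-range reads used for
mapping, clustering and differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass
class SmallRNARead:
    """One sequencing read: id, nucleotide sequence and per-base Phred scores."""

    read_id: str
    seq: str
    qual: list[int] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_quality(self) -> float:
        return sum(self.qual) / len(self.qual) if self.qual else 0.0

    @property
    def n_fraction(self) -> float:
        return self.seq.count("N") / len(self.seq) if self.seq else 1.0


@dataclass
class ReadStats:
    """Accounting of one library through the cleaning stages.

    Every raw read is counted exactly once: either clean or in one failure
    bin, so ``n_clean = n_raw - sum(failure bins)`` always holds.
    ``n_adapter_trimmed`` counts reads shortened by adapter trimming and is
    informational (trimmed reads are not removed).
    """

    n_raw: int = 0
    n_adapter_trimmed: int = 0
    n_fail_quality: int = 0
    n_fail_polyN: int = 0
    n_fail_length_stage1: int = 0
    n_fail_length_stage2: int = 0
    n_clean: int = 0

    def failures(self) -> int:
        return (self.n_fail_quality + self.n_fail_polyN
                + self.n_fail_length_stage1 + self.n_fail_length_stage2)

    def validate(self) -> None:
        counts = (self.n_raw, self.n_adapter_trimmed, self.n_fail_quality,
                  self.n_fail_polyN, self.n_fail_length_stage1,
                  self.n_fail_length_stage2, self.n_clean)
        if any(c < 0 for c in counts):
            raise ValueError("negative count in ReadStats")
        if self.n_clean != self.n_raw - self.failures():
            raise ValueError(
                f"inconsistent ReadStats: clean={self.n_clean} != "
                f"raw={self.n_raw} - failures={self.failures()}"
            )


def trim_adapter(read: SmallRNARead, adapter: str, min_overlap: int = 5) -> SmallRNARead:
    """Remove the longest 3′ suffix of ``read`` that exactly matches a prefix
    of ``adapter`` (at least ``min_overlap`` bases); quality is truncated in
    lockstep.  A read with no adapter suffix is returned unchanged.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    max_ov = min(len(read.seq), len(adapter))
    for ov in range(max_ov, min_overlap - 1, -1):
        if read.seq[-ov:] == adapter[:ov]:
            return SmallRNARead(read.read_id, read.seq[:-ov], read.qual[:-ov])
    return read


def filter_reads(
    reads: Iterable[SmallRNARead],
    stage1_window: tuple[int, int] = (18, 34),
    stage2_window: tuple[int, int] = (24, 32),
    max_n_frac: float = 0.10,
    min_mean_quality: float = 20.0,
) -> tuple[list[SmallRNARead], ReadStats]:
    """Apply the quality → poly-N → stage-1 length → stage-2 length filter.

    Both windows are inclusive on both ends and stage 2 must nest inside
    stage 1.  Returns the surviving (piRNA-range) reads and the stats.
    """
    s1_lo, s1_hi = stage1_window
    s2_lo, s2_hi = stage2_window
    if not (s1_lo <= s2_lo and s2_hi <= s1_hi):
        raise ValueError(f"stage2 window {stage2_window} not nested in stage1 {stage1_window}")

    stats = ReadStats()
    clean: list[SmallRNARead] = []
    for read in reads:
        stats.n_raw += 1
        if read.mean_quality < min_mean_quality:
            stats.n_fail_quality += 1
        elif read.n_fraction > max_n_frac:
            stats.n_fail_polyN += 1
        elif not (s1_lo <= len(read) <= s1_hi):
            stats.n_fail_length_stage1 += 1
        elif not (s2_lo <= len(read) <= s2_hi):
            stats.n_fail_length_stage2 += 1
        else:
            stats.n_clean += 1
            clean.append(read)
    stats.validate()
    return clean, stats


def process_reads(
    reads: Iterable[SmallRNARead],
    adapter: str,
    min_overlap: int = 5,
    **filter_kwargs,
) -> tuple[list[SmallRNARead], ReadStats]:
    """Trim the 3′ adapter from every read, then run :func:`filter_reads`."""
    trimmed: list[SmallRNARead] = []
    n_trimmed = 0
    for read in reads:
        out = trim_adapter(read, adapter, min_overlap) if adapter else read
        if len(out) < len(read):
            n_trimmed += 1
        trimmed.append(out)
    clean, stats = filter_reads(trimmed, **filter_kwargs)
    stats.n_adapter_trimmed = n_trimmed
    stats.validate()
    return clean, stats


STATS_COLUMNS: Sequence[str] = (
    "n_raw", "n_clean", "n_adapter_trimmed", "n_fail_quality",
    "n_fail_polyN", "n_fail_length_stage1", "n_fail_length_stage2",
)


def summarize(stats: ReadStats) -> str:
    """One tab-separated row of the library accounting, raw and clean counts
    first (the order the study's overview table prints them).  Inconsistent
    stats are rejected.
    """
    stats.validate()
    return "\t".join(str(getattr(stats, col)) for col in STATS_COLUMNS)
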