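"""ncRNA filtering and end-to-end genome mapping of piRNA-range reads.

Reads matching known non-coding RNA (rRNA, tRNA, snRNA, snoRNA, repeat)
reference sequences are removed by exact substring match before mapping.
The mapper is a k-mer seed-and-verify aligner: end-to-end, substitutions
only, no indels.  For ``max_mismatch`` mismatches it places ``max_mismatch
+ 1`` non-overlapping seeds along the read (pigeonhole: at least one seed
is mismatch-free), looks each up in a genome k-mer index and verifies the
implied window.  Reads shorter than ``(max_mismatch + 1) * k`` fall back
to a full scan.  Both strands are searched; multi-mapped reads keep all
hits and are weighted 1/(number of hits) downstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .readproc import SmallRNARead
from .seqio import revcomp


@dataclass(frozen=True, order=True)
class GenomeHit:
    """Placement of a read on the reference: 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Coordinate of the read's 5′ end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class MappingStats:
    """Input/ncRNA-removed/mapped/unmapped accounting for one library."""

    n_input: int
    n_ncrna_removed: int
    n_mapped: int
    n_unmapped: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in (self.n_input, self.n_ncrna_removed, self.n_mapped, self.n_unmapped)):
            raise ValueError("negative count in MappingStats")
        if self.n_input != self.n_ncrna_removed + self.n_mapped + self.n_unmapped:
            raise ValueError("MappingStats does not balance: input != removed + mapped + unmapped")

    @property
    def mapped_ratio(self) -> float:
        # denominator = clean reads entering this stage (before ncRNA removal),
        # the only denominator consistent with the study's overview table
        return mapped_ratio(self.n_mapped, self.n_input)


def mapped_ratio(n_mapped: int, n_clean: int) -> float:
    """Percentage of clean reads placed on the genome: 100 * mapped / clean."""
    if n_clean <= 0:
        raise ValueError("mapped ratio undefined for zero clean reads")
    return 100.0 * n_mapped / n_clean


def filter_ncrna(
    reads: Sequence[SmallRNARead],
    ncrna_sequences: Iterable[str],
) -> tuple[list[SmallRNARead], int]:
    """Remove reads whose sequence is an exact substring of any ncRNA
    reference (either strand).  Returns (kept reads, removed count).
    """
    refs = list(ncrna_sequences)
    haystack = "#".join(refs + [revcomp(r) for r in refs])
    kept = [r for r in reads if r.seq not in haystack]
    return kept, len(reads) - len(kept)


class GenomeIndex:
    """k-mer index of a genome's forward strand for seed-and-verify mapping."""

    def __init__(self, genome: dict[str, str], k: int = 12):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.chroms = {name: seq.upper() for name, seq in genome.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.chroms.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i:i + k]].append((name, i))

    def _verify(self, query: str, chrom: str, start: int, max_mismatch: int) -> int | None:
        seq = self.chroms[chrom]
        end = start + len(query)
        if start < 0 or end > len(seq):
            return None
        mm = 0
        for a, b in zip(query, seq[start:end]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    return None
        return mm

    def _candidates(self, query: str, max_mismatch: int) -> set[tuple[str, int]]:
        k, L = self.k, len(query)
        n_seeds = max_mismatch + 1
        cands: set[tuple[str, int]] = set()
        if L >= n_seeds * k:
            # non-overlapping seeds; pigeonhole guarantees one exact seed
            offsets = [i * (L // n_seeds) for i in range(n_seeds)]
            for off in offsets:
                for chrom, pos in self._index.get(query[off:off + k], ()):
                    cands.add((chrom, pos - off))
        else:
            for chrom, seq in self.chroms.items():
                cands.update((chrom, i) for i in range(len(seq) - L + 1))
        return cands

    def map_sequence(self, seq: str, max_mismatch: int = 0) -> list[GenomeHit]:
        """All end-to-end placements of ``seq`` with <= max_mismatch
        substitutions, both strands, sorted by (chrom, start, strand).
        """
        hits: list[GenomeHit] = []
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for chrom, start in self._candidates(query, max_mismatch):
                mm = self._verify(query, chrom, start, max_mismatch)
                if mm is not None:
                    hits.append(GenomeHit(chrom, start, start + len(seq), strand, mm))
        return sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))


def map_reads(
    reads: Sequence[SmallRNARead],
    index: GenomeIndex,
    max_mismatch: int = 0,
) -> dict[str, list[GenomeHit]]:
    """Map every read; identical sequences are aligned once and shared.

    Returns {read_id: hits}; an empty list means unmapped.
    """
    by_seq: dict[str, list[GenomeHit]] = {}
    out: dict[str, list[GenomeHit]] = {}
    for read in reads:
        if read.seq not in by_seq:
            by_seq[read.seq] = index.map_sequence(read.seq, max_mismatch)
        out[read.read_id] = by_seq[read.seq]
    return out


def mapping_stats(n_input: int, n_ncrna_removed: int, hits: dict[str, list[GenomeHit]]) -> MappingStats:
    n_mapped = sum(1 for h in hits.values() if h)
    n_unmapped = len(hits) - n_mapped
    return MappingStats(n_input, n_ncrna_removed, n_mapped, n_unmapped)
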