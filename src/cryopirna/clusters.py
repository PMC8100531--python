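"""piRNA cluster detection and sequence-level expression quantification.

Clusters are called with a density criterion in the spirit of the standard
piRNA cluster finders: mapped-read 5′ ends on one chromosome are scanned in
sorted order and merged into maximal runs in which consecutive 5′ ends are
at most ``max_gap`` apart.  A run is reported as a cluster when it spans at
least ``min_span`` nt, contains at least ``min_members`` distinct piRNA
sequences, and its members show the primary-piRNA fingerprint: a 5′-U
fraction of at least ``min_u1`` and at least ``min_window_frac`` of members
within the 24–32 nt piRNA length window.  Resulting clusters never overlap.

A piRNA's identity is its distinct read sequence.  Expression is quantified
as TPM-style normalised counts: raw count × 10⁶ / library total, without
per-kilobase scaling (piRNA lengths vary only 24–32 nt; an optional switch
restores per-kilobase scaling).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mapping import GenomeHit


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds of the density criterion (all configurable)."""

    min_members: int = 10
    min_span: int = 1000
    max_gap: int = 1000
    min_u1: float = 0.3
    min_window_frac: float = 0.75
    length_window: tuple[int, int] = (24, 32)


@dataclass
class PiRNACluster:
    """A genomic interval producing many distinct piRNAs at high density."""

    chrom: str
    start: int
    end: int
    member_sequences: set[str] = field(repr=False)
    n_reads: float = 0.0
    u1_fraction: float = 0.0
    length_window_fraction: float = 0.0

    @property
    def n_member_sequences(self) -> int:
        return len(self.member_sequences)

    @property
    def span(self) -> int:
        return self.end - self.start

    def to_bed(self) -> str:
        return (f"{self.chrom}\t{self.start}\t{self.end}\t"
                f"cluster_{self.chrom}_{self.start}\t{self.n_member_sequences}\t+")


# one mapped read occurrence: (hit, read sequence, weight = 1/n_hits)
WeightedHit = tuple[GenomeHit, str, float]


def detect_clusters(
    hits: Sequence[WeightedHit],
    params: ClusterParams = ClusterParams(),
) -> list[PiRNACluster]:
    """Merge sorted hit 5′ ends into gap-bounded runs and threshold them.

    ``hits`` must be sorted by (chrom, start); an unsorted input raises.
    """
    keys = [(h.chrom, h.start) for h, _, _ in hits]
    if keys != sorted(keys):
        raise ValueError("hits must be sorted by (chrom, start)")

    clusters: list[PiRNACluster] = []
    run: list[WeightedHit] = []

    def flush(run: list[WeightedHit]) -> None:
        if not run:
            return
        seqs = {seq for _, seq, _ in run}
        lo, hi = params.length_window
        span_start = min(h.start for h, _, _ in run)
        span_end = max(h.end for h, _, _ in run)
        cluster = PiRNACluster(
            chrom=run[0][0].chrom,
            start=span_start,
            end=span_end,
            member_sequences=seqs,
            n_reads=sum(w for _, _, w in run),
            u1_fraction=sum(1 for s in seqs if s.startswith("T")) / len(seqs),
            length_window_fraction=sum(1 for s in seqs if lo <= len(s) <= hi) / len(seqs),
        )
        if (cluster.span >= params.min_span
                and cluster.n_member_sequences >= params.min_members
                and cluster.u1_fraction >= params.min_u1
                and cluster.length_window_fraction >= params.min_window_frac):
            clusters.append(cluster)

    prev_chrom: str | None = None
    prev_5p: int | None = None
    for item in hits:
        hit = item[0]
        if run and (hit.chrom != prev_chrom or hit.five_prime - prev_5p > params.max_gap):
            flush(run)
            run = []
        run.append(item)
        prev_chrom, prev_5p = hit.chrom, hit.five_prime
    flush(run)
    return clusters


def weight_hits(
    read_hits: Mapping[str, Sequence[GenomeHit]],
    read_seqs: Mapping[str, str],
) -> list[WeightedHit]:
    """Expand a read→hits map into (hit, seq, 1/n_hits) tuples sorted by
    (chrom, start) as :func:`detect_clusters` requires.
    """
    out: list[WeightedHit] = []
    for read_id, hits in read_hits.items():
        if not hits:
            continue
        w = 1.0 / len(hits)
        seq = read_seqs[read_id]
        out.extend((h, seq, w) for h in hits)
    out.sort(key=lambda t: (t[0].chrom, t[0].start))
    return out


def quantify(
    libraries: Mapping[str, Iterable[str]],
    per_kilobase: bool = False,
) -> pd.DataFrame:
    """Sequence-level expression table across libraries.

    ``libraries`` maps library name → iterable of clean piRNA-range read
    sequences.  Returns a DataFrame indexed by piRNA sequence with columns
    ``raw_<lib>`` and ``tpm_<lib>``; each library's TPM column sums to 10⁶.
    Empty libraries are an error.
    """
    counts: dict[str, Counter] = {}
    for lib, seqs in libraries.items():
        c = Counter(seqs)
        if not c:
            raise ValueError(f"library {lib!r} has no reads")
        counts[lib] = c

    all_seqs = sorted(set().union(*counts.values()))
    df = pd.DataFrame(index=pd.Index(all_seqs, name="pirna_seq"))
    for lib, c in counts.items():
        raw = pd.Series({s: c.get(s, 0) for s in all_seqs}, dtype=float)
        abundance = raw / [len(s) / 1000 for s in all_seqs] if per_kilobase else raw
        df[f"raw_{lib}"] = raw
        df[f"tpm_{lib}"] = 1e6 * abundance / abundance.sum()
    return df
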