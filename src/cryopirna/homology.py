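"""Cross-species piRNA homology matching and the common/unique partition.

Two piRNAs from different species are homologous when, anchored at the 5′
end, positions 1–18 are perfectly matched and at most one mismatch occurs
from position 19 to the end of the shorter sequence; the 3′ overhang of the
longer sequence is ignored.  Because positions 1–18 must be identical, the
18-nt 5′ prefix serves as an exact index key, which makes the partition of
two whole DE sets fast while staying equivalent to the all-pairs scan.

A DE piRNA with at least one homolog in the other species' DE set is
"common"; the remainder are the species-unique DE piRNAs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .seqio import normalize_seq

SEED_LEN = 18          # 5' bases that must match perfectly
MAX_TAIL_MISMATCH = 1  # mismatches tolerated from position 19 onward

_VALID = set("ACGT")


def _check(seq: str) -> str:
    s = normalize_seq(seq)
    if not s or set(s) - _VALID:
        raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")
    return s


@dataclass(frozen=True)
class HomologyPair:
    """A matched cross-species piRNA pair with its mismatch profile."""

    seq_a: str
    seq_b: str
    overlap_len: int
    mismatch_positions: tuple[int, ...]  # 1-based, all >= 19

    @property
    def score(self) -> tuple[int, int]:
        """(mismatches, -overlap) — lexicographically smaller is better."""
        return (len(self.mismatch_positions), -self.overlap_len)


def match_pair(seq_a: str, seq_b: str) -> Optional[HomologyPair]:
    """Apply the homology rule to one pair; None when it is not satisfied.

    Sequences shorter than 19 nt cannot satisfy the rule.  U is normalised
    to T; non-ACGT characters raise.
    """
    a, b = _check(seq_a), _check(seq_b)
    overlap = min(len(a), len(b))
    if overlap < SEED_LEN + 1:
        return None
    if a[:SEED_LEN] != b[:SEED_LEN]:
        return None
    mismatches = tuple(i + 1 for i in range(SEED_LEN, overlap) if a[i] != b[i])
    if len(mismatches) > MAX_TAIL_MISMATCH:
        return None
    return HomologyPair(a, b, overlap, mismatches)


def best_pair(query_seq: str, candidates: Iterable[str]) -> Optional[HomologyPair]:
    """Best-matching candidate: fewest mismatches, then longest overlap,
    then lexicographically smallest candidate sequence.  Deterministic;
    None when nothing matches.
    """
    best: Optional[HomologyPair] = None
    for cand in candidates:
        pair = match_pair(query_seq, cand)
        if pair is None:
            continue
        if best is None or (pair.score, pair.seq_b) < (best.score, best.seq_b):
            best = pair
    return best


@dataclass
class PartitionResult:
    """Common/unique partition of two species' DE piRNA sets."""

    common_pairs: list[HomologyPair]
    unique_a: set[str]
    unique_b: set[str]
    matched_a: set[str] = field(default_factory=set)
    matched_b: set[str] = field(default_factory=set)

    @property
    def n_common_a(self) -> int:
        return len(self.matched_a)

    @property
    def n_common_b(self) -> int:
        return len(self.matched_b)


def partition(
    de_set_a: Iterable[str],
    de_set_b: Iterable[str],
    one_to_one: bool = False,
) -> PartitionResult:
    """Partition two deduplicated DE sets into common and unique piRNAs.

    A sequence is common iff :func:`best_pair` finds a homolog in the other
    set (membership-based; a candidate may be the best pair of several
    queries).  With ``one_to_one=True`` each candidate is consumed by the
    first query (in sorted order) that selects it.
    """
    set_a = sorted({_check(s) for s in de_set_a})
    set_b = sorted({_check(s) for s in de_set_b})

    index_b: dict[str, list[str]] = defaultdict(list)
    for s in set_b:
        if len(s) > SEED_LEN:
            index_b[s[:SEED_LEN]].append(s)

    common_pairs: list[HomologyPair] = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    consumed: set[str] = set()
    for a in set_a:
        if len(a) <= SEED_LEN:
            continue
        cands = index_b.get(a[:SEED_LEN], ())
        if one_to_one:
            cands = [c for c in cands if c not in consumed]
        pair = best_pair(a, cands)
        if pair is not None:
            common_pairs.append(pair)
            matched_a.add(a)
            matched_b.add(pair.seq_b)
            consumed.add(pair.seq_b)

    if not one_to_one:
        # symmetric closure: b sequences matching some a are common even if
        # no a selected them as best pair
        index_a: dict[str, list[str]] = defaultdict(list)
        for s in set_a:
            if len(s) > SEED_LEN:
                index_a[s[:SEED_LEN]].append(s)
        for b in set_b:
            if b in matched_b or len(b) <= SEED_LEN:
                continue
            pair = best_pair(b, index_a.get(b[:SEED_LEN], ()))
            if pair is not None:
                matched_b.add(b)
                matched_a.add(pair.seq_b)

    return PartitionResult(
        common_pairs=common_pairs,
        unique_a=set(set_a) - matched_a,
        unique_b=set(set_b) - matched_b,
        matched_a=matched_a,
        matched_b=matched_b,
    )
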