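"""piRNA target prediction and GO/KEGG over-representation analysis.

Target prediction uses an antisense seed-plus-extension rule: a piRNA hits
a transcript when the reverse complement of its seed (positions 2–11,
1-based, the region a PIWI-loaded guide engages first) occurs exactly in
the transcript and the full-length antisense extension carries at most
``max_ext_mismatch`` substitutions.  The rule is a configurable stand-in
for heterogeneous database alignment protocols and is fully specified so
it can be checked against a brute-force scan.

Enrichment of the target gene set is the hypergeometric upper-tail
(over-representation) test per GO term / KEGG pathway, with
Benjamini–Hochberg adjustment applied within each ontology separately.
The universe is the set of annotated transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .seqio import revcomp, normalize_seq


@dataclass(frozen=True)
class TargetHit:
    """Antisense placement of a piRNA on a transcript."""

    pirna_seq: str
    transcript_id: str
    position: int          # 0-based start of the antisense window on the transcript
    ext_mismatches: int


@dataclass(frozen=True)
class TargetParams:
    seed_start: int = 2    # 1-based, inclusive
    seed_end: int = 11     # 1-based, inclusive
    max_ext_mismatch: int = 2


def predict_targets(
    de_pirnas: Iterable[str],
    transcripts: Mapping[str, str],
    params: TargetParams = TargetParams(),
) -> list[TargetHit]:
    """All antisense seed-anchored hits of each piRNA on each transcript.

    The reverse complement of the piRNA's seed must occur exactly; the full
    reverse complement of the piRNA must then fit inside the transcript
    with at most ``max_ext_mismatch`` substitutions outside the seed.
    """
    hits: list[TargetHit] = []
    s0, s1 = params.seed_start - 1, params.seed_end  # python slice of the seed
    for pirna in de_pirnas:
        p = normalize_seq(pirna)
        L = len(p)
        if L < s1:
            continue
        rc = revcomp(p)
        # piRNA positions [s0, s1) map to rc positions [L - s1, L - s0)
        rc_seed = rc[L - s1:L - s0]
        rc_seed_off = L - s1
        for tid, tseq in transcripts.items():
            t = normalize_seq(tseq)
            start = t.find(rc_seed)
            while start != -1:
                win_start = start - rc_seed_off
                win_end = win_start + L
                if win_start >= 0 and win_end <= len(t):
                    window = t[win_start:win_end]
                    mm = sum(1 for i in range(L)
                             if rc[i] != window[i]
                             and not (rc_seed_off <= i < rc_seed_off + (s1 - s0)))
                    if mm <= params.max_ext_mismatch:
                        hits.append(TargetHit(p, tid, win_start, mm))
                start = t.find(rc_seed, start + 1)
    return hits


@dataclass
class EnrichmentResult:
    """One term's over-representation statistics."""

    term_id: str
    ontology: str
    k: int   # target genes annotated to the term
    n: int   # total target genes
    K: int   # universe genes annotated to the term
    N: int   # universe size
    p: float
    padj: float = float("nan")


def hypergeom_enrich(
    targets: Iterable[str],
    annotation: pd.DataFrame,
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``targets`` per annotated term.

    ``annotation`` needs columns transcript_id, term_id, ontology.  The
    universe defaults to all annotated transcripts; targets outside the
    universe raise.  p = P(X >= k) for X ~ Hypergeom(N, K, n); BH is applied
    within each ontology.
    """
    ann = annotation[["transcript_id", "term_id", "ontology"]].drop_duplicates()
    if universe is None:
        uni = set(ann["transcript_id"])
    else:
        uni = set(universe)
    tset = set(targets)
    missing = tset - uni
    if missing:
        raise ValueError(f"{len(missing)} target gene(s) absent from the universe, "
                         f"e.g. {sorted(missing)[:3]}")
    ann = ann[ann["transcript_id"].isin(uni)]
    N, n = len(uni), len(tset)

    results: list[EnrichmentResult] = []
    for (ontology, term), genes in ann.groupby(["ontology", "term_id"])["transcript_id"]:
        members = set(genes)
        K = len(members)
        if K == 0:
            continue
        k = len(members & tset)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, ontology, k, n, K, N, min(p, 1.0)))

    for ontology in {r.ontology for r in results}:
        group = [r for r in results if r.ontology == ontology]
        adj = bh_adjust([r.p for r in group])
        for r, q in zip(group, adj):
            r.padj = float(q)
    return results


def rank_terms(results: Sequence[EnrichmentResult], top_n: int = 10) -> list[EnrichmentResult]:
    """Top terms by ascending adjusted p, ties by descending k then term id."""
    return sorted(results, key=lambda r: (r.padj, -r.k, r.term_id))[:top_n]


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.ontology, r.term_id, r.k, r.n, r.K, r.N, r.p, r.padj) for r in results],
        columns=["ontology", "term_id", "k", "n", "K", "N", "p", "padj"],
    )
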