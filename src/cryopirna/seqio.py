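"""Thin FASTA/FASTQ helpers built on Biopython's SeqIO.

All sequences are handled as plain uppercase DNA strings (U normalised to
T); qualities are lists of Phred+33 integer scores.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    return {rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (read_id, sequence, phred_scores) from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, normalize_seq(str(rec.seq)), list(rec.letter_annotations["phred_quality"])


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str, list[int]]]) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{''.join(chr(q + 33) for q in qual)}\n")
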