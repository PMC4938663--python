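"""FASTA/FASTQ input and output.

Reading goes through Bio.SeqIO; writing is plain text formatting (60-column
FASTA wrap, constant 'I' FASTQ qualities as produced by the simulator).
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO

FASTA_WRAP = 60
FASTQ_QUAL_CHAR = "I"


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate reference name {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no sequences found in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def read_reads(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTA or FASTQ file (sniffed)."""
    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(path, fmt):
        yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant qualities."""
    with open(path, "w") as fh:
        chunk: list[str] = []
        for rid, seq in reads:
            chunk.append(f"@{rid}\n{seq}\n+\n{FASTQ_QUAL_CHAR * len(seq)}\n")
            if len(chunk) >= 10000:
                fh.write("".join(chunk))
                chunk.clear()
        fh.write("".join(chunk))
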