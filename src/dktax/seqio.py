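"""Thin FASTA/FASTQ plumbing over Biopython, gzip-transparent."""

from __future__ import annotations

import gzip
import os
from contextlib import contextmanager

from Bio import SeqIO


@contextmanager
def open_text(path: str, mode: str = "rt"):
    opener = gzip.open if str(path).endswith(".gz") else open
    fh = opener(path, mode)
    try:
        yield fh
    finally:
        fh.close()


def sniff_format(path: str) -> str:
    """'fasta' or 'fastq', by extension then by first byte."""
    base = str(path)
    if base.endswith(".gz"):
        base = base[:-3]
    ext = os.path.splitext(base)[1].lower()
    if ext in {".fq", ".fastq"}:
        return "fastq"
    if ext in {".fa", ".fasta", ".fna", ".ffn"}:
        return "fasta"
    with open_text(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def read_sequences(path: str):
    """Yield (id, sequence-string) from a FASTA/FASTQ file; the ID is the
    first whitespace-delimited header token (SeqIO's convention)."""
    fmt = sniff_format(path)
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq)


def read_fasta_paths(paths) -> dict[str, str]:
    genomes: dict[str, str] = {}
    for path in paths:
        for seq_id, seq in read_sequences(path):
            genomes[seq_id] = seq
    return genomes


def collect_fasta_inputs(path: str) -> list[str]:
    """Expand a file or directory argument into FASTA file paths."""
    if os.path.isdir(path):
        exts = (".fa", ".fasta", ".fna", ".ffn", ".fa.gz", ".fasta.gz", ".fna.gz")
        return sorted(
            os.path.join(path, f) for f in os.listdir(path) if f.endswith(exts)
        )
    return [path]


def write_fasta(records, path: str) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(records, path: str, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f"@{seq_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
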