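"""FASTA/FASTQ reading and writing (Biopython-backed, 60-column FASTA)."""

from __future__ import annotations

import os
from typing import Dict, Iterable, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_WRAP = 60


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict.

    Duplicate ids raise ``ValueError`` (downstream stages key on ids).
    """
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | os.PathLike, seqs: Iterable[Tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


def read_fastx(path: str | os.PathLike) -> Dict[str, str]:
    """Read FASTA or FASTQ (by extension; falls back to sniffing '>' vs '@')."""
    p = str(path)
    if p.endswith((".fq", ".fastq")):
        fmt = "fastq"
    elif p.endswith((".fa", ".fasta", ".fna")):
        fmt = "fasta"
    else:
        with open(p) as fh:
            first = fh.read(1)
        fmt = "fastq" if first == "@" else "fasta"
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(p, fmt):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fastq(path: str | os.PathLike, reads: Iterable[Tuple[str, str]], qual_char: str = "I") -> None:
    """Write reads with a constant placeholder quality (standard 4-line dialect)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")
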