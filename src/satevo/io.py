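"""Thin FASTA/FASTQ helpers built on Biopython's SeqIO."""
from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, sequence, quality-string) triples as Sanger FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out
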