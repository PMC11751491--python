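"""Sequence I/O: FASTA/FASTQ streaming (plain or gzipped), format
autodetected from the first record byte."""

from __future__ import annotations

import gzip
from typing import IO, Iterable, Iterator

from Bio import SeqIO

__all__ = ["read_sequences", "write_fasta", "write_fastq"]


def _open_text(path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path) -> Iterator[tuple[str, str]]:
    """Stream ``(name, sequence)`` from a FASTA or FASTQ file (gzip ok).

    Multi-line FASTA is supported.  Malformed input raises ``ValueError``
    naming the offending line.
    """
    fh = _open_text(path)
    try:
        first = fh.read(1)
        if not first:
            return
        fh.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(
                f"{path}: line 1: expected '>' (FASTA) or '@' (FASTQ), got {first!r}"
            )
        if fmt == "fastq":
            # SeqIO's FASTQ parser reports structural errors; add line context
            line_no = 0
            try:
                for rec in SeqIO.parse(fh, fmt):
                    line_no += 4
                    yield rec.id, str(rec.seq)
            except ValueError as exc:
                raise ValueError(f"{path}: near line {line_no + 1}: {exc}") from exc
        else:
            for rec in SeqIO.parse(fh, fmt):
                yield rec.id, str(rec.seq)
    finally:
        fh.close()


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with open(path, "wt") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str]], path, quality: str = "I") -> None:
    with open(path, "wt") as out:
        for name, seq in records:
            out.write(f"@{name}\n{seq}\n+\n{quality * len(seq)}\n")
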