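"""Tolerant FASTA reading/writing and the assembly cleaning protocol.

The cleaning step mirrors the usual preprocessing applied before k-mer
extraction and byte-level storage comparisons: sequences are uppercased
and split at every unknown nucleotide, short fragments are dropped
(default threshold 18 bp), and the survivors are renamed to sequential
integers. Output FASTA is one sequence per line by default so that
whole-file byte accounting is reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from io import StringIO
from typing import Iterable

from .kmers import segments_of
from .represent import Representation

__all__ = [
    "SequenceRecord",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "format_fasta",
    "clean_records",
    "records_of",
]


@dataclass
class SequenceRecord:
    name: str
    sequence: str


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Parse a FASTA file tolerantly (multi-line sequences, CRLF endings,
    trailing whitespace, blank lines). An empty file yields an empty list;
    sequence data before the first header is an error naming the line."""
    records: list[SequenceRecord] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(SequenceRecord(name, "".join(chunks)))
                name = line[1:].strip()
                if not name:
                    raise FastaParseError(
                        f"{path}: line {lineno}: empty FASTA header"
                    )
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before any "
                        "'>' header"
                    )
                chunks.append(line)
    if name is not None:
        records.append(SequenceRecord(name, "".join(chunks)))
    return records


def format_fasta(records: Iterable[SequenceRecord], line_width: int = 0) -> str:
    """Render records as FASTA text; line_width = 0 leaves sequences
    unwrapped (one line each)."""
    out = StringIO()
    for rec in records:
        out.write(f">{rec.name}\n")
        seq = rec.sequence
        if line_width and line_width > 0:
            for i in range(0, len(seq), line_width):
                out.write(seq[i : i + line_width] + "\n")
            if not seq:
                out.write("\n")
        else:
            out.write(seq + "\n")
    return out.getvalue()


def write_fasta(
    records: Iterable[SequenceRecord], path: str | os.PathLike, line_width: int = 0
) -> None:
    with open(path, "w") as fh:
        fh.write(format_fasta(records, line_width=line_width))


def clean_records(
    records: Iterable[SequenceRecord], min_length: int = 18
) -> list[SequenceRecord]:
    """Split each record at non-ACGT characters, drop segments shorter
    than ``min_length``, uppercase, and rename survivors "1", "2", ..."""
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    cleaned: list[SequenceRecord] = []
    counter = 0
    for rec in records:
        for seg in segments_of(rec.sequence):
            if len(seg) >= min_length:
                counter += 1
                cleaned.append(SequenceRecord(str(counter), seg))
    return cleaned


def records_of(rep: Representation, descriptive: bool = False) -> list[SequenceRecord]:
    """Turn a representation into FASTA records with sequential integer
    headers (or descriptive kind/k/index headers on request)."""
    if descriptive:
        return [
            SequenceRecord(f"{rep.kind}_k{rep.k}_{i}", seq)
            for i, seq in enumerate(rep.sequences, start=1)
        ]
    return [
        SequenceRecord(str(i), seq)
        for i, seq in enumerate(rep.sequences, start=1)
    ]
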