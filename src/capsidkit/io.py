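"""Readers and writers for genome-length inputs (FASTA and tabular)."""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .predictor import GenomeRecord, TAssignment, assignments_to_dataframe


class ParseError(ValueError):
    pass


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta_lengths(path, source: str = "isolate") -> list[GenomeRecord]:
    """One record per FASTA sequence; length = residue count (ambiguity codes
    included, dsDNA assumed so one residue = 1 bp); id = header word."""
    with _open_text(path) as handle:
        text = handle.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ParseError(f"{path}: line {lineno}: expected a FASTA header, got {line[:40]!r}")
        break
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: sequence {rec.id!r} is empty")
        records.append(GenomeRecord(id=rec.id, length_bp=len(rec.seq), source=source))
    return records


_ID_NAMES = {"id", "name", "accession", "contig", "genome", "identifier"}
_LEN_NAMES = {"length", "length_bp", "genome_length", "genome_length_bp", "bp", "size"}


def read_length_table(path, source: str = "isolate") -> list[GenomeRecord]:
    """Read a two-column (id, genome length in bp) TSV/CSV table.

    A header row is auto-detected; duplicate identifiers and non-numeric
    lengths are rejected with the offending id / row named.
    """
    path = Path(path)
    with _open_text(path) as handle:
        text = handle.read()
    if not text.strip():
        return []
    first = text.splitlines()[0]
    sep = "\t" if "\t" in first else ","
    fields = [f.strip().lower() for f in first.split(sep)]
    has_header = any(f in _ID_NAMES for f in fields) or any(f in _LEN_NAMES for f in fields)
    frame = pd.read_csv(_io.StringIO(text), sep=sep, header=0 if has_header else None, dtype=str)
    if has_header:
        id_col = next((c for c in frame.columns if str(c).strip().lower() in _ID_NAMES), frame.columns[0])
        len_col = next(
            (c for c in frame.columns if str(c).strip().lower() in _LEN_NAMES), frame.columns[1]
        )
    else:
        id_col, len_col = frame.columns[0], frame.columns[1]
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    ids = frame[id_col].astype(str).tolist()
    raw_lengths = frame[len_col].tolist()
    for i, (ident, raw_len) in enumerate(zip(ids, raw_lengths), start=2 if has_header else 1):
        try:
            length = int(float(raw_len))
        except (TypeError, ValueError):
            raise ParseError(f"{path}: row {i}: non-numeric genome length {raw_len!r}") from None
        if ident in seen:
            raise ParseError(f"{path}: duplicate genome identifier {ident!r}")
        seen.add(ident)
        records.append(GenomeRecord(id=ident, length_bp=length, source=source))
    return records


def read_genomes(path, source: str = "isolate") -> list[GenomeRecord]:
    """Dispatch on file content: FASTA if the first line is a header, else table."""
    with _open_text(path) as handle:
        for line in handle:
            if line.strip():
                return (
                    read_fasta_lengths(path, source)
                    if line.startswith(">")
                    else read_length_table(path, source)
                )
    return []


def write_length_table(records: Sequence[GenomeRecord], path) -> None:
    frame = pd.DataFrame(
        [{"id": r.id, "length_bp": r.length_bp, "source": r.source} for r in records]
    )
    frame.to_csv(path, sep="\t", index=False)


def write_assignments(assignments: Sequence[TAssignment], path) -> None:
    assignments_to_dataframe(assignments).to_csv(path, index=False)
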