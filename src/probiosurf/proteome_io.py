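"""Protein FASTA input/output and tabular result writing.

Sequences are stored upper-cased with a trailing stop codon ``*`` stripped;
an internal ``*`` is rejected so truncated ORFs are never silently scored.
The record id is the FASTA header token before the first whitespace.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

# 20 canonical residues plus the ambiguity/rare letters tolerated on input.
CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
TOLERATED = CANONICAL | set("XBZU")


class FastaFormatError(ValueError):
    """Raised for files that are not parseable protein FASTA."""


class ProteomeValidationError(ValueError):
    """Raised for structurally valid FASTA whose content breaks an invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence: the unit of proteome analysis."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ProteomeValidationError("protein id must be nonempty")
        if len(self.sequence) < 1:
            raise ProteomeValidationError(f"{self.id}: empty sequence")
        if not set(self.sequence) <= TOLERATED:
            for pos, ch in enumerate(self.sequence, start=1):
                if ch not in TOLERATED:
                    raise ProteomeValidationError(
                        f"{self.id}: illegal residue {ch!r} at position {pos}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """Ordered, id-unique collection of protein records."""

    records: list[ProteinRecord]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ProteomeValidationError("proteome must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ProteomeValidationError(f"duplicate protein id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _normalize_sequence(record_id: str, raw: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        pos = seq.index("*") + 1
        raise ProteomeValidationError(
            f"{record_id}: internal stop '*' at position {pos} (truncated ORF?)"
        )
    return seq


def read_fasta(path: str | Path, source_label: str | None = None) -> Proteome:
    """Read a protein multi-FASTA into a :class:`Proteome`.

    Sequences are upper-cased and a single trailing ``*`` is stripped; the id
    is the header token before the first whitespace. Raises
    :class:`FastaFormatError` for empty/non-FASTA files and
    :class:`ProteomeValidationError` for duplicate ids or illegal residues.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            raise FastaFormatError(f"{path}: empty file")
        if first != ">":
            raise FastaFormatError(f"{path}: not FASTA (no '>' header)")
        handle.seek(0)
        for title, raw_seq in SimpleFastaParser(handle):
            tokens = title.split(None, 1)
            if not tokens:
                raise FastaFormatError(f"{path}: record with empty header")
            rec_id = tokens[0]
            description = tokens[1] if len(tokens) > 1 else ""
            seq = _normalize_sequence(rec_id, raw_seq.replace(" ", ""))
            records.append(ProteinRecord(id=rec_id, sequence=seq, description=description))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records")
    return Proteome(records=records, source_label=source_label or path.name)


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> Path:
    """Write a proteome back to FASTA, wrapping sequences at ``width``."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in proteome:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")
    return path


def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
) -> Path:
    """Write homogeneous mapping rows as TSV or JSON with deterministic column order.

    Column order is ``columns`` if given, else sorted keys. Heterogeneous key
    sets raise ``ValueError`` naming the first offending row.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown table format {format!r}")
    path = Path(path)
    rows = list(rows)
    if rows:
        keys = set(rows[0].keys())
        for i, row in enumerate(rows):
            if set(row.keys()) != keys:
                raise ValueError(f"row {i} has keys {sorted(row.keys())}, expected {sorted(keys)}")
        cols = list(columns) if columns is not None else sorted(keys)
    else:
        cols = list(columns) if columns is not None else []
    if format == "json":
        payload = [{c: row[c] for c in cols} for row in rows]
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for row in rows:
            writer.writerow([row[c] for c in cols])
    return path


def read_table(path: str | Path, format: str = "tsv") -> list[dict[str, str]]:
    """Read a table written by :func:`write_table` (values as strings for TSV)."""
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text())
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        return [dict(row) for row in reader]
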