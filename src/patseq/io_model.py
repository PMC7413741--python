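"""Domain types and readers/writers for reads, transcript databases, gene sets
and the tail-call record table.

Sequence I/O is delegated to Biopython's :mod:`Bio.SeqIO`; this module adds
the validation layer (alphabet, id uniqueness, record invariants) and the
flat-file conventions used throughout the pipeline.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from Bio import SeqIO

__all__ = [
    "ParseError",
    "CCSRead",
    "Transcript",
    "TranscriptDB",
    "GeneSet",
    "TailRecord",
    "DEFAULT_MITO_DENYLIST",
    "TAIL_TABLE_COLUMNS",
    "read_sequences",
    "write_fasta",
    "load_transcript_db",
    "write_transcript_fasta",
    "load_gene_sets",
    "write_tail_table",
    "read_tail_table",
]

VALID_BASES = frozenset("ACGTN")

#: Mammalian mitochondrion-encoded mRNA gene symbols; used as the default
#: denylist when flagging mitochondrial transcripts.
DEFAULT_MITO_DENYLIST = frozenset(
    {
        "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5",
        "MT-ND6", "MT-CYB", "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6",
        "MT-ATP8",
    }
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _validate_sequence(seq: str, context: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ParseError(f"{context}: empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ParseError(f"{context}: invalid characters {sorted(bad)!r}")
    return seq


@dataclass(frozen=True)
class CCSRead:
    """One single-molecule consensus read."""

    read_id: str
    sequence: str
    num_passes: Optional[int] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _validate_sequence(self.sequence, f"read {self.read_id!r}")
        )
        if not self.read_id:
            raise ParseError("read with empty id")
        if self.num_passes is not None and self.num_passes < 0:
            raise ParseError(f"read {self.read_id!r}: negative num_passes")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    sequence: str
    gene_id: str
    gene_symbol: str
    is_mitochondrial: bool = False


class TranscriptDB:
    """Transcript sequences keyed by id, with a gene -> transcripts index."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.entries: dict[str, Transcript] = {}
        self.gene_index: dict[str, list[str]] = {}
        for tx in transcripts:
            if tx.transcript_id in self.entries:
                raise ParseError(f"duplicate transcript id {tx.transcript_id!r}")
            _validate_sequence(tx.sequence, f"transcript {tx.transcript_id!r}")
            self.entries[tx.transcript_id] = tx
            self.gene_index.setdefault(tx.gene_id, []).append(tx.transcript_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.entries.values())

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self.entries[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.entries

    def mitochondrial_genes(self) -> frozenset[str]:
        return frozenset(tx.gene_id for tx in self if tx.is_mitochondrial)


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ParseError("gene set with empty name")
        if not self.gene_ids:
            raise ParseError(f"gene set {self.name!r} is empty")


ORIENTATIONS = ("forward", "reverse")

TAIL_TABLE_COLUMNS = (
    "read_id",
    "transcript_id",
    "gene_id",
    "pat_length",
    "n_disruptions",
    "orientation",
    "score",
    "condition",
    "timepoint_min",
)


@dataclass(frozen=True)
class TailRecord:
    """One accepted (read, transcript) tail call, as stored in the tail table."""

    read_id: str
    transcript_id: str
    gene_id: str
    pat_length: int
    n_disruptions: int
    orientation: str
    score: float
    condition: str = ""
    timepoint_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pat_length < 1:
            raise ParseError(f"record {self.read_id!r}: pat_length must be >= 1")
        if self.n_disruptions < 0:
            raise ParseError(f"record {self.read_id!r}: negative n_disruptions")
        if self.n_disruptions >= self.pat_length:
            raise ParseError(
                f"record {self.read_id!r}: n_disruptions must be < pat_length"
            )
        if self.orientation not in ORIENTATIONS:
            raise ParseError(
                f"record {self.read_id!r}: orientation must be one of {ORIENTATIONS}"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    raise ParseError(f"cannot infer sequence format from {path.name!r}")


def read_sequences(path, format: Optional[str] = None) -> list[CCSRead]:
    """Read CCS-style reads from FASTA or FASTQ.

    Qualities in FASTQ are discarded (Biopython enforces that their length
    matches the sequence). Record order is preserved; lowercase bases are
    upper-cased; duplicate ids are rejected.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in {"fasta", "fastq"}:
        raise ParseError(f"unsupported format {fmt!r}")
    reads: list[CCSRead] = []
    seen: set[str] = set()
    with open(path) as handle:
        parser = SeqIO.parse(handle, fmt)
        index = 0
        while True:
            try:
                record = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(f"{path.name}: record {index}: {exc}") from exc
            if record.id in seen:
                raise ParseError(f"{path.name}: record {index}: duplicate id {record.id!r}")
            seen.add(record.id)
            try:
                reads.append(CCSRead(record.id, str(record.seq), source=path.name))
            except ParseError as exc:
                raise ParseError(f"{path.name}: record {index}: {exc}") from exc
            index += 1
    return reads


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    """Write (header, sequence) pairs as FASTA with fixed line wrapping."""
    with open(path, "w") as handle:
        for header, seq in records:
            handle.write(f">{header}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _parse_transcript_header(header: str) -> tuple[str, str, str]:
    """Split a FASTA header into (transcript_id, gene_id, gene_symbol).

    Supports plain ``>id`` headers and GENCODE-style pipe-delimited headers.
    The first pipe field is the transcript id, the second the gene id; the
    symbol is field 6 for full GENCODE headers, field 3 for the short
    ``tid|gid|symbol`` dialect.
    """
    token = header.split()[0] if header.split() else ""
    if not token:
        raise ParseError("FASTA header lacks a transcript id")
    fields = token.split("|")
    transcript_id = fields[0]
    if not transcript_id:
        raise ParseError(f"header {header!r} lacks a transcript id")
    gene_id = fields[1] if len(fields) > 1 and fields[1] else transcript_id
    if len(fields) >= 6 and fields[5]:
        gene_symbol = fields[5]
    elif len(fields) >= 3 and fields[2]:
        gene_symbol = fields[2]
    else:
        gene_symbol = gene_id
    return transcript_id, gene_id, gene_symbol


def load_transcript_db(path, mito_denylist: Optional[Iterable[str]] = None) -> TranscriptDB:
    """Load a transcript FASTA into a :class:`TranscriptDB`.

    ``mito_denylist`` is matched against both gene ids and gene symbols to
    set the per-transcript mitochondrial flag (default: the 13 mammalian
    mitochondrion-encoded mRNA symbols).
    """
    denylist = frozenset(
        DEFAULT_MITO_DENYLIST if mito_denylist is None else mito_denylist
    )
    transcripts = []
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            tid, gid, symbol = _parse_transcript_header(record.description)
            transcripts.append(
                Transcript(
                    transcript_id=tid,
                    sequence=str(record.seq).upper(),
                    gene_id=gid,
                    gene_symbol=symbol,
                    is_mitochondrial=gid in denylist or symbol in denylist,
                )
            )
    return TranscriptDB(transcripts)


def write_transcript_fasta(db: TranscriptDB, path) -> None:
    write_fasta(
        (
            (f"{tx.transcript_id}|{tx.gene_id}|{tx.gene_symbol}", tx.sequence)
            for tx in db
        ),
        path,
    )


def load_gene_sets(path) -> list[GeneSet]:
    """Load a GMT-like file: name, description, then gene ids, tab-separated."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 tab-separated fields")
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if name in names:
                raise ParseError(f"line {lineno}: duplicate gene set name {name!r}")
            names.add(name)
            try:
                sets.append(GeneSet(name=name, gene_ids=genes, description=description))
            except ParseError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return sets


def _format_timepoint(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))


def write_tail_table(records: Iterable[TailRecord], path) -> None:
    """Write tail records as a TSV with the fixed column set.

    Floats are written with ``repr`` so that read(write(x)) == x exactly.
    """
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TAIL_TABLE_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.read_id,
                    rec.transcript_id,
                    rec.gene_id,
                    rec.pat_length,
                    rec.n_disruptions,
                    rec.orientation,
                    repr(float(rec.score)),
                    rec.condition,
                    _format_timepoint(rec.timepoint_min),
                ]
            )


def read_tail_table(path) -> list[TailRecord]:
    records: list[TailRecord] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty tail table") from None
        if tuple(header) != TAIL_TABLE_COLUMNS:
            raise ParseError(
                f"{path}: unexpected columns {header!r}; expected {list(TAIL_TABLE_COLUMNS)}"
            )
        for rowno, row in enumerate(reader, start=2):
            if len(row) != len(TAIL_TABLE_COLUMNS):
                raise ParseError(f"{path}: row {rowno}: wrong field count")
            try:
                records.append(
                    TailRecord(
                        read_id=row[0],
                        transcript_id=row[1],
                        gene_id=row[2],
                        pat_length=int(row[3]),
                        n_disruptions=int(row[4]),
                        orientation=row[5],
                        score=float(row[6]),
                        condition=row[7],
                        timepoint_min=float(row[8]) if row[8] else None,
                    )
                )
            except (ParseError, ValueError) as exc:
                raise ParseError(f"{path}: row {rowno}: {exc}") from exc
    return records
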