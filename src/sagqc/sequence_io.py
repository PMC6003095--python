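"""Core sequence types and readers/writers for the formats the pipeline touches.

FASTA and FASTQ parsing is delegated to Biopython; this module adds the
pipeline's contracts on top: residues are uppercased, IUPAC ambiguity codes
other than A/C/G/T are collapsed to N, and malformed input raises
:class:`ParseError` with a line number where one is known.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence as TypingSequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Sequence",
    "QualRead",
    "Contig",
    "Assembly",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tsv",
    "write_report_tsv",
    "format_scientific",
]

# Anything outside the unambiguous DNA alphabet maps to N after uppercasing.
_AMBIGUITY_TO_N = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVNU-."}
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _clean_residues(raw: str) -> str:
    return raw.upper().translate(_AMBIGUITY_TO_N)


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "Sequence":
        rc = str(Seq(self.residues).reverse_complement())
        return Sequence(id=self.id, residues=rc, description=self.description)


@dataclass(frozen=True)
class QualRead:
    """A read with per-base Phred quality scores (one per residue)."""

    id: str
    residues: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if len(self.quals) != len(self.residues):
            raise ValueError(
                f"read {self.id!r}: {len(self.quals)} qualities for "
                f"{len(self.residues)} residues"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError("Phred scores must be non-negative")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Contig:
    """One assembled contig; ``truth_label`` is set only by the simulator."""

    sequence: Sequence
    truth_label: Optional[str] = None  # {"host", "contaminant"} in synthetic mode

    @property
    def id(self) -> str:
        return self.sequence.id

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """A per-SAG set of contigs with free-form metadata (depth, taxonomy...)."""

    name: str
    contigs: list[Contig] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate contig ids in assembly {self.name!r}: {dupes}")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def contig_ids(self) -> list[str]:
        return [c.id for c in self.contigs]


def _check_fasta_header(path: Path) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {line.strip()[:40]!r}"
                )
            return  # first non-blank line is a header; Biopython takes it from here


def read_fasta(path) -> list[Sequence]:
    """Read a FASTA file into :class:`Sequence` records.

    Blank lines are ignored, residues are uppercased and ambiguity codes
    collapsed to N. The description (text after the first whitespace in the
    header) is stored separately from the id. An empty file yields an empty
    list; a file whose first non-blank line is not a header raises
    :class:`ParseError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fasta_header(path)
    # blank lines are legal in this dialect but not for Biopython's strict parser
    text = "\n".join(l for l in path.read_text().splitlines() if l.strip())
    out: list[Sequence] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(Sequence(id=rec.id, residues=_clean_residues(str(rec.seq)),
                            description=desc))
    return out


def write_fasta(sequences: Iterable[Sequence], path, width: int = 70) -> None:
    """Write sequences as FASTA with a fixed line width."""
    path = Path(path)
    with open(path, "w") as handle:
        for seq in sequences:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                handle.write(seq.residues[i:i + width] + "\n")


def read_fastq(path) -> list[QualRead]:
    """Read 4-line FASTQ records (Phred+33) into :class:`QualRead` records.

    A length mismatch between sequence and quality lines raises
    :class:`ParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[QualRead] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            out.append(QualRead(id=rec.id, residues=_clean_residues(str(rec.seq)),
                                quals=quals))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fastq(reads: Iterable[QualRead], path) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        for read in reads:
            rec = SeqRecord(Seq(read.residues), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = list(read.quals)
            SeqIO.write(rec, handle, "fastq")


def format_scientific(value: Optional[float]) -> str:
    """Render a genome-size estimate with 3 significant digits, e.g. 2.66E+06.

    ``None`` (undefined, completeness 0) renders as ``-``.
    """
    if value is None:
        return "-"
    return f"{value:.2E}"


def write_report_tsv(rows: TypingSequence[Mapping], path,
                     columns: Optional[TypingSequence[str]] = None,
                     formatters: Optional[Mapping] = None) -> None:
    """Write report rows sharing one column schema as a TSV with header.

    ``formatters`` maps column name -> callable applied to each cell of that
    column before writing. Rows with inconsistent schemas raise ValueError.
    With an empty row list, ``columns`` supplies the header to write.
    """
    path = Path(path)
    rows = list(rows)
    if rows:
        schema = tuple(rows[0].keys())
        for i, row in enumerate(rows):
            if tuple(row.keys()) != schema:
                raise ValueError(f"row {i} schema {tuple(row.keys())} differs "
                                 f"from {schema}")
        df = pd.DataFrame(rows, columns=list(schema))
    else:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    if formatters:
        for col, fn in formatters.items():
            if col in df.columns:
                df[col] = df[col].map(fn)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    """Read a tab-separated table with a header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t")
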