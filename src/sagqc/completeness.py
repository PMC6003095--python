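"""Marker-based completeness and genome-size estimation.

Completeness of a SAG assembly is estimated as the recovered fraction f of a
set of ubiquitously conserved single-copy marker genes (35 COG families by
default). Because each marker occurs exactly once per genome, the fraction
of the set found on valid contigs estimates the fraction of the genome that
was recovered, and scaling the valid assembly length by 1/f back-estimates
the genome size: G = L / f. Marker presence is tallied from a best-hit table
(an HMM search against a marker model database in a full deployment; exact
token matching against embedded marker strings in synthetic mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence as TypingSequence

from sagqc.sequence_io import Assembly

__all__ = [
    "MARKER_SET_SIZE",
    "MarkerSet",
    "MarkerHit",
    "CompletenessEstimate",
    "default_marker_set",
    "load_marker_set",
    "scan_marker_tokens",
    "tally_markers",
    "completeness_fraction",
    "estimate_genome_size",
    "estimate_completeness",
]

MARKER_SET_SIZE = 35


@dataclass(frozen=True)
class MarkerSet:
    """An ordered set of single-copy marker identifiers (COG families)."""

    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in set(self.marker_ids)


@dataclass(frozen=True)
class MarkerHit:
    """Best hit of one gene against the marker models."""

    gene_id: str
    contig_id: str
    marker_id: str
    score: float = 0.0


@dataclass(frozen=True)
class CompletenessEstimate:
    """Marker tally, completeness fraction and genome-size estimate.

    ``genome_size_estimate`` is ``None`` (reported as a dash) when no marker
    was recovered: with f = 0 the inverse-fraction formula is undefined.
    """

    present_markers: int
    total_markers: int
    fraction: float
    valid_length: int
    genome_size_estimate: Optional[float]
    duplicated_markers: tuple[str, ...] = ()


def default_marker_set(n: int = MARKER_SET_SIZE) -> MarkerSet:
    """Placeholder marker set with ``n`` named slots.

    Real analyses should load the actual conserved-COG identifiers with
    :func:`load_marker_set`; synthetic runs pair these slots with generated
    marker tokens.
    """
    return MarkerSet(tuple(f"SCG{i:03d}" for i in range(1, n + 1)))


def load_marker_set(path) -> MarkerSet:
    """Load a marker set from a text file, one identifier per line.

    Blank lines and lines starting with '#' are ignored.
    """
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines()
           if line.strip() and not line.lstrip().startswith("#")]
    if not ids:
        raise ValueError(f"{path}: no marker identifiers found")
    return MarkerSet(tuple(ids))


def scan_marker_tokens(assembly: Assembly,
                       token_map: Mapping[str, str]) -> list[MarkerHit]:
    """Exact-substring scan for embedded marker tokens (synthetic-mode mock).

    ``token_map`` maps marker id -> token sequence. Each occurrence of a
    token on a contig yields one hit (gene ids are synthesised). Tokens are
    matched on the given strand only, which is exact for simulator output
    (fragmentation never reverse-complements).
    """
    hits: list[MarkerHit] = []
    g = 0
    for contig in assembly.contigs:
        residues = contig.sequence.residues
        for marker_id, token in token_map.items():
            start = residues.find(token)
            while start != -1:
                g += 1
                hits.append(MarkerHit(gene_id=f"gene{g:05d}",
                                      contig_id=contig.id,
                                      marker_id=marker_id, score=1.0))
                start = residues.find(token, start + 1)
    return hits


def tally_markers(hits: Iterable[MarkerHit], markers: MarkerSet,
                  valid_contig_ids: Optional[TypingSequence[str]] = None
                  ) -> tuple[int, tuple[str, ...]]:
    """Count distinct markers present on valid contigs.

    Presence, not copy number: several genes hitting one marker count once,
    but markers seen more than once are returned as duplicates — a possible
    contamination signal worth a warning. Hits naming a marker id outside
    the set are ignored with a warning. ``valid_contig_ids=None`` counts all
    contigs.
    """
    valid = None if valid_contig_ids is None else set(valid_contig_ids)
    known = set(markers.marker_ids)
    seen: dict[str, int] = {}
    for hit in hits:
        if valid is not None and hit.contig_id not in valid:
            continue
        if hit.marker_id not in known:
            warnings.warn(f"hit {hit.gene_id} references unknown marker "
                          f"{hit.marker_id!r}; ignored", stacklevel=2)
            continue
        seen[hit.marker_id] = seen.get(hit.marker_id, 0) + 1
    duplicated = tuple(sorted(m for m, c in seen.items() if c > 1))
    return len(seen), duplicated


def completeness_fraction(present: int, total: int = MARKER_SET_SIZE) -> float:
    """f = present / total."""
    if not 0 <= present <= total:
        raise ValueError(f"present markers ({present}) must lie in [0, {total}]")
    return present / total


def estimate_genome_size(valid_length: int, fraction: float) -> Optional[float]:
    """G = L / f; undefined (None) when f = 0."""
    if valid_length < 0:
        raise ValueError("valid assembly length cannot be negative")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("completeness fraction must lie in [0, 1]")
    if fraction == 0.0:
        return None
    return valid_length / fraction


def estimate_completeness(hits: Iterable[MarkerHit], markers: MarkerSet,
                          valid_assembly: Assembly) -> CompletenessEstimate:
    """Tally markers on a validated assembly and derive f and G = L/f."""
    ids = valid_assembly.contig_ids()
    present, duplicated = tally_markers(hits, markers, ids)
    f = completeness_fraction(present, len(markers))
    length = valid_assembly.total_length
    return CompletenessEstimate(
        present_markers=present,
        total_markers=len(markers),
        fraction=f,
        valid_length=length,
        genome_size_estimate=estimate_genome_size(length, f),
        duplicated_markers=duplicated,
    )
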