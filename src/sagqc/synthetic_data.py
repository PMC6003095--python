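"""Simulators producing inputs with the statistical structure the QC assumes.

The generators emulate the artifacts each pipeline stage has to cope with:
two-genome contig mixtures with controlled compositional divergence (for
tetranucleotide decontamination), incomplete assemblies at a known genome
fraction ``f`` carrying embedded single-copy marker tokens (for completeness
estimation), Sanger reads with low-quality positions (for trimming), and
log-linear qPCR dilution series with Gaussian Cq noise (for standard-curve
fitting). Every generator is a pure function of its explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence as TypingSequence

import numpy as np

from sagqc.sequence_io import Assembly, Contig, QualRead, Sequence

__all__ = [
    "GenomeModel",
    "TruthTable",
    "make_genome",
    "fragment_genome",
    "make_marker_tokens",
    "embed_markers",
    "mix_contamination",
    "simulate_sanger_read",
    "simulate_qpcr_series",
]

_BASES = np.array(list("ACGT"))
_MIN_CONTIG_LEN = 500  # SAG assemblies are heavily fragmented; shorter pieces are discarded


@dataclass(frozen=True)
class GenomeModel:
    """Compositional model of a genome: iid with a GC content, or order-1 Markov.

    Exactly one of ``gc_content`` and ``transition`` must be given.
    ``transition`` is a 4x4 row-stochastic matrix over (A, C, G, T).
    """

    name: str
    length: int
    gc_content: Optional[float] = None
    transition: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be >= 1")
        if (self.gc_content is None) == (self.transition is None):
            raise ValueError("specify exactly one of gc_content or transition")
        if self.gc_content is not None and not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.transition is not None:
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (4, 4) or np.any(t < 0) or \
                    not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition must be a 4x4 row-stochastic matrix")


@dataclass
class TruthTable:
    """Ground truth emitted alongside a simulated assembly.

    Maps every contig id to its label (host/contaminant), records the true
    genome fraction of the fragmentation, the source interval of each contig
    in its genome (1-based inclusive), and how many marker tokens were
    embedded in the parent genome.
    """

    labels: dict[str, str] = field(default_factory=dict)
    f_true: float = 1.0
    source_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    markers_embedded: int = 0

    def merge(self, other: "TruthTable") -> "TruthTable":
        overlap = set(self.labels) & set(other.labels)
        if overlap:
            raise ValueError(f"contig ids appear in both truth tables: {sorted(overlap)[:5]}")
        return TruthTable(
            labels={**self.labels, **other.labels},
            f_true=self.f_true,
            source_intervals={**self.source_intervals, **other.source_intervals},
            markers_embedded=self.markers_embedded + other.markers_embedded,
        )


def make_genome(model: GenomeModel) -> Sequence:
    """Draw a random genome from a compositional model; deterministic per seed."""
    rng = np.random.default_rng(model.seed)
    if model.gc_content is not None:
        gc = model.gc_content
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        idx = rng.choice(4, size=model.length, p=probs)
    else:
        t = np.asarray(model.transition, dtype=float)
        # start from the chain's stationary distribution
        evals, evecs = np.linalg.eig(t.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat = np.abs(stat) / np.abs(stat).sum()
        idx = np.empty(model.length, dtype=np.int64)
        idx[0] = rng.choice(4, p=stat)
        u = rng.random(model.length)
        cum = np.cumsum(t, axis=1)
        for i in range(1, model.length):
            idx[i] = np.searchsorted(cum[idx[i - 1]], u[i])
    return Sequence(id=model.name, residues="".join(_BASES[idx]))


def fragment_genome(genome: Sequence, f: float, contig_len_mean: int,
                    seed: int, *, min_len: int = _MIN_CONTIG_LEN,
                    sigma: float = 0.5,
                    contig_prefix: Optional[str] = None,
                    label: str = "host") -> tuple[Assembly, TruthTable]:
    """Sample non-overlapping contigs recovering a fraction ``f`` of a genome.

    Contig lengths are lognormal around ``contig_len_mean`` (truncated below
    at ``min_len``); lengths are drawn until their total reaches
    ``f * len(genome)``, so the recovered length overshoots the target by at
    most one contig. Contigs are then placed without overlap by spreading the
    unrecovered residue as random gaps. Source intervals (1-based inclusive)
    are recorded in the returned :class:`TruthTable`.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError("genome fraction f must lie in (0, 1]")
    glen = len(genome.residues)
    rng = np.random.default_rng(seed)
    prefix = contig_prefix if contig_prefix is not None else genome.id
    target = f * glen

    if f == 1.0 and contig_len_mean >= glen:
        # degenerate case: the whole genome comes back as one contig
        cid = f"{prefix}_c0001"
        contig = Contig(Sequence(id=cid, residues=genome.residues), truth_label=label)
        truth = TruthTable(labels={cid: label}, f_true=1.0,
                           source_intervals={cid: (1, glen)})
        return Assembly(name=prefix, contigs=[contig]), truth

    # lognormal with the requested arithmetic mean: mu = ln(mean) - sigma^2/2
    mu = np.log(max(contig_len_mean, min_len + 1)) - sigma ** 2 / 2
    lengths: list[int] = []
    while sum(lengths) < target:
        ln = int(round(rng.lognormal(mu, sigma)))
        ln = max(ln, min_len)
        remaining_genome = glen - sum(lengths)
        ln = min(ln, remaining_genome)
        if ln <= 0:
            break
        lengths.append(ln)
    total = sum(lengths)

    # distribute the slack uniformly into n+1 gaps so contigs never overlap
    slack = glen - total
    n = len(lengths)
    if slack > 0:
        cuts = np.sort(rng.integers(0, slack + 1, size=n))
        gaps = np.diff(np.concatenate(([0], cuts, [slack])))
    else:
        gaps = np.zeros(n + 1, dtype=int)

    contigs: list[Contig] = []
    truth = TruthTable(f_true=f)
    pos = 0
    for i, ln in enumerate(lengths):
        pos += int(gaps[i])
        start, end = pos, pos + ln  # 0-based half-open
        cid = f"{prefix}_c{i + 1:04d}"
        seq = Sequence(id=cid, residues=genome.residues[start:end])
        contigs.append(Contig(sequence=seq, truth_label=label))
        truth.labels[cid] = label
        truth.source_intervals[cid] = (start + 1, end)  # 1-based inclusive
        pos = end
    asm = Assembly(name=prefix, contigs=contigs)
    return asm, truth


def make_marker_tokens(n: int = 35, length: int = 30, seed: int = 0) -> list[str]:
    """Generate ``n`` distinct random DNA tokens to stand in for marker genes.

    At 30 bp a random token has collision probability < 1e-6 against a
    megabase-scale background, which is what makes exact-substring scanning
    a faithful mock of an HMM marker search on synthetic data.
    """
    if length < 25:
        raise ValueError("tokens shorter than 25 bp risk background collisions")
    rng = np.random.default_rng(seed)
    tokens: set[str] = set()
    while len(tokens) < n:
        tokens.add("".join(_BASES[rng.integers(0, 4, size=length)]))
    return sorted(tokens)


def embed_markers(genome: Sequence, marker_tokens: TypingSequence[str],
                  seed: int) -> tuple[Sequence, dict[str, int]]:
    """Insert each marker token exactly once at a uniform random position.

    Returns the augmented genome and a map token -> 1-based start position in
    the augmented coordinates. Raises if a token already occurs in the
    background genome or the tokens are not unique.
    """
    tokens = list(marker_tokens)
    if len(set(tokens)) != len(tokens):
        raise ValueError("marker tokens must be unique")
    for tok in tokens:
        if tok in genome.residues:
            raise ValueError(f"token {tok!r} collides with the background genome")
    if not tokens:
        return genome, {}
    rng = np.random.default_rng(seed)
    insert_at = np.sort(rng.integers(0, len(genome.residues) + 1, size=len(tokens)))
    order = rng.permutation(len(tokens))  # which token goes at which site

    pieces: list[str] = []
    positions: dict[str, int] = {}
    prev = 0
    offset = 0
    for site, which in zip(insert_at, order):
        tok = tokens[which]
        pieces.append(genome.residues[prev:site])
        positions[tok] = int(site) + offset + 1  # 1-based in augmented coords
        pieces.append(tok)
        offset += len(tok)
        prev = int(site)
    pieces.append(genome.residues[prev:])
    return Sequence(id=genome.id, residues="".join(pieces)), positions


def mix_contamination(host: Assembly, contaminant: Assembly,
                      seed: int) -> tuple[Assembly, TruthTable]:
    """Union two assemblies in shuffled contig order, preserving truth labels."""
    host_ids = set(host.contig_ids())
    clash = host_ids & set(contaminant.contig_ids())
    if clash:
        raise ValueError(f"contig id collision between host and contaminant: {sorted(clash)[:5]}")
    rng = np.random.default_rng(seed)
    contigs = (
        [Contig(c.sequence, truth_label=c.truth_label or "host") for c in host.contigs]
        + [Contig(c.sequence, truth_label=c.truth_label or "contaminant")
           for c in contaminant.contigs]
    )
    order = rng.permutation(len(contigs))
    contigs = [contigs[i] for i in order]
    truth = TruthTable(labels={c.id: c.truth_label for c in contigs})
    return Assembly(name=host.name, contigs=contigs), truth


def simulate_sanger_read(length: int, good_quality: int = 30,
                         bad_positions: TypingSequence[int] = (),
                         seed: int = 0, bad_quality: int = 5,
                         read_id: str = "read") -> QualRead:
    """Simulate a Sanger read: uniform quality with dips at given positions.

    ``bad_positions`` are 1-based; each listed base gets ``bad_quality``.
    """
    if length < 1:
        raise ValueError("read length must be >= 1")
    for p in bad_positions:
        if not 1 <= p <= length:
            raise ValueError(f"bad position {p} outside read of length {length}")
    rng = np.random.default_rng(seed)
    residues = "".join(_BASES[rng.integers(0, 4, size=length)])
    quals = [good_quality] * length
    for p in bad_positions:
        quals[p - 1] = bad_quality
    return QualRead(id=read_id, residues=residues, quals=tuple(quals))


def simulate_qpcr_series(copies_list: TypingSequence[float], slope: float,
                         intercept: float, noise_sd: float = 0.0,
                         seed: int = 0) -> list[tuple[float, float]]:
    """Simulate a qPCR dilution series: Cq = intercept + slope*log10(copies) + noise."""
    copies = np.asarray(copies_list, dtype=float)
    if np.any(copies <= 0):
        raise ValueError("template copy numbers must be positive")
    rng = np.random.default_rng(seed)
    cq = intercept + slope * np.log10(copies)
    if noise_sd > 0:
        cq = cq + rng.normal(0.0, noise_sd, size=copies.size)
    return list(zip(copies.tolist(), cq.tolist()))
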