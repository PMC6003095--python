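"""Canonical tetranucleotide frequency profiles and their PCA embedding.

Tetranucleotide composition is a genome signature: 4-mer frequency vectors
of contigs from the same genome cluster together, so outlier contigs in a
low-dimensional embedding of the profiles are candidate contaminants.
Because contigs are unoriented, each 4-mer is folded onto the
lexicographically smaller of itself and its reverse complement, giving
(256 - 16) / 2 + 16 = 136 canonical features.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from sagqc.sequence_io import Assembly, Sequence

__all__ = [
    "TetraProfileMatrix",
    "PCAResult",
    "canonical_kmer_labels",
    "count_kmers",
    "build_profile",
    "pca",
    "N_CANONICAL_TETRAMERS",
    "DEFAULT_MIN_CONTIG_LEN",
]

N_CANONICAL_TETRAMERS = 136
DEFAULT_MIN_CONTIG_LEN = 1000  # shorter contigs give noisy 4-mer frequencies

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _revcomp(kmer: str) -> str:
    return "".join(_COMP[b] for b in reversed(kmer))


def canonical_kmer_labels(k: int = 4) -> list[str]:
    """Sorted canonical k-mer labels (lexicographic min of k-mer and revcomp)."""
    return sorted({min(kmer, _revcomp(kmer))
                   for kmer in ("".join(p) for p in product("ACGT", repeat=k))})


# canonical index tables, built once per k on first use
_TABLES: dict[int, tuple[np.ndarray, list[str]]] = {}


def _canonical_table(k: int) -> tuple[np.ndarray, list[str]]:
    """Map 4**k k-mer codes to dense canonical feature indices."""
    if k in _TABLES:
        return _TABLES[k]
    labels = canonical_kmer_labels(k)
    label_idx = {lab: i for i, lab in enumerate(labels)}
    table = np.empty(4 ** k, dtype=np.int64)
    for code, kmer in enumerate("".join(p) for p in product("ACGT", repeat=k)):
        table[code] = label_idx[min(kmer, _revcomp(kmer))]
    _TABLES[k] = (table, labels)
    return table, labels


def _count_vector(residues: str, k: int, canonical: bool) -> np.ndarray:
    """Counts over all width-k windows free of N, as a dense vector."""
    codes = np.frombuffer(residues.encode(), dtype=np.uint8)
    base = np.full(codes.size, -1, dtype=np.int64)
    for b, i in _BASE_IDX.items():
        base[codes == ord(b)] = i
    n = codes.size - k + 1
    if n <= 0:
        size = len(_canonical_table(k)[1]) if canonical else 4 ** k
        return np.zeros(size, dtype=np.int64)
    window_codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = base[j:j + n]
        valid &= col >= 0
        window_codes = window_codes * 4 + np.where(col >= 0, col, 0)
    window_codes = window_codes[valid]
    if canonical:
        table, labels = _canonical_table(k)
        return np.bincount(table[window_codes], minlength=len(labels))
    return np.bincount(window_codes, minlength=4 ** k)


def count_kmers(seq: Sequence, k: int = 4, canonical: bool = True) -> dict[str, int]:
    """Count k-mers in all sliding windows of width k (step 1).

    Windows containing N are skipped. With ``canonical=True`` counts are
    folded onto the lexicographically smaller of each k-mer and its reverse
    complement. Only k-mers with nonzero counts appear in the result.
    """
    vec = _count_vector(seq.residues.upper(), k, canonical)
    if canonical:
        labels = _canonical_table(k)[1]
    else:
        labels = ["".join(p) for p in product("ACGT", repeat=k)]
    return {labels[i]: int(c) for i, c in enumerate(vec) if c > 0}


@dataclass
class TetraProfileMatrix:
    """Per-contig canonical 4-mer frequency rows (each row sums to 1)."""

    contig_ids: list[str]
    features: list[str]
    values: np.ndarray  # shape (n_contigs, 136)
    skipped: list[str]  # contigs below min_len or with no countable window

    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)


def build_profile(assembly: Assembly, min_len: int = DEFAULT_MIN_CONTIG_LEN,
                  k: int = 4) -> TetraProfileMatrix:
    """Build the tetranucleotide profile matrix of an assembly.

    Contigs shorter than ``min_len`` or without a single N-free window are
    listed as skipped rather than zero-filled. Raises when no contig
    qualifies.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    skipped: list[str] = []
    for contig in assembly.contigs:
        if contig.length < min_len:
            skipped.append(contig.id)
            continue
        counts = _count_vector(contig.sequence.residues, k, canonical=True)
        total = counts.sum()
        if total == 0:
            skipped.append(contig.id)
            continue
        ids.append(contig.id)
        rows.append(counts / total)
    if not rows:
        raise ValueError(
            f"assembly {assembly.name!r}: no contig of length >= {min_len} "
            f"with countable {k}-mer windows ({len(skipped)} skipped)"
        )
    labels = _canonical_table(k)[1]
    return TetraProfileMatrix(contig_ids=ids, features=list(labels),
                              values=np.vstack(rows), skipped=skipped)


@dataclass
class PCAResult:
    """Principal components of a profile matrix (centered, unscaled)."""

    scores: np.ndarray                 # (n_contigs, n_components)
    loadings: np.ndarray               # (n_features, n_components)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(profile: TetraProfileMatrix | np.ndarray, n_components: int,
        scale: bool = False) -> PCAResult:
    """PCA of profile rows: column-centered, optionally unit-variance scaled.

    Frequencies share a common scale, so variance scaling is off by default
    (scaling would inflate the influence of rare k-mers). Components are
    ordered by decreasing explained variance; each loading column is oriented
    so its largest-magnitude entry is positive, making results deterministic.
    """
    x = profile.values if isinstance(profile, TetraProfileMatrix) else np.asarray(profile, float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 profile rows")
    max_comp = min(x.shape[0] - 1, x.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must lie in [1, {max_comp}]")
    if scale:
        sd = x.std(axis=0, ddof=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T.copy()
    # orient each component: largest-|loading| entry positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=model.explained_variance_ratio_.copy())
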