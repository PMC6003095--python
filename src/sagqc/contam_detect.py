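"""Contaminant detection: DBSCAN over the tetranucleotide PCA embedding.

Contigs are embedded by PCA of their canonical 4-mer frequencies and
clustered with DBSCAN (Euclidean metric). The cluster holding the most
assembled sequence (base pairs) is taken as the genome of the sorted cell;
every other cluster and all density-noise points are flagged as candidate
contaminants. Flagged contigs whose gene-level taxonomy calls intersect the
taxonomic range of the main cluster are reclassified as valid — a
composition outlier that annotates like the host genome is more likely an
atypical genomic island than a contaminant.

DBSCAN is implemented here directly (core point: at least ``min_pts``
neighbours within ``eps`` including itself; clusters are maximal
density-connected sets; border points join the first cluster that reaches
them in input order) so its semantics — in particular deterministic border
assignment — are fixed by this module, not by a library version.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from sagqc.sequence_io import Assembly
from sagqc.tetra_profile import DEFAULT_MIN_CONTIG_LEN, build_profile, pca

__all__ = [
    "NOISE",
    "ClusterLabeling",
    "ContamReport",
    "TaxonomyCall",
    "DecontamConfig",
    "dbscan",
    "choose_eps",
    "label_contigs",
    "refine_with_taxonomy",
    "decontaminate",
]

NOISE = -1

VALID = "valid"
CONTAMINANT = "contaminant"
RECLASSIFIED = "reclassified_valid"
UNPROFILED = "unprofiled"


@dataclass
class ClusterLabeling:
    """DBSCAN output: per-point cluster id (dense from 0) or NOISE (-1)."""

    labels: np.ndarray           # shape (n,), int
    core: np.ndarray             # shape (n,), bool
    eps: float
    min_pts: int
    n_components_used: int = 0

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size and self.labels.max() >= 0 else 0


@dataclass
class ContamReport:
    """Per-contig classification with the rationale for each call."""

    status: dict[str, str] = field(default_factory=dict)
    rationale: dict[str, str] = field(default_factory=dict)
    main_cluster_id: Optional[int] = None

    def contigs_with_status(self, *statuses: str) -> list[str]:
        return [c for c, s in self.status.items() if s in statuses]


@dataclass
class TaxonomyCall:
    """Gene-level taxonomy calls aggregated per contig.

    ``genes`` maps gene id -> (contig id, taxon label, score). The classifier
    producing these is pluggable (BLAST against RefSeq in a full deployment,
    a truth-table mock in synthetic mode).
    """

    genes: dict[str, tuple[str, str, float]] = field(default_factory=dict)

    def contig_taxa(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for contig_id, taxon, _score in self.genes.values():
            out.setdefault(contig_id, set()).add(taxon)
        return out


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> ClusterLabeling:
    """Density-based clustering with Euclidean eps-neighbourhoods.

    A point is core when at least ``min_pts`` points (itself included) lie
    within ``eps``. Clusters are grown from core points in input order;
    border points are assigned to the first cluster that reaches them.
    Unreachable non-core points are NOISE.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return ClusterLabeling(labels=np.empty(0, dtype=int),
                               core=np.empty(0, dtype=bool),
                               eps=eps, min_pts=min_pts)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    dist = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])

    labels = np.full(n, NOISE, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        # BFS over density-reachable points, expanding through core points only
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop(0)
            for k in neighbors[j]:
                if labels[k] == NOISE:
                    labels[k] = cluster
                    if core[k]:
                        frontier.append(int(k))
        cluster += 1
    return ClusterLabeling(labels=labels, core=core, eps=eps, min_pts=min_pts)


def choose_eps(points: np.ndarray, min_pts: int,
               knee_ratio: float = 5.0) -> float:
    """Pick eps from the sorted min_pts-nearest-neighbour distance curve.

    The knee is the point of maximum second difference of the sorted
    k-distance curve. When the curve has no pronounced knee (the maximum
    second difference does not exceed ``knee_ratio`` times the median
    absolute second difference), the 90th percentile of the k-distances is
    used instead. The rule is scale-equivariant: scaling the points by c
    scales the chosen eps by c.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n < min_pts + 1:
        raise ValueError(f"need at least {min_pts + 1} points to choose eps")
    dist = squareform(pdist(pts))
    # distance to the min_pts-th nearest neighbour, self excluded
    kdist = np.sort(np.sort(dist, axis=1)[:, min_pts])
    if kdist[-1] == 0:
        raise ValueError("all points are identical; eps is undefined")
    if n >= 3:
        second = np.diff(kdist, n=2)
        abs_second = np.abs(second)
        med = np.median(abs_second)
        if abs_second.size and abs_second.max() > knee_ratio * max(med, 0.0) \
                and abs_second.max() > 0:
            knee_idx = int(np.argmax(second)) + 1
            eps = float(kdist[knee_idx])
            if eps > 0:
                return eps
    eps = float(np.percentile(kdist, 90))
    if eps <= 0:
        eps = float(kdist[kdist > 0][0])
    return eps


def label_contigs(labeling: ClusterLabeling,
                  contig_lengths: Mapping[str, int],
                  contig_ids: TypingSequence[str]) -> ContamReport:
    """Classify profiled contigs: main-cluster members valid, the rest flagged.

    The main cluster is the one holding the largest total base-pair mass
    (ties broken by contig count, then lowest cluster id). All other
    clusters and NOISE points are flagged as contaminants. Raises when every
    point is NOISE — that calls for a parameter review, mirroring the manual
    inspection step of the bench workflow.
    """
    if len(contig_ids) != labeling.labels.size:
        raise ValueError("labeling does not cover the contig list")
    if labeling.n_clusters == 0:
        raise ValueError(
            "DBSCAN labelled every contig as noise; review eps/min_pts "
            "(or inspect the PCA scores) before classification"
        )
    mass: dict[int, int] = {}
    count: dict[int, int] = {}
    for cid, lab in zip(contig_ids, labeling.labels):
        if lab == NOISE:
            continue
        mass[lab] = mass.get(lab, 0) + contig_lengths[cid]
        count[lab] = count.get(lab, 0) + 1
    main = max(mass, key=lambda c: (mass[c], count[c], -c))
    report = ContamReport(main_cluster_id=int(main))
    for cid, lab in zip(contig_ids, labeling.labels):
        if lab == main:
            report.status[cid] = VALID
            report.rationale[cid] = f"main_cluster_{main}"
        elif lab == NOISE:
            report.status[cid] = CONTAMINANT
            report.rationale[cid] = "density_noise"
        else:
            report.status[cid] = CONTAMINANT
            report.rationale[cid] = f"minor_cluster_{lab}"
    return report


def refine_with_taxonomy(report: ContamReport, calls: TaxonomyCall,
                         main_range: set[str]) -> ContamReport:
    """Reclassify flagged contigs whose taxonomy matches the main cluster.

    A flagged contig whose aggregated gene-level taxa intersect
    ``main_range`` becomes ``reclassified_valid``. Contigs with no calls keep
    contaminant status with rationale ``no_taxonomy``. Valid contigs are
    never demoted.
    """
    taxa_by_contig = calls.contig_taxa()
    refined = ContamReport(status=dict(report.status),
                           rationale=dict(report.rationale),
                           main_cluster_id=report.main_cluster_id)
    for cid, status in report.status.items():
        if status != CONTAMINANT:
            continue
        taxa = taxa_by_contig.get(cid)
        if taxa is None:
            refined.rationale[cid] = refined.rationale[cid] + ";no_taxonomy"
        elif taxa & main_range:
            refined.status[cid] = RECLASSIFIED
            refined.rationale[cid] = (
                refined.rationale[cid] + ";taxonomy_matches_main_range"
            )
        else:
            refined.rationale[cid] = refined.rationale[cid] + ";taxonomy_disjoint"
    return refined


@dataclass
class DecontamConfig:
    """Parameters of the decontamination stage."""

    n_components: int = 3          # PCA dimensions fed to DBSCAN
    eps: Optional[float] = None    # None -> choose_eps heuristic
    min_pts: int = 4               # ~2x embedding dimension rule of thumb
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN
    keep_unprofiled: bool = True   # short contigs kept valid-with-warning
    taxonomy: Optional[TaxonomyCall] = None
    main_range: Optional[set[str]] = None  # None -> taxa of main-cluster contigs


def decontaminate(assembly: Assembly,
                  config: Optional[DecontamConfig] = None
                  ) -> tuple[Assembly, ContamReport, dict]:
    """Full decontamination: profile -> PCA -> DBSCAN -> classify -> refine.

    Returns the validated assembly (valid + reclassified contigs, plus
    unprofiled short contigs when the keep policy says so), the per-contig
    report, and a diagnostics dict with the PCA scores and cluster labels
    for optional manual inspection.
    """
    config = config or DecontamConfig()
    try:
        profile = build_profile(assembly, min_len=config.min_contig_len)
    except ValueError as exc:
        raise ValueError(f"[profile] {exc}") from exc

    n_comp = min(config.n_components, profile.n_contigs - 1,
                 len(profile.features))
    if n_comp < 1:
        raise ValueError(
            f"[pca] assembly {assembly.name!r} has {profile.n_contigs} "
            f"profiled contig(s); need at least 2 to embed"
        )
    embedding = pca(profile, n_components=n_comp)
    points = embedding.scores

    try:
        eps = config.eps if config.eps is not None else choose_eps(points, config.min_pts)
        labeling = dbscan(points, eps=eps, min_pts=config.min_pts)
    except ValueError as exc:
        raise ValueError(f"[dbscan] {exc}") from exc
    labeling.n_components_used = n_comp

    lengths = {c.id: c.length for c in assembly.contigs}
    try:
        report = label_contigs(labeling, lengths, profile.contig_ids)
    except ValueError as exc:
        raise ValueError(f"[classify] {exc}") from exc

    if config.taxonomy is not None:
        if config.main_range is not None:
            main_range = config.main_range
        else:
            taxa_by_contig = config.taxonomy.contig_taxa()
            main_range = set()
            for cid in report.contigs_with_status(VALID):
                main_range |= taxa_by_contig.get(cid, set())
        report = refine_with_taxonomy(report, config.taxonomy, main_range)

    for cid in profile.skipped:
        report.status[cid] = UNPROFILED
        report.rationale[cid] = (
            f"below_min_len_{config.min_contig_len}"
            + (";kept_by_policy" if config.keep_unprofiled else ";dropped_by_policy")
        )

    keep = {VALID, RECLASSIFIED} | ({UNPROFILED} if config.keep_unprofiled else set())
    validated = Assembly(
        name=assembly.name,
        contigs=[c for c in assembly.contigs if report.status.get(c.id) in keep],
        metadata=dict(assembly.metadata),
    )
    diagnostics = {
        "scores": pd.DataFrame(points, index=profile.contig_ids,
                               columns=[f"PC{i + 1}" for i in range(n_comp)]),
        "cluster_labels": pd.Series(labeling.labels, index=profile.contig_ids,
                                    name="cluster"),
        "explained_variance_ratio": embedding.explained_variance_ratio,
        "eps": labeling.eps,
        "min_pts": labeling.min_pts,
        "skipped_contigs": list(profile.skipped),
    }
    return validated, report, diagnostics
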