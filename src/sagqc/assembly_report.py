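"""Assembly statistics, per-SAG report rows, cohort summaries and the pipeline.

N50/L50 follow the standard definition: sort contigs by decreasing length;
L50 is the smallest number of largest contigs whose lengths sum to at least
half the assembly, and N50 is the length of the last contig in that set. The
half-total comparison is done on doubled integers so even totals never hit a
float boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence as TypingSequence

import numpy as np
import pandas as pd

from sagqc import completeness as cmp_mod
from sagqc import contam_detect, sequence_io, synthetic_data
from sagqc.read_screen import ScreeningSummary
from sagqc.sequence_io import Assembly, format_scientific

__all__ = [
    "AssemblyStats",
    "CohortSummary",
    "n50_l50",
    "gc_content",
    "compute_stats",
    "summarize_cohort",
    "load_reference_cohort",
    "run_pipeline",
]


@dataclass(frozen=True)
class AssemblyStats:
    """One report row: the per-SAG statistics of the validated assembly."""

    sag_name: str
    taxonomy: str
    depth_m: Optional[float]
    n_contigs: int
    n50: int
    l50: int
    assembly_size: int
    gc: Optional[float]
    completeness: float
    genome_size_estimate: Optional[float]

    def as_row(self) -> dict:
        return {
            "sag_name": self.sag_name,
            "taxonomy": self.taxonomy,
            "depth_m": self.depth_m,
            "n_contigs": self.n_contigs,
            "n50": self.n50,
            "l50": self.l50,
            "assembly_size": self.assembly_size,
            "gc": None if self.gc is None else round(self.gc, 4),
            "completeness": round(self.completeness, 2),
            "genome_size_estimate": format_scientific(self.genome_size_estimate),
        }


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level means plus the screening success rate."""

    n_sags: int
    mean_n50: int
    mean_l50: float
    screening: Optional[ScreeningSummary] = None


def n50_l50(lengths: TypingSequence[int]) -> tuple[int, int]:
    """N50 and L50 of a set of contig lengths.

    L50 = smallest m such that the m largest contigs cover at least half the
    total length; N50 = length of the m-th largest contig.
    """
    if len(lengths) == 0:
        raise ValueError("cannot compute N50 of an empty assembly")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    acc = 0
    for m, length in enumerate(ordered, start=1):
        acc += length
        if 2 * acc >= total:  # integer arithmetic: acc >= total/2 exactly
            return length, m
    raise AssertionError("unreachable")


def gc_content(assembly_or_lengths) -> Optional[float]:
    """(G+C) / (A+C+G+T) over all contigs; N excluded from the denominator.

    Returns None when the assembly contains no unambiguous base.
    """
    if isinstance(assembly_or_lengths, Assembly):
        seqs = (c.sequence.residues for c in assembly_or_lengths.contigs)
    else:
        seqs = iter(assembly_or_lengths)
    gc = 0
    atgc = 0
    for residues in seqs:
        residues = residues if isinstance(residues, str) else residues.residues
        gc += residues.count("G") + residues.count("C")
        atgc += sum(residues.count(b) for b in "ACGT")
    if atgc == 0:
        return None
    return gc / atgc


def compute_stats(valid_assembly: Assembly,
                  estimate: cmp_mod.CompletenessEstimate) -> AssemblyStats:
    """Assemble the per-SAG report row for one validated assembly."""
    lengths = [c.length for c in valid_assembly.contigs]
    n50, l50 = n50_l50(lengths)
    meta = valid_assembly.metadata
    return AssemblyStats(
        sag_name=valid_assembly.name,
        taxonomy=str(meta.get("taxonomy", "")),
        depth_m=meta.get("depth_m"),
        n_contigs=len(lengths),
        n50=n50,
        l50=l50,
        assembly_size=valid_assembly.total_length,
        gc=gc_content(valid_assembly),
        completeness=estimate.fraction,
        genome_size_estimate=estimate.genome_size_estimate,
    )


def summarize_cohort(stats: TypingSequence[AssemblyStats] | TypingSequence[int],
                     screening: Optional[ScreeningSummary] = None
                     ) -> CohortSummary:
    """Arithmetic means over a cohort; mean N50 rounded to the nearest bp.

    Accepts either report rows or a bare list of N50 values (in which case
    mean_l50 is reported as nan).
    """
    if len(stats) == 0:
        raise ValueError("cannot summarise an empty cohort")
    if isinstance(stats[0], AssemblyStats):
        n50s = [s.n50 for s in stats]
        l50s = [s.l50 for s in stats]
        mean_l50 = float(np.mean(l50s))
    else:
        n50s = list(stats)
        mean_l50 = float("nan")
    return CohortSummary(
        n_sags=len(stats),
        mean_n50=round(float(np.mean(n50s))),
        mean_l50=mean_l50,
        screening=screening,
    )


def load_reference_cohort() -> pd.DataFrame:
    """Published per-SAG statistics of the 20-genome marine reference cohort.

    Columns: sag_name, taxonomy, depth_m, n50, assembly_size, completeness.
    Shipped as package data; used by the worked examples and the
    reproduction script.
    """
    with resources.files("sagqc.data").joinpath("sag_cohort.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# end-to-end pipeline on simulated SAGs


@dataclass
class SyntheticSagSpec:
    """Configuration of one simulated SAG."""

    name: str
    genome_length: int = 200_000
    gc: float = 0.45
    f_true: float = 0.6
    contig_len_mean: int = 8000
    contaminant_gc: Optional[float] = None      # None -> no contamination
    contaminant_contigs: int = 5
    contaminant_contig_len: int = 5000
    taxonomy: str = "synthetic"
    depth_m: float = 250.0


@dataclass
class PipelineConfig:
    """Configuration of a synthetic end-to-end run."""

    sags: list[SyntheticSagSpec] = field(default_factory=list)
    seed: int = 0
    out_dir: Optional[Path] = None
    decontam: contam_detect.DecontamConfig = field(
        default_factory=contam_detect.DecontamConfig)
    n_markers: int = cmp_mod.MARKER_SET_SIZE


def _simulate_sag(spec: SyntheticSagSpec, seed: int,
                  token_map: dict[str, str]
                  ) -> tuple[Assembly, synthetic_data.TruthTable]:
    genome = synthetic_data.make_genome(synthetic_data.GenomeModel(
        name=spec.name, length=spec.genome_length, gc_content=spec.gc,
        seed=seed))
    genome, _ = synthetic_data.embed_markers(genome, list(token_map.values()),
                                             seed=seed + 1)
    host, truth = synthetic_data.fragment_genome(
        genome, f=spec.f_true, contig_len_mean=spec.contig_len_mean,
        seed=seed + 2, contig_prefix=spec.name)
    if spec.contaminant_gc is not None:
        contam_len = spec.contaminant_contigs * spec.contaminant_contig_len
        cgenome = synthetic_data.make_genome(synthetic_data.GenomeModel(
            name=f"{spec.name}.contam", length=contam_len,
            gc_content=spec.contaminant_gc, seed=seed + 3))
        contam, ctruth = synthetic_data.fragment_genome(
            cgenome, f=1.0, contig_len_mean=spec.contaminant_contig_len,
            seed=seed + 4, contig_prefix=f"{spec.name}.contam",
            label="contaminant")
        ctruth.f_true = spec.f_true
        mixed, truth = synthetic_data.mix_contamination(host, contam, seed=seed + 5)
        truth.f_true = spec.f_true
        host = mixed
    host.metadata.update({"taxonomy": spec.taxonomy, "depth_m": spec.depth_m,
                          "f_true": spec.f_true,
                          "true_genome_length": len(genome.residues)})
    return host, truth


def _truth_taxonomy(assembly: Assembly) -> contam_detect.TaxonomyCall:
    """Truth-table taxonomy mock: one call per contig from its true label."""
    calls = contam_detect.TaxonomyCall()
    for i, contig in enumerate(assembly.contigs):
        taxon = "host_taxon" if contig.truth_label != "contaminant" else "other_taxon"
        calls.genes[f"mockgene{i:05d}"] = (contig.id, taxon, 1.0)
    return calls


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, CohortSummary]:
    """Run the post-sequencing QC stages over a cohort of simulated SAGs.

    For each SAG: simulate genome + contamination -> decontaminate ->
    marker-based completeness -> report row. Writes the per-SAG report TSV,
    validated FASTA files and a cohort summary when ``out_dir`` is set.
    Deterministic for a fixed config seed.
    """
    if not config.sags:
        raise ValueError("pipeline config lists no SAGs")
    markers = cmp_mod.default_marker_set(config.n_markers)
    stats_rows: list[AssemblyStats] = []
    for i, spec in enumerate(config.sags):
        sag_seed = config.seed + 1000 * i
        tokens = synthetic_data.make_marker_tokens(
            n=len(markers), seed=sag_seed + 7)
        token_map = dict(zip(markers.marker_ids, tokens))
        try:
            assembly, _truth = _simulate_sag(spec, sag_seed, token_map)
            dconf = contam_detect.DecontamConfig(
                n_components=config.decontam.n_components,
                eps=config.decontam.eps,
                min_pts=config.decontam.min_pts,
                min_contig_len=config.decontam.min_contig_len,
                keep_unprofiled=config.decontam.keep_unprofiled,
                taxonomy=_truth_taxonomy(assembly),
            )
            valid, report, diagnostics = contam_detect.decontaminate(assembly, dconf)
            hits = cmp_mod.scan_marker_tokens(valid, token_map)
            estimate = cmp_mod.estimate_completeness(hits, markers, valid)
            stats = compute_stats(valid, estimate)
        except (ValueError, OSError) as exc:
            raise RuntimeError(f"SAG {spec.name!r}: {exc}") from exc
        stats_rows.append(stats)
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            sequence_io.write_fasta((c.sequence for c in valid.contigs),
                                    out / f"{spec.name}.valid.fasta")
    summary = summarize_cohort(stats_rows)
    table = pd.DataFrame([s.as_row() for s in stats_rows])
    if config.out_dir is not None:
        out = Path(config.out_dir)
        sequence_io.write_report_tsv([s.as_row() for s in stats_rows],
                                     out / "sag_report.tsv")
        pd.Series({
            "n_sags": summary.n_sags,
            "mean_n50": summary.mean_n50,
            "mean_l50": summary.mean_l50,
            "seed": config.seed,
        }).to_json(out / "cohort_summary.json")
    return table, summary
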