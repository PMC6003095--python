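"""Sanger-read quality trimming and qPCR screening of WGA reaction products.

Whole-genome amplification (WGA) reactions are screened by quantitative PCR
of the 16S rRNA gene against a plasmid standard dilution series; reactions
quantifying below a detection limit (default 100 copies/ul) or showing an
anomalous melt temperature are rejected. Sanger reads of the screening
amplicons are trimmed to their longest contiguous stretch of bases with
per-base Phred quality above 10 and mean quality of at least 20; trimmed
reads shorter than 100 bp are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence as TypingSequence

import numpy as np
from scipy import stats

from sagqc.sequence_io import QualRead

__all__ = [
    "TrimResult",
    "QPCRCurve",
    "ScreenResult",
    "ScreeningSummary",
    "trim_by_quality",
    "fit_standard_curve",
    "quantify",
    "screen_reaction",
    "screening_summary",
    "DEFAULT_DETECTION_THRESHOLD",
    "DEFAULT_MELT_MIN",
]

DEFAULT_DETECTION_THRESHOLD = 100.0  # copies/ul
# No universal melt cutoff exists; 78 degC is a typical floor for bacterial
# 16S amplicons in SYBR assays. Always overridable per assay.
DEFAULT_MELT_MIN = 78.0

R_SQUARED_MIN = 0.95


@dataclass(frozen=True)
class TrimResult:
    """Outcome of quality-trimming one read.

    ``kept_interval`` is 1-based inclusive, or None when no base survives.
    A read is discarded when fewer than 100 bp (``len_min``) of high-quality
    sequence remain.
    """

    read_id: str
    kept_interval: Optional[tuple[int, int]]
    kept_length: int
    status: str  # {"kept", "discarded"}


@dataclass(frozen=True)
class QPCRCurve:
    """A fitted qPCR standard curve: Cq = intercept + slope * log10(copies).

    ``efficiency`` is the per-cycle amplification gain, 10**(-1/slope) - 1;
    a perfect doubling per cycle gives slope -3.3219 and efficiency 1.0.
    Curves with R^2 below 0.95 are flagged invalid.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int

    @property
    def valid(self) -> bool:
        return self.slope < 0 and self.r_squared >= R_SQUARED_MIN


@dataclass(frozen=True)
class ScreenResult:
    """Pass/fail decision for one WGA reaction."""

    reaction_id: str
    copies_per_ul: float
    melt_temp: float
    passed: bool
    exclusion_reason: Optional[str] = None  # {low_melt_temp, below_detection, curve_invalid}


class ScreeningSummary(NamedTuple):
    n_attempted: int
    n_passed: int
    percent_passed: Optional[int]


def _quality_runs(quals: TypingSequence[int], q_min: int) -> list[tuple[int, int]]:
    """Maximal runs (0-based half-open) where every base has quality > q_min."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, q in enumerate(quals):
        if q > q_min:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(quals)))
    return runs


def trim_by_quality(read: QualRead, q_min: int = 10, mean_min: float = 20.0,
                    len_min: int = 100) -> TrimResult:
    """Trim a read to its longest contiguous high-quality stretch.

    Among maximal runs in which every base has Phred quality strictly above
    ``q_min``, the longest run whose mean quality is at least ``mean_min`` is
    kept (leftmost on ties). If no such run exists or the selected run is
    shorter than ``len_min``, the read is discarded.
    """
    if len(read) == 0:
        raise ValueError("cannot trim an empty read")
    candidates = [(s, e) for s, e in _quality_runs(read.quals, q_min)
                  if np.mean(read.quals[s:e]) >= mean_min]
    if not candidates:
        return TrimResult(read.id, None, 0, "discarded")
    best = max(candidates, key=lambda se: (se[1] - se[0], -se[0]))
    length = best[1] - best[0]
    interval = (best[0] + 1, best[1])  # 1-based inclusive
    status = "kept" if length >= len_min else "discarded"
    return TrimResult(read.id, interval, length, status)


def fit_standard_curve(points: TypingSequence[tuple[float, float]]) -> QPCRCurve:
    """Fit Cq on log10(copies) by ordinary least squares.

    Requires at least 3 dilution points with positive copy numbers spanning
    more than one concentration. Melt-excluded standards must be removed
    before fitting.
    """
    if len(points) < 3:
        raise ValueError(f"standard curve needs >= 3 dilution points, got {len(points)}")
    copies = np.array([c for c, _ in points], dtype=float)
    cq = np.array([q for _, q in points], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("standard copy numbers must be positive")
    x = np.log10(copies)
    if np.ptp(x) == 0:
        raise ValueError("standards must span more than one concentration")
    fit = stats.linregress(x, cq)
    slope = float(fit.slope)
    r2 = float(fit.rvalue ** 2)
    efficiency = 10.0 ** (-1.0 / slope) - 1.0 if slope != 0 else math.nan
    return QPCRCurve(slope=slope, intercept=float(fit.intercept),
                     r_squared=r2, efficiency=float(efficiency),
                     n_points=len(points))


def quantify(curve: QPCRCurve, cq: float) -> float:
    """Invert a valid standard curve: copies = 10**((Cq - intercept) / slope)."""
    if not curve.valid:
        raise ValueError(
            f"cannot quantify against an invalid curve "
            f"(slope={curve.slope:.3f}, R^2={curve.r_squared:.3f})"
        )
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def screen_reaction(copies: float, melt_temp: float,
                    threshold: float = DEFAULT_DETECTION_THRESHOLD,
                    melt_min: float = DEFAULT_MELT_MIN,
                    reaction_id: str = "") -> ScreenResult:
    """Decide pass/fail for one reaction.

    A reaction passes when its quantified copy number reaches the detection
    threshold (inclusive) and its melt temperature is not anomalously low
    (primer dimers and short artifacts melt early). Melt exclusion takes
    precedence, mirroring the bench practice of discarding dissociation-curve
    failures before reading quantities.
    """
    if copies < 0:
        raise ValueError("copy number cannot be negative")
    if melt_temp < melt_min:
        return ScreenResult(reaction_id, copies, melt_temp, False, "low_melt_temp")
    if copies < threshold:
        return ScreenResult(reaction_id, copies, melt_temp, False, "below_detection")
    return ScreenResult(reaction_id, copies, melt_temp, True, None)


def screening_summary(results: TypingSequence[ScreenResult]) -> ScreeningSummary:
    """Count attempted and passing reactions; percent rounded to nearest integer."""
    n = len(results)
    passed = sum(1 for r in results if r.passed)
    if n == 0:
        return ScreeningSummary(0, 0, None)
    return ScreeningSummary(n, passed, round(100.0 * passed / n))
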