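"""Probe-distribution QC: spacing statistics, outliers, accounting.

Summaries follow array-design convention: spacing is the start-to-start
distance between consecutive probes on a chromosome, so a chromosome
with N probes contributes N-1 intervals and its mean spacing is close to
chromosome span / (N-1).  A genome-wide report adds threshold coverage
fractions and Tukey-style outlier intervals.

The module also ships the published probe-distribution summary of the
110,456-probe feline oaCGH design (``FELINE_ARRAY_TABLE``) and its
migration stage counts (``FELINE_DESIGN_LEDGER``), as reference inputs
for the report arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Probe, ValidationError
from .migration import Ledger

__all__ = [
    "SpacingSummary",
    "GenomeSpacingReport",
    "spacing_summary",
    "outlier_intervals",
    "coverage_fractions",
    "genome_spacing_report",
    "accounting_report",
    "totals_row",
    "FELINE_ARRAY_TABLE",
    "FELINE_DESIGN_LEDGER",
]


@dataclass(frozen=True)
class SpacingSummary:
    """Per-chromosome probe-distribution statistics (all bp)."""

    chromosome: str
    size: int
    probe_count: int
    mean_spacing: float | None
    median_spacing: float | None
    max_spacing: int | None
    probes_per_mb: int

    @property
    def has_spacing(self) -> bool:
        return self.mean_spacing is not None


def _intervals(starts: Sequence[int]) -> np.ndarray:
    return np.diff(np.asarray(starts, dtype=np.int64))


def spacing_summary(
    probes: Sequence[Probe] | Sequence[int], chromosome: str, size: int
) -> SpacingSummary:
    """Spacing statistics for one chromosome's probes.

    Accepts probes (sorted by start) or raw start positions.  Spacing
    fields are None when fewer than two probes are present.
    ``probes_per_mb`` = round(count / (size / 1e6)).
    """
    starts = [
        p.interval.start if isinstance(p, Probe) else int(p) for p in probes
    ]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValidationError(f"{chromosome}: probe starts not strictly increasing")
    count = len(starts)
    probes_per_mb = round(count / (size / 1e6))
    if count < 2:
        return SpacingSummary(chromosome, size, count, None, None, None, probes_per_mb)
    iv = _intervals(starts)
    return SpacingSummary(
        chromosome,
        size,
        count,
        float(iv.mean()),
        float(np.median(iv)),
        int(iv.max()),
        probes_per_mb,
    )


def outlier_intervals(intervals: Sequence[float]) -> list[float]:
    """Intervals strictly greater than Q3 + 1.5*IQR (Tukey upper fence).

    Quartiles use linear interpolation.  Fewer than 4 intervals: no
    meaningful quartiles, returns [] with a warning.
    """
    if len(intervals) < 4:
        warnings.warn("fewer than 4 intervals: outlier fence undefined")
        return []
    arr = np.asarray(intervals, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return [float(x) for x in arr[arr > fence]]


def coverage_fractions(
    intervals: Sequence[float],
    thresholds: Sequence[float] = (50_000, 100_000, 1_000_000),
) -> dict:
    """Fraction of inter-probe intervals strictly below each threshold,
    plus the count strictly above the largest threshold."""
    if len(intervals) == 0:
        raise ValidationError("no intervals")
    arr = np.asarray(intervals, dtype=float)
    fractions = {
        float(t): float((arr < t).mean()) for t in sorted(thresholds)
    }
    largest = max(thresholds)
    return {
        "fractions_below": fractions,
        "count_above_largest": int((arr > largest).sum()),
        "largest_threshold": float(largest),
        "n_intervals": int(arr.size),
    }


@dataclass(frozen=True)
class GenomeSpacingReport:
    per_chromosome: tuple[SpacingSummary, ...]
    total_size: int
    total_probes: int
    mean_spacing_unweighted: float  # mean of per-chromosome mean spacings
    probes_per_mb_unweighted: float  # mean of per-chromosome probes/Mb
    mean_spacing_pooled: float | None  # all intervals pooled genome-wide
    probes_per_mb_pooled: float  # total probes / total Mb
    coverage: dict | None
    outliers: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chromosome": s.chromosome,
                "size_bp": s.size,
                "probes": s.probe_count,
                "mean_spacing_bp": (
                    round(s.mean_spacing) if s.has_spacing else None
                ),
                "median_spacing_bp": (
                    round(s.median_spacing) if s.has_spacing else None
                ),
                "max_spacing_bp": s.max_spacing,
                "probes_per_mb": s.probes_per_mb,
            }
            for s in self.per_chromosome
        ]
        rows.append(
            {
                "chromosome": "Total",
                "size_bp": self.total_size,
                "probes": self.total_probes,
                "mean_spacing_bp": round(self.mean_spacing_unweighted),
                "median_spacing_bp": None,
                "max_spacing_bp": None,
                "probes_per_mb": round(self.probes_per_mb_unweighted),
            }
        )
        return pd.DataFrame(rows)


def totals_row(summaries: Iterable[SpacingSummary]) -> dict:
    """Totals logic over per-chromosome rows.

    Sizes and probe counts are summed; mean spacing and probes/Mb are
    reported two ways: the *unweighted* mean of per-chromosome values
    (the convention of the published design summary — "paper-style"),
    and pooled genome-wide variants.
    """
    rows = list(summaries)
    if not rows:
        raise ValidationError("no chromosome summaries")
    with_spacing = [s for s in rows if s.has_spacing]
    total_size = sum(s.size for s in rows)
    total_probes = sum(s.probe_count for s in rows)
    return {
        "total_size": total_size,
        "total_probes": total_probes,
        "mean_spacing_unweighted": float(
            np.mean([s.mean_spacing for s in with_spacing])
        ),
        "probes_per_mb_unweighted": float(np.mean([s.probes_per_mb for s in rows])),
        "probes_per_mb_pooled": total_probes / (total_size / 1e6),
    }


def genome_spacing_report(
    probes_by_chrom: dict[str, Sequence],
    sizes: dict[str, int],
    thresholds: Sequence[float] = (50_000, 100_000, 1_000_000),
) -> GenomeSpacingReport:
    """Full design-QC report from per-chromosome probe start positions."""
    summaries = []
    all_intervals: list[np.ndarray] = []
    for chrom in sizes:
        probes = probes_by_chrom.get(chrom, [])
        summaries.append(spacing_summary(probes, chrom, sizes[chrom]))
        starts = [
            p.interval.start if isinstance(p, Probe) else int(p) for p in probes
        ]
        if len(starts) >= 2:
            all_intervals.append(_intervals(starts))
    pooled = np.concatenate(all_intervals) if all_intervals else np.array([])
    totals = totals_row(summaries)
    return GenomeSpacingReport(
        per_chromosome=tuple(summaries),
        total_size=totals["total_size"],
        total_probes=totals["total_probes"],
        mean_spacing_unweighted=totals["mean_spacing_unweighted"],
        probes_per_mb_unweighted=totals["probes_per_mb_unweighted"],
        mean_spacing_pooled=float(pooled.mean()) if pooled.size else None,
        probes_per_mb_pooled=totals["probes_per_mb_pooled"],
        coverage=coverage_fractions(pooled, thresholds) if pooled.size else None,
        outliers=tuple(outlier_intervals(pooled)) if pooled.size >= 4 else (),
    )


# ---------------------------------------------------------------------------
# Migration accounting
# ---------------------------------------------------------------------------

def accounting_report(ledger: Ledger) -> dict:
    """Derived percentages and stage arithmetic of a migration ledger.

    The Ledger constructor enforces the stage identities; an
    inconsistent ledger therefore cannot reach this function.  The
    report spells them out: successful alignments = total − failures,
    candidates = exact + direct + adjusted, failed adjustments =
    attempted − adjusted, final probes = candidates − ambiguous.
    """
    return {
        "total_input": ledger.total,
        "no_alignment": ledger.no_alignment,
        "failure_rate_percent": round(100 * ledger.failure_rate),
        "successful_alignments": ledger.successful_alignments,
        "exact_match": ledger.exact_match,
        "direct_ortholog": ledger.direct_ortholog,
        "adjust_attempted": ledger.adjust_attempted,
        "adjusted": ledger.adjusted,
        "failed_adjust": ledger.failed_adjust,
        "candidates": ledger.candidates,
        "ambiguous_map": ledger.ambiguous_map,
        "final_probes": ledger.final_probes,
    }


# ---------------------------------------------------------------------------
# Published reference values: the feline 110k oaCGH design
# ---------------------------------------------------------------------------

#: Published per-chromosome probe distribution of the feline oaCGH array:
#: (chromosome, size bp, probes, mean spacing bp, median spacing bp,
#:  maximum spacing bp, probes/Mb).
FELINE_ARRAY_TABLE: tuple[tuple, ...] = (
    ("A1", 242_100_913, 10_648, 22_664, 17_125, 2_635_625, 44),
    ("A2", 171_471_747, 7_944, 21_469, 15_552, 2_272_323, 46),
    ("A3", 143_202_405, 6_653, 21_434, 16_188, 2_630_398, 46),
    ("B1", 208_212_889, 9_420, 22_001, 16_824, 2_362_299, 45),
    ("B2", 155_302_638, 7_160, 21_603, 16_296, 2_303_124, 46),
    ("B3", 149_751_809, 7_026, 21_173, 15_704, 2_516_731, 47),
    ("B4", 144_528_695, 6_559, 21_942, 16_343, 2_103_152, 45),
    ("C1", 222_790_142, 10_724, 20_646, 15_770, 2_108_648, 48),
    ("C2", 161_193_150, 7_462, 21_511, 16_288, 3_159_135, 46),
    ("D1", 117_648_028, 5_174, 22_610, 16_463, 2_184_516, 44),
    ("D2", 90_186_660, 3_863, 23_132, 16_397, 2_155_220, 43),
    ("D3", 96_884_206, 4_275, 22_564, 16_227, 2_223_652, 44),
    ("D4", 96_521_652, 4_249, 22_622, 16_361, 2_213_074, 44),
    ("E1", 63_494_689, 2_712, 22_955, 15_407, 2_301_848, 43),
    ("E2", 64_340_295, 2_352, 27_026, 18_082, 2_536_363, 37),
    ("E3", 44_648_284, 1_561, 28_241, 17_413, 3_394_005, 35),
    ("F1", 71_664_243, 3_082, 22_498, 16_523, 650_963, 43),
    ("F2", 85_752_456, 4_137, 20_102, 15_601, 333_037, 48),
    ("X", 130_557_009, 5_455, 23_800, 15_598, 2_487_257, 42),
)


def feline_array_summaries() -> list[SpacingSummary]:
    """The published table rows as :class:`SpacingSummary` objects."""
    return [
        SpacingSummary(chrom, size, count, float(mean), float(median), mx, ppm)
        for chrom, size, count, mean, median, mx, ppm in FELINE_ARRAY_TABLE
    ]


#: Published stage counts of the feline design's migration from the
#: 171,534-probe canine template.
FELINE_DESIGN_LEDGER = Ledger(
    total=171_534,
    no_alignment=58_255,
    exact_match=1_512,
    direct_ortholog=83_488,
    adjusted=27_400,
    failed_adjust=879,
    ambiguous_map=1_944,
)
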