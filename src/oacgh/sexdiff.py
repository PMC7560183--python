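"""Sex-mismatch hybridization analysis.

Hybridizing female against male DNA gives a known dosage truth: the X
chromosome carries two copies in the test versus one in the reference
(theoretical log2 = 1) except in the pseudoautosomal region (PAR), which
is shared with Y and stays balanced (log2 = 0), as do all autosomes.
This module summarizes chromosome-level means with optional region
exclusion, locates the PAR boundary as the balanced→gained transition
along X, and reports unexpected autosomal imbalances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cgh import RatioTrack, Segment, Thresholds, segment_track
from .core import GeneAnnotation, GenomicInterval, ValidationError

__all__ = [
    "ParBoundary",
    "chromosome_mean",
    "detect_par_boundary",
    "find_discordant_autosomal_regions",
]


@dataclass(frozen=True)
class ParBoundary:
    """The PAR breakpoint as the open window between flanking probes.

    ``last_balanced_pos`` is the position of the final probe of the
    balanced (pseudoautosomal) head; ``first_unbalanced_pos`` the first
    probe of the sustained gained run; ``window_bp`` their difference —
    the resolution to which probe spacing localizes the transition.
    """

    last_balanced_pos: int
    first_unbalanced_pos: int
    proximal_gene: str | None = None
    distal_gene: str | None = None

    def __post_init__(self) -> None:
        if self.first_unbalanced_pos <= self.last_balanced_pos:
            raise ValidationError("boundary window must have positive size")

    @property
    def window_bp(self) -> int:
        return self.first_unbalanced_pos - self.last_balanced_pos

    @property
    def window(self) -> tuple[int, int]:
        return (self.last_balanced_pos, self.first_unbalanced_pos)


def chromosome_mean(
    track: RatioTrack,
    chrom: str,
    exclude: GenomicInterval | tuple[int, int] | None = None,
) -> float:
    """Arithmetic mean log2 over one chromosome's probes.

    ``exclude`` omits probes inside an interval (e.g. the PAR when
    summarizing the X-specific dosage difference).  Raises when no probe
    survives the exclusion.
    """
    sub = track.chromosome(chrom)
    if len(sub) == 0:
        raise ValidationError(f"chromosome {chrom!r} not in track")
    values = sub["log2"].to_numpy()
    if exclude is not None:
        if isinstance(exclude, GenomicInterval):
            lo, hi = exclude.start, exclude.end
        else:
            lo, hi = exclude
        pos = sub["pos"].to_numpy()
        keep = ~((pos >= lo) & (pos < hi))
        values = values[keep]
    if values.size == 0:
        raise ValidationError(f"no probes on {chrom} after exclusion")
    return float(values.mean())


def autosomal_mean(track: RatioTrack, x_chrom: str = "X") -> float:
    """Mean log2 over every chromosome except the X."""
    sub = track.data[track.data["chrom"] != x_chrom]
    if len(sub) == 0:
        raise ValidationError("no autosomal probes")
    return float(sub["log2"].mean())


def detect_par_boundary(
    track: RatioTrack,
    chrom: str = "X",
    thresholds: Thresholds | None = None,
    k: int | None = None,
    genes: Sequence[GeneAnnotation] | None = None,
    strategy: str = "segment",
) -> ParBoundary:
    """Locate the PAR boundary on a sex-mismatch X-chromosome track.

    The track is read from the p-terminus; the boundary falls between
    the last probe of the initial balanced head and the first probe of
    the first *sustained* gained run — at least ``k`` consecutive probes
    (default: the calling minimum window) at or above the gain
    threshold, so an isolated noise probe in the head cannot trigger it.

    strategy="segment" (default) finds the transition on the segmented
    track, which is robust to per-probe noise; strategy="runs" applies
    the literal consecutive-probe rule to raw values.  Both agree on
    noise-free data.

    Raises "no transition detected" when no sustained gained run exists;
    a track gained from its very first probe yields a degenerate
    boundary at the track start (window from position 0).
    """
    t = thresholds or Thresholds()
    k = t.min_probes if k is None else k
    sub = track.chromosome(chrom)
    if len(sub) == 0:
        raise ValidationError(f"chromosome {chrom!r} not in track")
    pos = sub["pos"].to_numpy()
    values = sub["log2"].to_numpy()

    if strategy == "runs":
        first_idx = _first_sustained_run(values, t.gain, k)
    elif strategy == "segment":
        segs = segment_track(RatioTrack(sub), t)
        first_idx = None
        confirm = max(2 * k, 6)
        for s in segs:
            if s.state not in ("gain", "high_gain") or s.n_probes < k:
                continue
            i0 = s.index[0]
            # sustained: the window following the candidate transition
            # must clear the gain threshold too, so an isolated noise
            # cluster in the balanced head cannot pass as the boundary
            window = values[i0 : i0 + confirm]
            if window.mean() >= t.gain:
                first_idx = i0
                break
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if first_idx is None:
        raise ValidationError("no transition detected on " + chrom)
    if first_idx == 0:
        # gained from the first probe: degenerate boundary at track start
        return _with_genes(ParBoundary(max(int(pos[0]) - 1, 0), int(pos[0])),
                           chrom, genes)

    balanced = np.abs(values[:first_idx]) < t.gain
    if not balanced.any():
        raise ValidationError("no balanced probe precedes the transition")
    last_idx = int(np.nonzero(balanced)[0][-1])
    return _with_genes(
        ParBoundary(int(pos[last_idx]), int(pos[first_idx])), chrom, genes
    )


def _first_sustained_run(values: np.ndarray, gain: float, k: int) -> int | None:
    gained = values >= gain
    run = 0
    for i, g in enumerate(gained):
        run = run + 1 if g else 0
        if run == k:
            return i - k + 1
    return None


def _with_genes(
    boundary: ParBoundary, chrom: str, genes: Sequence[GeneAnnotation] | None
) -> ParBoundary:
    if not genes:
        return boundary
    lo, hi = boundary.window
    proximal = distal = None
    best_prox = best_dist = None
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        if g.interval.start <= lo:
            # nearest gene on or spanning the balanced flank
            d = lo - g.interval.start
            if best_prox is None or d < best_prox:
                best_prox, proximal = d, g.symbol
        else:
            # nearest gene starting beyond the window, on the gained side
            d = g.interval.start - lo
            if best_dist is None or d < best_dist:
                best_dist, distal = d, g.symbol
    return ParBoundary(lo, hi, proximal_gene=proximal, distal_gene=distal)


def find_discordant_autosomal_regions(
    track: RatioTrack,
    thresholds: Thresholds | None = None,
    x_chrom: str = "X",
) -> list[Segment]:
    """Called (non-balanced) segments on the autosomes.

    In a sex-mismatch experiment the autosomes should be balanced
    throughout; any called segment here is an unexpected region of
    relative copy-number imbalance, reported with its probe count and
    span.
    """
    t = thresholds or Thresholds()
    auto = track.subset(c for c in track.chromosomes if c != x_chrom)
    if len(auto) == 0:
        return []
    return [s for s in segment_track(auto, t) if s.state != "balanced"]
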