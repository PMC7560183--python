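"""Array-CGH copy-number analysis.

A :class:`RatioTrack` holds per-probe log2 test:reference ratios ordered
along the genome.  After QC filtering, each chromosome is partitioned
into segments of constant underlying copy number by least-squares
changepoint detection (binary segmentation with a BIC-style penalty — a
named, swappable strategy), and each segment's mean is thresholded into
a five-level state:

    high_loss <= -1.1 < loss <= -0.234 < balanced < 0.201 <= gain < 1.14 <= high_gain

Threshold comparisons are inclusive, and a called (non-balanced) segment
must contain at least ``min_probes`` consecutive probes (default 3);
shorter runs are merged into the flanking segment with the closer mean.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomicInterval, ValidationError

__all__ = [
    "RatioTrack",
    "Thresholds",
    "Segment",
    "compute_log2_ratios",
    "filter_track",
    "segment_track",
    "classify_state",
    "annotate_segments",
    "write_segments_bed",
]

logger = logging.getLogger(__name__)

STATES = ("high_loss", "loss", "balanced", "gain", "high_gain")

TRACK_COLUMNS = ["probe_id", "chrom", "pos", "log2", "non_uniform", "saturated"]


@dataclass(frozen=True)
class Thresholds:
    """Log2-ratio calling thresholds.

    Defaults are the platform's calling settings: gain >= 0.201, loss
    <= -0.234, high-amplitude gain >= 1.14, high-amplitude loss <= -1.1,
    minimum window of 3 consecutive probes.
    """

    gain: float = 0.201
    loss: float = -0.234
    high_gain: float = 1.14
    high_loss: float = -1.1
    min_probes: int = 3

    def __post_init__(self) -> None:
        if not (self.loss < 0 < self.gain):
            raise ValidationError("require loss < 0 < gain")
        if self.high_loss > self.loss or self.high_gain < self.gain:
            raise ValidationError("high thresholds must be at least as extreme")
        if self.min_probes < 1:
            raise ValidationError("min_probes must be >= 1")


def classify_state(mean_log2: float, thresholds: Thresholds | None = None) -> str:
    """Five-level state of a segment mean; high thresholds take precedence."""
    t = thresholds or Thresholds()
    if not math.isfinite(mean_log2):
        raise ValidationError("mean log2 must be finite")
    if mean_log2 >= t.high_gain:
        return "high_gain"
    if mean_log2 <= t.high_loss:
        return "high_loss"
    if mean_log2 >= t.gain:
        return "gain"
    if mean_log2 <= t.loss:
        return "loss"
    return "balanced"


class RatioTrack:
    """Ordered per-probe log2 ratios with QC flags.

    Backed by a DataFrame with columns probe_id, chrom, pos, log2,
    non_uniform, saturated; kept sorted by (chrom, pos).
    """

    def __init__(self, data: pd.DataFrame):
        missing = set(TRACK_COLUMNS) - set(data.columns)
        if missing:
            raise ValidationError(f"ratio track missing columns {sorted(missing)}")
        df = data.loc[:, TRACK_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["log2"] = df["log2"].astype(float)
        for c in ("non_uniform", "saturated"):
            df[c] = df[c].astype(bool)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.data = df

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "RatioTrack":
        df = pd.DataFrame(list(records))
        for c in ("non_uniform", "saturated"):
            if c not in df.columns:
                df[c] = False
        return cls(df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == chrom]

    def subset(self, chroms: Iterable[str]) -> "RatioTrack":
        chroms = set(chroms)
        return RatioTrack(self.data[self.data["chrom"].isin(chroms)])

    # -- I/O ------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path: str | Path) -> "RatioTrack":
        return cls(pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def compute_log2_ratios(
    intensities: pd.DataFrame, normalization: str = "median",
    autosomes: Sequence[str] | None = None,
) -> RatioTrack:
    """Per-probe log2(test/reference) from a two-channel intensity table.

    ``intensities`` needs columns probe_id, chrom, pos, test, reference
    (optional non_uniform / saturated flag columns are carried through).
    Probes with a non-positive intensity in either channel are excluded
    (logged), not raised.  ``normalization="median"`` recenters by
    subtracting the autosomal median log2 (all chromosomes not named
    like X/Y count as autosomes unless ``autosomes`` is given);
    ``"none"`` leaves raw ratios.
    """
    if normalization not in ("median", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    df = intensities.copy()
    ok = (df["test"] > 0) & (df["reference"] > 0)
    if (~ok).any():
        logger.warning("excluding %d probes with non-positive intensities",
                       int((~ok).sum()))
    df = df[ok]
    df["log2"] = np.log2(df["test"] / df["reference"])
    if normalization == "median":
        if autosomes is None:
            is_auto = ~df["chrom"].str.upper().str.rstrip("0123456789").str.endswith(("X", "Y"))
        else:
            is_auto = df["chrom"].isin(set(autosomes))
        if not is_auto.any():
            raise ValidationError("no autosomal probes to normalize against")
        df["log2"] = df["log2"] - df.loc[is_auto, "log2"].median()
    for c in ("non_uniform", "saturated"):
        if c not in df.columns:
            df[c] = False
    return RatioTrack(df[TRACK_COLUMNS])


def filter_track(track: RatioTrack) -> RatioTrack:
    """Drop probes flagged non-uniform or saturated (QC exclusion)."""
    flagged = track.data["non_uniform"] | track.data["saturated"]
    n = int(flagged.sum())
    if n:
        logger.info("filtered %d flagged probes of %d", n, len(track))
    if n == len(track):
        warnings.warn("all probes flagged: empty track after filtering")
    return RatioTrack(track.data[~flagged])


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """A contiguous probe run with constant called copy-number state.

    start/end are the positions of the first and last probe of the run
    (0-based), so ``end - start`` is the printed span after I/O
    conversion.  ``index`` is the (first, last+1) probe index range
    within the chromosome's track.
    """

    chrom: str
    start: int
    end: int
    n_probes: int
    mean_log2: float
    state: str
    index: tuple[int, int] = field(default=(0, 0), compare=False)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end + 1, ".")


def _binary_segmentation(values: np.ndarray, penalty: float,
                         min_size: int = 1) -> list[int]:
    """Changepoint indices by recursive least-squares binary splitting.

    A split is accepted while it reduces the residual sum of squares by
    more than ``penalty``.  Returns sorted interior breakpoints (each b
    means a boundary between index b-1 and b).
    """
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])

    def sse(i: int, j: int) -> float:  # [i, j)
        s = csum[j] - csum[i]
        return -(s * s) / (j - i)

    breakpoints: list[int] = []

    def split(i: int, j: int) -> None:
        if j - i < 2 * min_size:
            return
        base = sse(i, j)
        ks = np.arange(i + min_size, j - min_size + 1)
        left = csum[ks] - csum[i]
        right = csum[j] - csum[ks]
        gains = base + (left * left) / (ks - i) + (right * right) / (j - ks)
        best = int(np.argmax(gains))
        if gains[best] > penalty:
            k = int(ks[best])
            breakpoints.append(k)
            split(i, k)
            split(k, j)

    split(0, n)
    return sorted(breakpoints)


def _estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise scale from median absolute successive differences."""
    if len(values) < 2:
        return 0.0
    d = np.diff(values)
    return float(np.median(np.abs(d)) / (0.954 * math.sqrt(2)))


def segment_track(
    track: RatioTrack,
    thresholds: Thresholds | None = None,
    penalty: float | None = None,
    min_size: int = 1,
    strategy: Callable[[np.ndarray, float, int], list[int]] | None = None,
) -> list[Segment]:
    """Partition a filtered track into called copy-number segments.

    Chromosomes are segmented independently.  ``penalty`` defaults to a
    BIC-style 2·σ²·log(n) with σ estimated robustly per chromosome;
    pass a ``strategy`` callable (values, penalty, min_size) -> breakpoints
    to swap the changepoint engine.  After changepoint detection, runs
    shorter than ``min_probes`` are merged into the flanking segment
    with the closer mean (tie → left), then states are assigned from
    segment means.  Every probe belongs to exactly one segment.
    """
    t = thresholds or Thresholds()
    engine = strategy or _binary_segmentation
    segments: list[Segment] = []
    for chrom in track.chromosomes:
        sub = track.chromosome(chrom)
        values = sub["log2"].to_numpy()
        positions = sub["pos"].to_numpy()
        n = len(values)
        if n == 0:
            continue
        if penalty is None:
            sd = _estimate_noise_sd(values)
            pen = 2.0 * sd * sd * math.log(max(n, 2))
        else:
            pen = penalty
        pen = max(pen, 1e-8)  # guard against float dust on constant runs
        bps = engine(values, pen, min_size) if n >= 2 else []
        bounds = [0, *bps, n]
        runs = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        runs, cores = _merge_short_runs(runs, values, t.min_probes)
        for (i0, i1), core in zip(runs, cores):
            mean = float(values[i0:i1].mean())
            # The call is decided by the probes forming a legitimate
            # >=min_probes window (the "core"): absorbed sub-minimum
            # excursions contribute to the segment mean but can never
            # drive its state across a calling threshold.
            if core:
                core_vals = np.concatenate([values[s:e] for s, e in core])
                state = classify_state(float(core_vals.mean()), t)
            else:
                state = "balanced"
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(positions[i0]),
                    end=int(positions[i1 - 1]),
                    n_probes=i1 - i0,
                    mean_log2=mean,
                    state=state,
                    index=(i0, i1),
                )
            )
    return segments


def _merge_short_runs(
    runs: list[tuple[int, int]], values: np.ndarray, min_probes: int
) -> tuple[list[tuple[int, int]], list[list[tuple[int, int]]]]:
    """Merge runs of < min_probes probes into the closer-mean neighbor.

    Returns the merged runs and, for each, its "core" spans: the index
    ranges that were part of a >=min_probes run (or that together form
    one after two sub-minimum runs coalesce).  A run left with no core —
    only possible when the whole chromosome is that short — cannot carry
    a call.
    """
    runs = list(runs)
    cores: list[list[tuple[int, int]]] = [
        [r] if r[1] - r[0] >= min_probes else [] for r in runs
    ]

    def mean(r):
        return values[r[0]:r[1]].mean()

    while len(runs) > 1:
        lengths = [r[1] - r[0] for r in runs]
        shorts = [i for i, L in enumerate(lengths) if L < min_probes]
        if not shorts:
            break
        # merge the shortest first for determinism
        i = min(shorts, key=lambda idx: (lengths[idx], idx))
        m = mean(runs[i])
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            dl = abs(m - mean(runs[i - 1]))
            dr = abs(m - mean(runs[i + 1]))
            j = i - 1 if dl <= dr else i + 1
        lo, hi = min(i, j), max(i, j)
        merged = (runs[lo][0], runs[hi][1])
        if cores[j]:
            core = cores[j]
        elif merged[1] - merged[0] >= min_probes:
            # two sub-minimum runs coalescing into a window-sized run
            core = [merged]
        else:
            core = []
        runs[lo:hi + 1] = [merged]
        cores[lo:hi + 1] = [core]
    return runs, cores


# ---------------------------------------------------------------------------
# Gene annotation and export
# ---------------------------------------------------------------------------

def annotate_segments(
    segments: Sequence[Segment], genes: Sequence[GeneAnnotation]
) -> dict[Segment, list[str]]:
    """Genes overlapping each segment by >= 1 bp (half-open arithmetic)."""
    out: dict[Segment, list[str]] = {}
    for seg in segments:
        iv = seg.interval
        out[seg] = [g.symbol for g in genes if g.interval.overlaps(iv)]
    return out


def write_segments_bed(segments: Sequence[Segment], path: str | Path) -> None:
    """Segments as BED5+ (0-based half-open; state, mean log2, n_probes)."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.interval.start}\t{s.interval.end}\t{s.state}\t"
                f"{s.mean_log2:.4f}\t{s.n_probes}\n"
            )


def read_segments_bed(path: str | Path) -> list[Segment]:
    segments = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, state, mean, n = line.split("\t")[:6]
            segments.append(
                Segment(chrom, int(start), int(end) - 1, int(n), float(mean), state)
            )
    return segments
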