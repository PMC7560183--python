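"""Paired tumor-profile comparison on a common probe grid.

Two segmentations of the same array design (e.g. a primary tumor and a
later mass from the same patient) are compared probe-by-probe: each
probe position takes its called state under each profile, concordance is
the fraction of probes with identical state, and maximal runs of
disagreeing probes become discordant regions annotated with the mean
log2 amplitude difference (A − B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cgh import Segment
from .core import ValidationError

__all__ = ["DiscordantRegion", "ProfileComparison", "compare_profiles"]

_COLLAPSE = {
    "high_loss": "loss",
    "loss": "loss",
    "balanced": "balanced",
    "gain": "gain",
    "high_gain": "gain",
}


@dataclass(frozen=True)
class DiscordantRegion:
    chrom: str
    start: int
    end: int
    n_probes: int
    state_a: str
    state_b: str
    mean_log2_diff: float  # mean over probes of (segment mean A − segment mean B)


@dataclass(frozen=True)
class ProfileComparison:
    concordance: float  # fraction of probes with identical state
    concordance_bp: float  # same, weighted by inter-probe spacing
    n_probes: int
    discordant_regions: tuple[DiscordantRegion, ...]
    states: pd.DataFrame  # per-probe chrom, pos, state_a, state_b

    def __post_init__(self) -> None:
        if not (0.0 <= self.concordance <= 1.0):
            raise ValidationError("concordance outside [0, 1]")


def _states_on_grid(
    segments: Sequence[Segment], chrom: str, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe (state, segment mean) under one profile; probes not
    covered by any segment count as balanced at 0."""
    states = np.full(len(positions), "balanced", dtype=object)
    means = np.zeros(len(positions))
    for s in segments:
        if s.chrom != chrom:
            continue
        mask = (positions >= s.start) & (positions <= s.end)
        states[mask] = s.state
        means[mask] = s.mean_log2
    return states, means


def compare_profiles(
    segments_a: Sequence[Segment],
    segments_b: Sequence[Segment],
    probes: pd.DataFrame,
    levels: int = 5,
) -> ProfileComparison:
    """Compare two segment profiles on a probe grid.

    ``probes`` needs columns chrom, pos (the union grid both profiles
    were segmented on).  ``levels=5`` compares the full state alphabet;
    ``levels=3`` collapses high-amplitude calls into gain/loss for a
    coarser, qualitative comparison.  Profiles must cover the same
    chromosome set.
    """
    if levels not in (3, 5):
        raise ValueError("levels must be 3 or 5")
    chroms_a = {s.chrom for s in segments_a}
    chroms_b = {s.chrom for s in segments_b}
    if chroms_a and chroms_b and chroms_a.isdisjoint(chroms_b):
        raise ValidationError("profiles cover disjoint chromosome sets")

    frames = []
    regions: list[DiscordantRegion] = []
    weights_all = []
    for chrom in dict.fromkeys(probes["chrom"]):
        pos = probes.loc[probes["chrom"] == chrom, "pos"].to_numpy(np.int64)
        pos = np.sort(pos)
        st_a, mean_a = _states_on_grid(segments_a, chrom, pos)
        st_b, mean_b = _states_on_grid(segments_b, chrom, pos)
        if levels == 3:
            st_a = np.array([_COLLAPSE[s] for s in st_a], dtype=object)
            st_b = np.array([_COLLAPSE[s] for s in st_b], dtype=object)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "state_a": st_a, "state_b": st_b}
            )
        )
        # probe weight: half the spacing to each neighbor (ends: outer spacing)
        if len(pos) > 1:
            gaps = np.diff(pos)
            w = np.empty(len(pos))
            w[0] = gaps[0]
            w[-1] = gaps[-1]
            if len(pos) > 2:
                w[1:-1] = (gaps[:-1] + gaps[1:]) / 2
        else:
            w = np.ones(len(pos))
        weights_all.append((st_a == st_b, w))

        # maximal discordant runs
        mismatch = st_a != st_b
        i = 0
        while i < len(pos):
            if not mismatch[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(pos) and mismatch[j + 1] and (
                st_a[j + 1] == st_a[i] and st_b[j + 1] == st_b[i]
            ):
                j += 1
            regions.append(
                DiscordantRegion(
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]),
                    n_probes=j - i + 1,
                    state_a=str(st_a[i]),
                    state_b=str(st_b[i]),
                    mean_log2_diff=float((mean_a[i:j + 1] - mean_b[i:j + 1]).mean()),
                )
            )
            i = j + 1

    states = pd.concat(frames, ignore_index=True)
    agree = states["state_a"] == states["state_b"]
    same = np.concatenate([m for m, _ in weights_all])
    w = np.concatenate([wt for _, wt in weights_all])
    return ProfileComparison(
        concordance=float(agree.mean()),
        concordance_bp=float((same * w).sum() / w.sum()),
        n_probes=len(states),
        discordant_regions=tuple(regions),
        states=states,
    )
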