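"""Seeded generators for every input the toolkit consumes.

These emulate the study conditions at desk scale: a template genome and
a diverged target genome with a known orthology map (substitutions,
geometric indels, deleted and duplicated loci); probe sets tiled at the
array's ~22.6 kb design spacing; CGH ratio tracks with piecewise-
constant copy-number truth plus i.i.d. Gaussian noise (default sd
0.15); and a sex-mismatch experiment with a balanced pseudoautosomal
head on X.  Every generator is deterministic under a fixed seed and
emits the same in-memory types and text formats the analysis modules
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import thermo
from .cgh import RatioTrack, Thresholds, classify_state
from .core import GenomeAssembly, GenomicInterval, Probe, ValidationError

__all__ = [
    "GenomePairTruth",
    "CnaTruth",
    "SexMismatchTruth",
    "simulate_genome_pair",
    "simulate_probes",
    "simulate_cgh",
    "simulate_sex_mismatch",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# Genome pair with orthology truth
# ---------------------------------------------------------------------------

@dataclass
class GenomePairTruth:
    """Ground truth of a simulated template→target divergence.

    ``orthology`` maps each template block (chrom, start, end) to its
    target interval (chrom, start, end) or None when deleted.
    ``sub_positions`` / ``indel_positions`` are the template coordinates
    of realized edits per chromosome; ``duplicated_loci`` lists template
    blocks whose target copy also exists verbatim on a decoy scaffold.
    """

    orthology: dict[tuple[str, int, int], tuple[str, int, int] | None]
    sub_positions: dict[str, np.ndarray]
    del_positions: dict[str, np.ndarray]  # template bases deleted in target
    ins_positions: dict[str, np.ndarray]  # insertion sits before this base
    duplicated_loci: list[tuple[str, int, int]] = field(default_factory=list)
    block_size: int = 0

    @property
    def indel_positions(self) -> dict[str, np.ndarray]:
        return {
            c: np.union1d(self.del_positions.get(c, np.array([], dtype=np.int64)),
                          self.ins_positions.get(c, np.array([], dtype=np.int64)))
            for c in set(self.del_positions) | set(self.ins_positions)
        }

    def deleted_blocks(self, chrom: str) -> list[tuple[int, int]]:
        return [
            (s, e)
            for (c, s, e), tgt in self.orthology.items()
            if c == chrom and tgt is None
        ]

    def expected_probe_fate(self, probe: Probe) -> str:
        """Expected migration fate class for a probe on the template.

        Returns one of "missing" (core overlaps a deleted block),
        "duplicated" (core overlaps a duplicated block), "conserved"
        (no realized edit inside the core → exact sequence match) or
        "diverged" (edited core: a non-identical ortholog exists).
        """
        iv = probe.interval
        for s, e in self.deleted_blocks(iv.chrom):
            if iv.start < e and s < iv.end:
                return "missing"
        for c, s, e in self.duplicated_loci:
            if c == iv.chrom and iv.start < e and s < iv.end:
                return "duplicated"
        subs = self.sub_positions.get(iv.chrom, np.array([]))
        dels = self.del_positions.get(iv.chrom, np.array([]))
        ins = self.ins_positions.get(iv.chrom, np.array([]))
        n_edits = int(((subs >= iv.start) & (subs < iv.end)).sum())
        n_edits += int(((dels >= iv.start) & (dels < iv.end)).sum())
        # an insertion sits between bases pos-1 and pos: it alters the core
        # sequence only strictly inside the interval
        n_edits += int(((ins > iv.start) & (ins < iv.end)).sum())
        return "conserved" if n_edits == 0 else "diverged"


def simulate_genome_pair(
    n_chrom: int = 2,
    lengths: int | Sequence[int] = 50_000,
    substitution_rate: float = 0.02,
    indel_rate: float = 0.001,
    deleted_fraction: float = 0.05,
    duplicated_fraction: float = 0.02,
    block_size: int = 4_000,
    seed: int = 0,
) -> tuple[GenomeAssembly, GenomeAssembly, GenomePairTruth]:
    """A template genome and a diverged target with known orthology.

    Divergence model: uniform per-base substitutions, indels starting at
    per-base rate ``indel_rate`` with geometric(0.5) lengths, whole
    ``block_size`` blocks deleted or duplicated at the given fractions.
    Duplicated blocks place a verbatim second copy of their *target*
    sequence on a decoy scaffold, so any probe migrated from them maps
    ambiguously.  Deterministic for a fixed seed.
    """
    for name, rate in (
        ("substitution_rate", substitution_rate),
        ("indel_rate", indel_rate),
        ("deleted_fraction", deleted_fraction),
        ("duplicated_fraction", duplicated_fraction),
    ):
        if not (0 <= rate < 1):
            raise ValidationError(f"{name} must be in [0, 1)")
    if deleted_fraction + duplicated_fraction >= 1:
        raise ValidationError("deleted + duplicated fractions leave no target")
    rng = np.random.default_rng(seed)
    if isinstance(lengths, int):
        lengths = [lengths] * n_chrom

    template: dict[str, str] = {}
    target: dict[str, str] = {}
    orthology: dict[tuple[str, int, int], tuple[str, int, int] | None] = {}
    sub_positions: dict[str, np.ndarray] = {}
    del_positions: dict[str, np.ndarray] = {}
    ins_positions: dict[str, np.ndarray] = {}
    duplicated_loci: list[tuple[str, int, int]] = []
    decoy_parts: list[str] = []

    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        L = int(lengths[ci])
        tmpl = _random_seq(rng, L)
        template[chrom] = tmpl

        blocks = [(s, min(s + block_size, L)) for s in range(0, L, block_size)]
        n_blocks = len(blocks)
        n_del = int(round(deleted_fraction * n_blocks))
        n_dup = int(round(duplicated_fraction * n_blocks))
        special = rng.choice(n_blocks, size=min(n_del + n_dup, n_blocks),
                             replace=False)
        deleted = set(special[:n_del].tolist())
        duplicated = set(special[n_del:].tolist())

        out: list[str] = []
        tmap = np.full(L, -1, dtype=np.int64)
        subs: list[int] = []
        dels: list[int] = []
        inss: list[int] = []
        cursor = 0
        i = 0
        block_of = lambda p: p // block_size  # noqa: E731
        while i < L:
            if block_of(i) in deleted:
                i += 1
                continue
            if rng.random() < indel_rate:
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:  # deletion from template
                    for j in range(i, min(i + length, L)):
                        if block_of(j) == block_of(i):
                            dels.append(j)
                    i = min(i + length, L)
                    continue
                else:  # insertion into target, before base i
                    ins = _random_seq(rng, length)
                    out.append(ins)
                    cursor += length
                    inss.append(i)
            base = tmpl[i]
            if rng.random() < substitution_rate:
                base = rng.choice([b for b in "ACGT" if b != base])
                subs.append(i)
            out.append(base)
            tmap[i] = cursor
            cursor += 1
            i += 1
        tgt_seq = "".join(out)
        target[chrom] = tgt_seq
        sub_positions[chrom] = np.array(sorted(subs), dtype=np.int64)
        del_positions[chrom] = np.array(sorted(dels), dtype=np.int64)
        ins_positions[chrom] = np.array(sorted(inss), dtype=np.int64)

        for bi, (bs, be) in enumerate(blocks):
            if bi in deleted:
                orthology[(chrom, bs, be)] = None
                continue
            mapped = tmap[bs:be]
            mapped = mapped[mapped >= 0]
            if mapped.size == 0:
                orthology[(chrom, bs, be)] = None
                continue
            t_iv = (chrom, int(mapped.min()), int(mapped.max()) + 1)
            orthology[(chrom, bs, be)] = t_iv
            if bi in duplicated:
                duplicated_loci.append((chrom, bs, be))
                decoy_parts.append(tgt_seq[t_iv[1]:t_iv[2]])

    if decoy_parts:
        # N spacers keep decoy copies as distinct, unbridgeable loci
        target["scaffold_dup"] = ("N" * 500).join(decoy_parts)

    if not any(target.values()):
        raise ValidationError("simulated target genome is empty")
    truth = GenomePairTruth(
        orthology=orthology,
        sub_positions=sub_positions,
        del_positions=del_positions,
        ins_positions=ins_positions,
        duplicated_loci=duplicated_loci,
        block_size=block_size,
    )
    return (
        GenomeAssembly("template", template),
        GenomeAssembly("target", target),
        truth,
    )


# ---------------------------------------------------------------------------
# Probe tiling
# ---------------------------------------------------------------------------

def simulate_probes(
    genome: GenomeAssembly,
    spacing: int = 22_600,
    probe_length: int = 60,
    seed: int = 0,
    thermo_params: thermo.ThermoParams | None = None,
) -> list[Probe]:
    """Tile N-free probes along a genome at a target mean spacing.

    Successive start-to-start gaps are Uniform(0.5, 1.5) × spacing, so
    the realized mean spacing converges to the target.  Windows
    containing N are advanced past.  Tm/GC are attached when
    ``thermo_params`` is given.
    """
    if spacing <= probe_length:
        raise ValidationError("spacing must exceed probe length")
    rng = np.random.default_rng(seed)
    probes: list[Probe] = []
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        pos = int(rng.integers(0, max(spacing // 2, 1)))
        idx = 0
        while pos + probe_length <= L:
            window = seq[pos : pos + probe_length]
            if "N" in window:
                pos += probe_length
                continue
            iv = GenomicInterval(chrom, pos, pos + probe_length, "+")
            p = Probe(f"{chrom}_p{idx:05d}", iv, window)
            if thermo_params is not None:
                p.gc = thermo.gc_content(window)
                p.tm = thermo.melting_temperature(window, thermo_params)
            probes.append(p)
            idx += 1
            pos += int(spacing * rng.uniform(0.5, 1.5))
    return probes


# ---------------------------------------------------------------------------
# CGH ratio tracks with copy-number truth
# ---------------------------------------------------------------------------

@dataclass
class CnaTruth:
    """Piecewise-constant copy-number truth underlying a simulated track.

    ``segments`` holds (chrom, start, end, log2 level) with half-open,
    per-chromosome non-overlapping intervals; positions not covered are
    balanced at level 0.  After simulation, ``probe_levels`` and
    ``probe_states`` record the truth at each probe of the emitted
    track.
    """

    segments: list[tuple[str, int, int, float]]
    noise_sd: float = 0.15
    probe_levels: np.ndarray | None = None
    probe_states: list[str] | None = None

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, level in self.segments:
            if not np.isfinite(level):
                raise ValidationError("truth level must be finite")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValidationError(f"overlapping truth intervals on {chrom}")

    def level_at(self, chrom: str, pos: int) -> float:
        for c, s, e, level in self.segments:
            if c == chrom and s <= pos < e:
                return level
        return 0.0


def _positions_frame(probes) -> pd.DataFrame:
    if isinstance(probes, pd.DataFrame):
        return probes[["probe_id", "chrom", "pos"]].copy()
    rows = [
        {"probe_id": p.id, "chrom": p.interval.chrom, "pos": p.interval.start}
        for p in probes
    ]
    return pd.DataFrame(rows)


def simulate_cgh(
    probes,
    truth: CnaTruth,
    noise_sd: float | None = None,
    seed: int = 0,
    thresholds: Thresholds | None = None,
) -> tuple[RatioTrack, CnaTruth]:
    """A ratio track: truth level at each probe plus Gaussian noise.

    ``probes`` is a list of :class:`Probe` or a DataFrame with columns
    probe_id, chrom, pos.  The returned truth carries per-probe levels
    and their threshold states.
    """
    sd = truth.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    df = _positions_frame(probes)
    levels = np.array(
        [truth.level_at(c, p) for c, p in zip(df["chrom"], df["pos"])]
    )
    noise = rng.normal(0.0, sd, size=len(df)) if sd > 0 else np.zeros(len(df))
    df["log2"] = levels + noise
    df["non_uniform"] = False
    df["saturated"] = False
    t = thresholds or Thresholds()
    truth.noise_sd = sd
    truth.probe_levels = levels
    truth.probe_states = [classify_state(v, t) for v in levels]
    return RatioTrack(df), truth


# ---------------------------------------------------------------------------
# Sex-mismatch experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexMismatchTruth:
    """Truth of a simulated female-vs-male hybridization."""

    par_interval: tuple[int, int]  # balanced head of X
    x_level: float  # log2 dosage of X-specific probes (2 vs 1 copies → 1.0)
    boundary_window: tuple[int, int]  # (last PAR probe pos, first X-specific pos)
    x_chrom: str = "X"


def simulate_sex_mismatch(
    x_length: int = 20_000_000,
    par_length: int = 7_000_000,
    n_autosomes: int = 2,
    autosome_length: int = 10_000_000,
    probe_spacing: int = 23_000,
    noise_sd: float = 0.15,
    seed: int = 0,
    autosomal_cna: Sequence[tuple[str, int, int, float]] = (),
) -> tuple[RatioTrack, SexMismatchTruth]:
    """Female-vs-male ratio track with a balanced PAR head on X.

    X probes distal to the PAR sit at log2 = 1 (two copies vs one);
    PAR and autosomal probes at 0, all plus Gaussian noise.  Optional
    ``autosomal_cna`` intervals (chrom, start, end, level) emulate
    unexpected autosomal imbalances.
    """
    if par_length >= x_length:
        raise ValidationError("par_length must be < x_length")
    rng = np.random.default_rng(seed)
    records = []

    def tile(chrom: str, length: int) -> np.ndarray:
        pos: list[int] = []
        p = int(rng.integers(0, probe_spacing))
        while p < length:
            pos.append(p)
            p += int(probe_spacing * rng.uniform(0.5, 1.5))
        return np.asarray(pos, dtype=np.int64)

    x_pos = tile("X", x_length)
    x_levels = np.where(x_pos < par_length, 0.0, 1.0)
    for i, (p, level) in enumerate(zip(x_pos, x_levels)):
        records.append(
            {"probe_id": f"X_p{i:05d}", "chrom": "X", "pos": int(p), "log2": level}
        )
    for a in range(n_autosomes):
        chrom = f"A{a + 1}"
        for i, p in enumerate(tile(chrom, autosome_length)):
            level = 0.0
            for c, s, e, lv in autosomal_cna:
                if c == chrom and s <= p < e:
                    level = lv
            records.append(
                {
                    "probe_id": f"{chrom}_p{i:05d}",
                    "chrom": chrom,
                    "pos": int(p),
                    "log2": level,
                }
            )

    df = pd.DataFrame(records)
    if noise_sd > 0:
        df["log2"] = df["log2"] + rng.normal(0.0, noise_sd, size=len(df))
    df["non_uniform"] = False
    df["saturated"] = False

    par_probes = x_pos[x_pos < par_length]
    distal = x_pos[x_pos >= par_length]
    if len(par_probes) == 0 or len(distal) == 0:
        raise ValidationError("PAR or X-specific region received no probes")
    truth = SexMismatchTruth(
        par_interval=(0, int(par_length)),
        x_level=1.0,
        boundary_window=(int(par_probes[-1]), int(distal[0])),
    )
    return RatioTrack(df), truth
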