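"""Melting-temperature / GC computation and thermodynamic probe adjustment.

Array probes must hybridize comparably under a single wash condition, so a
migrated probe is required to match its template's melting temperature (Tm)
and GC fraction within configurable tolerances.  Tm uses nearest-neighbor
thermodynamics (SantaLucia unified parameters via Biopython's ``Tm_NN``)
with configurable monovalent-salt and oligo concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.SeqUtils import MeltingTemp as _mt

from .core import GenomicInterval, Probe, ValidationError

__all__ = ["ThermoParams", "gc_content", "melting_temperature", "adjust_probe"]


@dataclass(frozen=True)
class ThermoParams:
    """Tolerances and Tm-model conditions for probe matching.

    tm_tolerance : max |ΔTm| in °C between candidate and template.
    gc_tolerance : max |ΔGC| as a fraction (0.05 = five percentage points).
    min_len, max_len : permitted probe lengths in nt (around the ~60-mer
        design length).
    na_mM : monovalent cation concentration for the Tm model.  The default
        (300 mM, a high-salt hybridization condition) places typical
        AT-rich 60-mers in the 71-85 °C band characteristic of long-oligo
        aCGH designs.
    dnac1_nM / dnac2_nM : strand concentrations passed to the model.
    """

    tm_tolerance: float = 2.0
    gc_tolerance: float = 0.05
    min_len: int = 45
    max_len: int = 75
    na_mM: float = 300.0
    dnac1_nM: float = 25.0
    dnac2_nM: float = 25.0

    def __post_init__(self) -> None:
        if self.tm_tolerance <= 0 or self.gc_tolerance <= 0:
            raise ValidationError("tolerances must be > 0")
        if not (0 < self.min_len < self.max_len):
            raise ValidationError("require 0 < min_len < max_len")


def gc_content(sequence: str) -> float:
    """Fraction of G+C bases, in [0, 1].

    Rejects empty sequences and any sequence containing N (candidate
    probes with masked/unknown bases are not designable).
    """
    if not sequence:
        raise ValidationError("gc_content of empty sequence")
    seq = sequence.upper()
    if "N" in seq:
        raise ValidationError("gc_content undefined for sequence containing N")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValidationError(f"non-nucleotide characters {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(sequence: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature in °C."""
    params = params or ThermoParams()
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValidationError(
            f"sequence of length {len(seq)} below nearest-neighbor model support (8)"
        )
    if set(seq) - set("ACGT"):
        raise ValidationError("melting_temperature requires an ACGT-only sequence")
    return _mt.Tm_NN(
        seq,
        Na=params.na_mM,
        dnac1=params.dnac1_nM,
        dnac2=params.dnac2_nM,
    )


def _within(candidate_tm: float, candidate_gc: float, template: Probe,
            params: ThermoParams) -> bool:
    return (
        abs(candidate_tm - template.tm) <= params.tm_tolerance
        and abs(candidate_gc - template.gc) <= params.gc_tolerance
    )


def adjust_probe(
    core: tuple[int, int],
    context: str,
    template: Probe,
    params: ThermoParams | None = None,
    chrom: str | None = None,
    context_offset: int = 0,
    probe_id: str | None = None,
) -> Optional[Probe]:
    """Match a candidate probe to a template's thermodynamic profile.

    ``core`` is the (start, end) of the orthologous candidate within
    ``context`` (the candidate plus its available flanking target
    sequence).  Both probe ends may be moved within the context, keeping
    the window overlapping the core and its length within bounds, until
    Tm and GC fall within tolerance of the template probe.  Windows
    containing N are not designable and are skipped.

    Returns the adjusted :class:`Probe` (coordinates shifted by
    ``context_offset`` onto chromosome ``chrom`` when given), or None when
    no window qualifies — the fate of template loci whose target
    nucleotide composition rules out a thermodynamically matched probe.

    Among feasible windows the one minimizing \\|ΔTm\\| is preferred,
    ties broken by \\|ΔGC\\| and then by least positional shift from the
    core, so results are deterministic and stay centered on the ortholog.
    """
    params = params or ThermoParams()
    cs, ce = core
    if not (0 <= cs < ce <= len(context)):
        raise ValidationError("core does not lie within context")
    if template.tm is None or template.gc is None:
        raise ValidationError("template probe lacks tm/gc")
    context = context.upper()

    # Fast path: unchanged core already within both tolerances.
    core_seq = context[cs:ce]
    if params.min_len <= len(core_seq) <= params.max_len and "N" not in core_seq:
        tm0 = melting_temperature(core_seq, params)
        gc0 = gc_content(core_seq)
        if _within(tm0, gc0, template, params):
            return _make(core, context, tm0, gc0, chrom, context_offset,
                         probe_id or template.id)

    # GC prefix sums let infeasible-GC windows be skipped without a Tm call.
    n = len(context)
    gc_prefix = [0] * (n + 1)
    n_prefix = [0] * (n + 1)
    for i, ch in enumerate(context):
        gc_prefix[i + 1] = gc_prefix[i] + (ch in "GC")
        n_prefix[i + 1] = n_prefix[i] + (ch not in "ACGT")

    best: tuple[float, float, int, tuple[int, int], float, float] | None = None
    for start in range(0, ce):  # window must overlap the core
        lo = max(start + params.min_len, cs + 1)
        hi = min(start + params.max_len, n)
        for end in range(lo, hi + 1):
            if end <= start:
                continue
            if n_prefix[end] - n_prefix[start] > 0:
                continue
            length = end - start
            gc = (gc_prefix[end] - gc_prefix[start]) / length
            if abs(gc - template.gc) > params.gc_tolerance:
                continue
            tm = melting_temperature(context[start:end], params)
            if abs(tm - template.tm) > params.tm_tolerance:
                continue
            shift = abs(start - cs) + abs(end - ce)
            key = (abs(tm - template.tm), abs(gc - template.gc), shift,
                   (start, end), tm, gc)
            if best is None or key[:4] < best[:4]:
                best = key
    if best is None:
        return None
    _, _, _, window, tm, gc = best
    return _make(window, context, tm, gc, chrom, context_offset,
                 probe_id or template.id)


def _make(window, context, tm, gc, chrom, context_offset, probe_id) -> Probe:
    start, end = window
    seq = context[start:end]
    interval = GenomicInterval(
        chrom or "context", context_offset + start, context_offset + end, "+"
    )
    return Probe(probe_id, interval, seq, tm=tm, gc=gc)
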