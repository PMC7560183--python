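"""Cross-species probe migration: template → target genome.

The pipeline mirrors the in-silico strategy used to derive one species'
array design from another's:

1. each template probe is *extended* with flanking genome sequence
   (default 100 nt per side, giving ~260 nt contexts for 60-mers);
2. the extension is aligned to the target genome to locate the single
   most conserved *orthologous* locus;
3. the target *core* — the columns aligned to the original probe — is
   extracted;
4. if the core is not an exact sequence match and does not already meet
   the template's Tm/GC profile, its ends are *adjusted* within the
   flanking target sequence;
5. every successful candidate is remapped against the whole target
   genome and demoted if its sequence is not *unique*.

Each input probe receives exactly one :class:`MigrationRecord`; the
:class:`Ledger` aggregates the per-stage accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import thermo
from .align import AlignmentHit, KmerIndex, SeededAligner
from .core import GenomeAssembly, GenomicInterval, Probe, ValidationError

__all__ = [
    "STATUSES",
    "MigrationRecord",
    "Ledger",
    "AlignParams",
    "extend_probe",
    "find_ortholog",
    "extract_core",
    "verify_unique",
    "migrate_probes",
    "write_records",
]

#: Probe fates, in pipeline order.  ``exact_match``, ``direct_ortholog``
#: and ``adjusted`` are the success (candidate) classes.
STATUSES = (
    "no_alignment",
    "exact_match",
    "direct_ortholog",
    "adjusted",
    "failed_adjust",
    "ambiguous_map",
)
_SUCCESS = {"exact_match", "direct_ortholog", "adjusted"}


@dataclass(frozen=True)
class AlignParams:
    """Knobs of the ortholog search and uniqueness remapping."""

    flank: int = 100
    kmer: int = 11
    min_identity: float = 0.75
    min_query_coverage: float = 0.5
    ambiguity_margin: float = 1.1
    min_core_coverage: float = 0.8
    near_match_identity: float = 0.9
    uniqueness_kmer: int = 8


@dataclass
class MigrationRecord:
    """The fate of one template probe.

    ``candidate_class`` preserves the success class a probe had reached
    before a uniqueness demotion to ``ambiguous_map``.
    """

    template_id: str
    status: str
    target_probe: Probe | None = None
    identity: float | None = None
    candidate_class: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")
        if (self.target_probe is not None) != (self.status in _SUCCESS):
            raise ValidationError(
                f"record {self.template_id}: target probe must be present "
                "iff status is a success class"
            )


@dataclass(frozen=True)
class Ledger:
    """Stage accounting of a migration run.

    ``exact_match``, ``direct_ortholog`` and ``adjusted`` count the
    candidate classes *before* the uniqueness remap; ``ambiguous_map``
    counts candidates subsequently excluded by it.  Probes whose primary
    ortholog search was ambiguous are counted under ``no_alignment``
    (no robust unambiguous alignment), with the ambiguity visible on the
    per-probe record.
    """

    total: int
    no_alignment: int
    exact_match: int
    direct_ortholog: int
    adjusted: int
    failed_adjust: int
    ambiguous_map: int

    def __post_init__(self) -> None:
        staged = (
            self.no_alignment
            + self.exact_match
            + self.direct_ortholog
            + self.adjusted
            + self.failed_adjust
        )
        if staged != self.total:
            raise ValidationError(
                f"ledger inconsistent: stage counts sum to {staged}, "
                f"total is {self.total}"
            )
        if not (0 <= self.ambiguous_map <= self.candidates):
            raise ValidationError(
                f"ambiguous_map ({self.ambiguous_map}) outside "
                f"[0, candidates={self.candidates}]"
            )

    # -- derived stage arithmetic --------------------------------------
    @property
    def successful_alignments(self) -> int:
        return self.total - self.no_alignment

    @property
    def adjust_attempted(self) -> int:
        return self.adjusted + self.failed_adjust

    @property
    def candidates(self) -> int:
        return self.exact_match + self.direct_ortholog + self.adjusted

    @property
    def final_probes(self) -> int:
        return self.candidates - self.ambiguous_map

    @property
    def failure_rate(self) -> float:
        return self.no_alignment / self.total

    @classmethod
    def from_records(cls, records: Sequence[MigrationRecord]) -> "Ledger":
        counts = {s: 0 for s in STATUSES}
        ambiguous_alignment = 0
        for r in records:
            if r.status == "ambiguous_map" and r.candidate_class is None:
                ambiguous_alignment += 1  # primary search ambiguous
            elif r.status == "ambiguous_map":
                counts[r.candidate_class] += 1
                counts["ambiguous_map"] += 1
            else:
                counts[r.status] += 1
        return cls(
            total=len(records),
            no_alignment=counts["no_alignment"] + ambiguous_alignment,
            exact_match=counts["exact_match"],
            direct_ortholog=counts["direct_ortholog"],
            adjusted=counts["adjusted"],
            failed_adjust=counts["failed_adjust"],
            ambiguous_map=counts["ambiguous_map"],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_input", self.total),
            ("no_alignment", self.no_alignment),
            ("successful_alignments", self.successful_alignments),
            ("exact_match", self.exact_match),
            ("direct_ortholog", self.direct_ortholog),
            ("adjust_attempted", self.adjust_attempted),
            ("adjusted", self.adjusted),
            ("failed_adjust", self.failed_adjust),
            ("candidates", self.candidates),
            ("ambiguous_map", self.ambiguous_map),
            ("final_probes", self.final_probes),
        ]
        return pd.DataFrame(rows, columns=["stage", "count"])


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def extend_probe(
    probe: Probe, genome: GenomeAssembly, flank: int = 100
) -> tuple[str, int, GenomicInterval]:
    """Flank a probe with genome sequence on both sides.

    Returns (extended sequence, offset of the probe core within it,
    extension interval).  Flanks are clipped at chromosome bounds, so the
    core offset equals the realized left flank.
    """
    iv = probe.interval
    chrom_len = genome.lengths[iv.chrom]
    start = max(0, iv.start - flank)
    end = min(chrom_len, iv.end + flank)
    ext = GenomicInterval(iv.chrom, start, end, "+")
    return genome.fetch(ext), iv.start - start, ext


def find_ortholog(
    extended_seq: str,
    target_genome: GenomeAssembly,
    params: AlignParams | None = None,
    aligner: SeededAligner | None = None,
    index: KmerIndex | None = None,
) -> tuple[str, AlignmentHit | None]:
    """Locate the single conserved ortholog of an extended probe.

    Returns ("hit", AlignmentHit) on success, or a failure status
    ("no_alignment", None) / ("ambiguous_map", None).  A hit requires
    identity >= min_identity, alignment spanning >= min_query_coverage of
    the query, and a best score exceeding the runner-up locus by the
    ambiguity margin.
    """
    params = params or AlignParams()
    aligner = aligner or SeededAligner(k=params.kmer)
    hits = aligner.search(extended_seq, target_genome, index=index)
    if not hits:
        return "no_alignment", None
    best = hits[0]
    if (
        best.identity < params.min_identity
        or best.query_coverage_span < params.min_query_coverage * len(extended_seq)
    ):
        return "no_alignment", None
    if len(hits) > 1 and best.score < params.ambiguity_margin * hits[1].score:
        return "ambiguous_map", None
    return "hit", best


def extract_core(
    hit: AlignmentHit,
    core_offset: int,
    core_length: int,
    target_genome: GenomeAssembly,
    min_core_coverage: float = 0.8,
) -> tuple[str, GenomicInterval] | None:
    """Project the template core through the alignment's column map.

    Target positions aligned to core columns define the target core
    interval (gap columns drop out, so indels shrink or stretch it).
    Returns None when fewer than ``min_core_coverage`` of the core's
    columns are aligned.
    """
    core_cols = [
        t for q, t in hit.column_map if core_offset <= q < core_offset + core_length
    ]
    if len(core_cols) < min_core_coverage * core_length or not core_cols:
        return None
    interval = GenomicInterval(
        hit.interval.chrom, min(core_cols), max(core_cols) + 1, "+"
    )
    return target_genome.fetch(interval), interval


def verify_unique(
    candidate: str,
    target_genome: GenomeAssembly,
    params: AlignParams | None = None,
    aligner: SeededAligner | None = None,
    index: KmerIndex | None = None,
) -> GenomicInterval | None:
    """Remap a candidate probe; return its locus iff it maps uniquely.

    A locus counts as a near match when its alignment covers the
    candidate at >= near_match_identity over the candidate's *full*
    length (matches / candidate length).  Returns None (ambiguous) when
    zero or more than one such locus exists.  The default seed size (8)
    guarantees a seed hit for any 60-mer copy within 10% divergence.
    """
    params = params or AlignParams()
    aligner = aligner or SeededAligner(k=params.uniqueness_kmer)
    hits = aligner.search(candidate, target_genome, index=index)
    needed = params.near_match_identity * len(candidate)
    loci = [h for h in hits if h.matches >= needed - 1e-9]
    if len(loci) != 1:
        return None
    return loci[0].interval


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def migrate_probes(
    probes: Iterable[Probe],
    template_genome: GenomeAssembly,
    target_genome: GenomeAssembly,
    thermo_params: thermo.ThermoParams | None = None,
    align_params: AlignParams | None = None,
) -> tuple[list[MigrationRecord], Ledger]:
    """Run the full migration cascade over a probe set.

    Per-probe failures become record statuses, never exceptions.  The
    cascade per probe: no_alignment → exact_match → direct_ortholog →
    adjusted → failed_adjust, then a uniqueness remap that demotes
    non-unique successes to ambiguous_map.  Deterministic: identical
    inputs and parameters give identical records.
    """
    tparams = thermo_params or thermo.ThermoParams()
    aparams = align_params or AlignParams()
    aligner = SeededAligner(k=aparams.kmer)
    search_index = aligner.index(target_genome)
    unique_aligner = SeededAligner(k=aparams.uniqueness_kmer)
    unique_index = unique_aligner.index(target_genome)

    records: list[MigrationRecord] = []
    for probe in probes:
        if probe.tm is None or probe.gc is None:
            probe.gc = thermo.gc_content(probe.sequence)
            probe.tm = thermo.melting_temperature(probe.sequence, tparams)
        records.append(
            _migrate_one(
                probe, template_genome, target_genome, tparams, aparams,
                aligner, search_index, unique_aligner, unique_index,
            )
        )
    return records, Ledger.from_records(records)


def _migrate_one(
    probe: Probe,
    template_genome: GenomeAssembly,
    target_genome: GenomeAssembly,
    tparams: thermo.ThermoParams,
    aparams: AlignParams,
    aligner: SeededAligner,
    search_index: KmerIndex,
    unique_aligner: SeededAligner,
    unique_index: KmerIndex,
) -> MigrationRecord:
    ext_seq, core_offset, _ = extend_probe(probe, template_genome, aparams.flank)

    status, hit = find_ortholog(
        ext_seq, target_genome, aparams, aligner, search_index
    )
    if status != "hit":
        note = "primary ortholog search ambiguous" if status == "ambiguous_map" else ""
        return MigrationRecord(probe.id, status, notes=note)

    core = extract_core(
        hit, core_offset, len(probe.sequence), target_genome,
        aparams.min_core_coverage,
    )
    if core is None:
        return MigrationRecord(
            probe.id, "no_alignment", identity=hit.identity,
            notes="ortholog alignment does not cover the probe core",
        )
    core_seq, core_iv = core

    candidate: Probe | None = None
    if core_seq == probe.sequence:
        cls = "exact_match"
        candidate = Probe(probe.id, core_iv, core_seq, tm=probe.tm, gc=probe.gc)
    else:
        direct = None
        if "N" not in core_seq and tparams.min_len <= len(core_seq) <= tparams.max_len:
            gc = thermo.gc_content(core_seq)
            tm = thermo.melting_temperature(core_seq, tparams)
            if (
                abs(tm - probe.tm) <= tparams.tm_tolerance
                and abs(gc - probe.gc) <= tparams.gc_tolerance
            ):
                direct = Probe(probe.id, core_iv, core_seq, tm=tm, gc=gc)
        if direct is not None:
            cls, candidate = "direct_ortholog", direct
        else:
            chrom_len = target_genome.lengths[core_iv.chrom]
            ctx_start = max(0, core_iv.start - aparams.flank)
            ctx_end = min(chrom_len, core_iv.end + aparams.flank)
            context = target_genome.fetch(
                GenomicInterval(core_iv.chrom, ctx_start, ctx_end, "+")
            )
            adjusted = thermo.adjust_probe(
                (core_iv.start - ctx_start, core_iv.end - ctx_start),
                context,
                probe,
                tparams,
                chrom=core_iv.chrom,
                context_offset=ctx_start,
            )
            if adjusted is None:
                return MigrationRecord(
                    probe.id, "failed_adjust", identity=hit.identity,
                    notes="target composition precludes a Tm/GC-matched probe",
                )
            cls, candidate = "adjusted", adjusted

    locus = verify_unique(
        candidate.sequence, target_genome, aparams, unique_aligner, unique_index
    )
    if locus is None:
        return MigrationRecord(
            probe.id, "ambiguous_map", identity=hit.identity,
            candidate_class=cls, notes="candidate maps to 0 or >1 target loci",
        )
    return MigrationRecord(
        probe.id, cls, target_probe=candidate, identity=hit.identity
    )


def write_records(records: Sequence[MigrationRecord], path: str | Path) -> None:
    """Records as TSV, target coordinates in 1-based inclusive form."""
    rows = []
    for r in records:
        p = r.target_probe
        rows.append(
            {
                "id": r.template_id,
                "status": r.status,
                "candidate_class": r.candidate_class or "",
                "target_chrom": p.interval.chrom if p else "",
                "target_start": p.interval.start_1based if p else "",
                "target_end": p.interval.end_1based if p else "",
                "sequence": p.sequence if p else "",
                "tm": f"{p.tm:.2f}" if p and p.tm is not None else "",
                "gc": f"{p.gc:.4f}" if p and p.gc is not None else "",
                "identity": f"{r.identity:.4f}" if r.identity is not None else "",
                "notes": r.notes,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
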