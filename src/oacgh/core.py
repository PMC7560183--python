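"""Shared domain types, coordinate conventions and plain-text I/O.

Internal coordinates are 0-based half-open throughout the package.  All
file input/output and printed reports use 1-based inclusive coordinates,
the convention of genome browsers and of the positional statements this
toolkit is meant to reproduce; conversion happens only at the I/O border.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "GenomeAssembly",
    "GenomicInterval",
    "Probe",
    "GeneAnnotation",
    "ParseError",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_probes",
    "write_probes",
    "read_genes_bed",
    "reverse_complement",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


class ValidationError(ValueError):
    """Raised when data violates a domain invariant."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_sequence(raw: str) -> str:
    """Uppercase and map any non-ACGTN character to N."""
    seq = raw.upper()
    if set(seq) <= _VALID:
        return seq
    return re.sub(r"[^ACGTN]", "N", seq)


@dataclass(frozen=True)
class GenomicInterval:
    """A location on a named sequence, 0-based half-open.

    ``strand`` is '+', '-' or '.' (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    # -- printed (1-based inclusive) form ---------------------------------
    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end

    @classmethod
    def from_1based(
        cls, chrom: str, start1: int, end1: int, strand: str = "."
    ) -> "GenomicInterval":
        return cls(chrom, start1 - 1, end1, strand)

    def span_bp(self) -> int:
        """Printed span: distance between the 1-based endpoints."""
        return self.end_1based - self.start_1based

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start_1based:,}-{self.end_1based:,}"


class GenomeAssembly:
    """A named set of chromosome/scaffold sequences held in memory.

    Sequences are uppercase strings over {A,C,G,T,N}.  Suited to the
    desk-scale assemblies this toolkit works with; random access is by
    plain slicing.
    """

    def __init__(self, name: str, sequences: Mapping[str, str]):
        if not sequences:
            raise ValidationError(f"assembly {name!r} has no sequences")
        cleaned: dict[str, str] = {}
        for chrom, seq in sequences.items():
            if not seq:
                raise ValidationError(f"sequence {chrom!r} is empty")
            cleaned[chrom] = _clean_sequence(seq)
        self.name = name
        self.sequences = cleaned

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def fetch(self, interval: GenomicInterval) -> str:
        """Extract the sequence of an interval, reverse-complemented for '-'."""
        if interval.chrom not in self.sequences:
            raise ValidationError(f"unknown sequence {interval.chrom!r}")
        seq = self.sequences[interval.chrom]
        if interval.end > len(seq):
            raise ValidationError(
                f"interval {interval} exceeds length of {interval.chrom} "
                f"({len(seq)} bp)"
            )
        sub = seq[interval.start : interval.end]
        if interval.strand == "-":
            sub = reverse_complement(sub)
        return sub

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenomeAssembly({self.name!r}, {len(self.sequences)} sequences)"


@dataclass
class Probe:
    """A located oligonucleotide with its thermodynamic attributes.

    ``tm`` (degrees Celsius) and ``gc`` (fraction in [0, 1]) are computed
    from ``sequence`` when a thermodynamic parameter set is at hand; they
    may be None for probes read from coordinate-only files without an
    attached genome.
    """

    id: str
    interval: GenomicInterval
    sequence: str
    tm: float | None = None
    gc: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != len(self.interval):
            raise ValidationError(
                f"probe {self.id}: sequence length {len(self.sequence)} != "
                f"interval length {len(self.interval)}"
            )

    def validate_against(self, genome: GenomeAssembly) -> None:
        expected = genome.fetch(self.interval)
        if expected != self.sequence:
            raise ValidationError(
                f"probe {self.id}: sequence disagrees with genome substring "
                f"at {self.interval}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    symbol: str
    interval: GenomicInterval


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a plain FASTA file into a :class:`GenomeAssembly`.

    Sequences are uppercased and non-ACGTN characters become N.  A header
    problem or an empty file raises :class:`ParseError` naming the line.
    """
    path = Path(path)
    name: str | None = None
    chunks: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                if header in chunks:
                    raise ParseError(
                        f"{path}: duplicate sequence name {header!r} at line {lineno}"
                    )
                name = header
                chunks[name] = []
                order.append(name)
            else:
                if name is None:
                    raise ParseError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks[name].append(line.strip())
    if not order:
        raise ParseError(f"{path}: empty FASTA file (no records)")
    sequences = {c: "".join(parts) for c, parts in chunks.items()}
    for c, s in sequences.items():
        if not s:
            raise ParseError(f"{path}: record {c!r} has no sequence")
    return GenomeAssembly(path.stem, sequences)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in assembly.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Probe tables (TSV / BED-like)
# ---------------------------------------------------------------------------

PROBE_COLUMNS = ["id", "chrom", "start", "end", "sequence", "tm", "gc"]


def read_probes(
    path: str | Path,
    genome: GenomeAssembly | None = None,
    coords: str = "1-based",
    thermo_params=None,
) -> list[Probe]:
    """Read a probe table (TSV with header: id, chrom, start, end[, sequence]).

    ``coords`` declares the file's coordinate convention: "1-based"
    (inclusive, the printed form; the default for our own exports) or
    "0-based" (half-open).  If a genome is supplied and the sequence
    column is missing, sequences are extracted from it; a present
    sequence column is validated against the genome.  Tm/GC are computed
    when ``thermo_params`` is given.  Output is sorted by (chrom, start).
    """
    if coords not in ("1-based", "0-based"):
        raise ValueError(f"coords must be '1-based' or '0-based', got {coords!r}")
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    required = {"id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing probe columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"{path}: duplicate probe id(s): {dupes[:5]}")

    probes: list[Probe] = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if coords == "1-based":
            interval = GenomicInterval.from_1based(row.chrom, start, end)
        else:
            interval = GenomicInterval(row.chrom, start, end)
        if genome is not None:
            if interval.chrom not in genome:
                raise ValidationError(
                    f"probe {row.id}: unknown chromosome {interval.chrom!r}"
                )
            if interval.end > genome.lengths[interval.chrom]:
                raise ValidationError(
                    f"probe {row.id}: interval {interval} outside chromosome"
                )
        seq = getattr(row, "sequence", None)
        if seq is None or (isinstance(seq, float) and pd.isna(seq)):
            if genome is None:
                raise ValidationError(
                    f"probe {row.id}: no sequence column and no genome supplied"
                )
            seq = genome.fetch(interval)
        probe = Probe(str(row.id), interval, str(seq))
        if genome is not None:
            probe.validate_against(genome)
        probes.append(probe)

    if thermo_params is not None:
        from . import thermo

        for p in probes:
            p.gc = thermo.gc_content(p.sequence)
            p.tm = thermo.melting_temperature(p.sequence, thermo_params)

    probes.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return probes


def write_probes(probes: Iterable[Probe], path: str | Path) -> None:
    """Write probes as TSV in 1-based inclusive coordinates."""
    rows = [
        {
            "id": p.id,
            "chrom": p.interval.chrom,
            "start": p.interval.start_1based,
            "end": p.interval.end_1based,
            "sequence": p.sequence,
            "tm": "" if p.tm is None else f"{p.tm:.2f}",
            "gc": "" if p.gc is None else f"{p.gc:.4f}",
        }
        for p in probes
    ]
    pd.DataFrame(rows, columns=PROBE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from BED4 (chrom, start, end, name; 0-based)."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: BED line {lineno} has <4 fields")
            chrom, start, end, symbol = parts[0], int(parts[1]), int(parts[2]), parts[3]
            genes.append(GeneAnnotation(symbol, GenomicInterval(chrom, start, end)))
    return genes
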