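"""The probe-migration cascade and its stage accounting."""

from collections import Counter

import pytest

from oacgh import synthetic, thermo
from oacgh.align import SeededAligner
from oacgh.core import GenomeAssembly, GenomicInterval, Probe, ValidationError
from oacgh.migration import (
    AlignParams,
    Ledger,
    MigrationRecord,
    extend_probe,
    extract_core,
    find_ortholog,
    migrate_probes,
    verify_unique,
)

TPARAMS = thermo.ThermoParams()

STATUS_TO_FATE = {
    "exact_match": "conserved",
    "direct_ortholog": "diverged",
    "adjusted": "diverged",
    "failed_adjust": "diverged",
    "no_alignment": "missing",
    "ambiguous_map": "duplicated",
}


def _probe_at(genome, chrom, start, end, pid="p"):
    iv = GenomicInterval(chrom, start, end, "+")
    seq = genome.fetch(iv)
    return Probe(pid, iv, seq, tm=thermo.melting_temperature(seq, TPARAMS),
                 gc=thermo.gc_content(seq))


class TestExtendProbe:
    def test_standard_extension_is_260nt_with_core_at_100(self, tiny_genome):
        p = _probe_at(tiny_genome, "chr1", 1000, 1060)
        seq, offset, iv = extend_probe(p, tiny_genome, flank=100)
        assert len(seq) == 260
        assert offset == 100
        assert (iv.start, iv.end) == (900, 1160)
        assert seq == tiny_genome.sequences["chr1"][900:1160]
        assert seq[100:160] == p.sequence

    def test_left_flank_clipped_at_chromosome_start(self, tiny_genome):
        p = _probe_at(tiny_genome, "chr1", 30, 90)
        seq, offset, iv = extend_probe(p, tiny_genome, flank=100)
        assert offset == 30
        assert iv.start == 0
        assert len(seq) == 190

    def test_right_flank_clipped_at_chromosome_end(self, tiny_genome):
        L = tiny_genome.lengths["chr2"]
        p = _probe_at(tiny_genome, "chr2", L - 70, L - 10)
        seq, offset, iv = extend_probe(p, tiny_genome, flank=100)
        assert iv.end == L
        assert seq == tiny_genome.sequences["chr2"][L - 170:]


class TestFindOrtholog:
    def test_identical_target_gives_perfect_hit(self, tiny_genome):
        p = _probe_at(tiny_genome, "chr1", 2000, 2060)
        ext, _, src = extend_probe(p, tiny_genome)
        status, hit = find_ortholog(ext, tiny_genome)
        assert status == "hit"
        assert hit.identity == 1.0
        assert hit.interval.chrom == "chr1"
        assert hit.interval.start == src.start

    def test_unrelated_target_gives_no_alignment(self, tiny_genome, rng):
        decoy = GenomeAssembly("d", {"s": "".join(rng.choice(list("ACGT"), 4000))})
        p = _probe_at(tiny_genome, "chr1", 2000, 2060)
        ext, _, _ = extend_probe(p, tiny_genome)
        status, hit = find_ortholog(ext, decoy)
        assert status == "no_alignment" and hit is None

    def test_verbatim_duplication_is_ambiguous(self, tiny_genome):
        chunk = tiny_genome.sequences["chr1"][1900:2400]
        dup = GenomeAssembly("d", {"s1": chunk, "s2": chunk})
        p = _probe_at(tiny_genome, "chr1", 2000, 2060)
        ext, _, _ = extend_probe(p, tiny_genome)
        status, _ = find_ortholog(ext, dup)
        assert status == "ambiguous_map"

    def test_empty_genome_is_an_error(self, tiny_genome):
        p = _probe_at(tiny_genome, "chr1", 2000, 2060)
        ext, _, _ = extend_probe(p, tiny_genome)
        with pytest.raises((ValidationError, TypeError)):
            find_ortholog(ext, None)


class TestExtractCore:
    def test_gap_free_alignment_recovers_colinear_core(self, tiny_genome):
        p = _probe_at(tiny_genome, "chr1", 2000, 2060)
        ext, off, _ = extend_probe(p, tiny_genome)
        _, hit = find_ortholog(ext, tiny_genome)
        core = extract_core(hit, off, 60, tiny_genome)
        assert core is not None
        seq, iv = core
        assert seq == p.sequence
        assert (iv.start, iv.end) == (2000, 2060)

    def test_deletion_inside_core_shrinks_it(self, tiny_genome):
        src = tiny_genome.sequences["chr1"]
        # target = chr1 with a 3-nt deletion inside the probe core
        target = GenomeAssembly("t", {"c": src[:2020] + src[2023:]})
        p = _probe_at(tiny_genome, "chr1", 2000, 2060)
        ext, off, _ = extend_probe(p, tiny_genome)
        status, hit = find_ortholog(ext, target)
        assert status == "hit"
        seq, iv = extract_core(hit, off, 60, target)
        assert len(seq) == 57
        assert len(iv) == 57

    def test_random_indels_match_column_walk_oracle(self, tiny_genome, rng):
        """Extracted interval equals replaying the column map by hand."""
        src = tiny_genome.sequences["chr1"]
        edited = src[:1985] + src[1985:2100:][::1]  # no-op guard
        target_seq = src[:2010] + "TT" + src[2010:2040] + src[2043:]
        target = GenomeAssembly("t", {"c": target_seq})
        p = _probe_at(tiny_genome, "chr1", 2000, 2060)
        ext, off, _ = extend_probe(p, tiny_genome)
        status, hit = find_ortholog(ext, target)
        assert status == "hit"
        core = extract_core(hit, off, 60, target)
        assert core is not None
        seq, iv = core
        cols = [t for q, t in hit.column_map if off <= q < off + 60]
        assert iv.start == min(cols) and iv.end == max(cols) + 1
        assert seq == target_seq[iv.start:iv.end]

    def test_unaligned_core_returns_none(self, tiny_genome):
        p = _probe_at(tiny_genome, "chr1", 2000, 2060)
        ext, off, _ = extend_probe(p, tiny_genome)
        _, hit = find_ortholog(ext, tiny_genome)
        # pretend the core sits outside the aligned columns
        assert extract_core(hit, 10_000, 60, tiny_genome) is None


def _hamming_loci(candidate: str, genome: GenomeAssembly, max_frac: float):
    """Exhaustive substitution-only scan: all loci within the identity
    threshold, as an independent locus-count oracle."""
    L = len(candidate)
    max_mm = int(max_frac * L)
    loci = []
    for chrom, seq in genome.sequences.items():
        for i in range(len(seq) - L + 1):
            mm = sum(a != b for a, b in zip(candidate, seq[i : i + L]))
            if mm <= max_mm:
                loci.append((chrom, i))
    # merge overlapping windows into loci
    merged = []
    for chrom, i in loci:
        if merged and merged[-1][0] == chrom and i - merged[-1][1] < L:
            continue
        merged.append((chrom, i))
    return merged


class TestVerifyUnique:
    def test_single_copy_is_unique(self, tiny_genome):
        cand = tiny_genome.sequences["chr1"][3000:3060]
        iv = verify_unique(cand, tiny_genome)
        assert iv is not None and iv.start == 3000

    def test_two_copies_are_ambiguous(self, tiny_genome):
        cand = tiny_genome.sequences["chr1"][3000:3060]
        dup = GenomeAssembly(
            "d",
            {"s1": tiny_genome.sequences["chr1"],
             "s2": "TTTT" + cand + "TTTT"},
        )
        assert verify_unique(cand, dup) is None

    def test_92_percent_near_match_trips_ambiguity(self, tiny_genome, rng):
        cand = tiny_genome.sequences["chr1"][3000:3060]
        near = list(cand)
        for pos in rng.choice(60, size=4, replace=False):  # ~93% identity
            near[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[near[pos]]
        genome = GenomeAssembly(
            "d", {"s1": tiny_genome.sequences["chr1"], "s2": "".join(near)}
        )
        oracle = _hamming_loci(cand, genome, 1 - 0.9)
        assert len(oracle) == 2
        assert verify_unique(cand, genome) is None

    def test_count_agrees_with_exhaustive_scan(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=2_000))
        cand = base[500:560]
        genome = GenomeAssembly("g", {"s": base})
        assert len(_hamming_loci(cand, genome, 0.1)) == 1
        assert verify_unique(cand, genome) is not None


@pytest.fixture(scope="module")
def identity_run():
    import numpy as np

    rng = np.random.default_rng(5)
    genome = GenomeAssembly(
        "g", {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}
    )
    probes = synthetic.simulate_probes(genome, spacing=1_000, seed=2,
                                       thermo_params=TPARAMS)
    records, ledger = migrate_probes(probes, genome, genome)
    return probes, records, ledger


class TestMigratePipeline:

    def test_identity_genome_all_exact(self, identity_run):
        probes, records, ledger = identity_run
        assert all(r.status == "exact_match" for r in records)
        assert ledger.final_probes == ledger.total == len(probes)

    def test_every_probe_has_exactly_one_record(self, identity_run):
        probes, records, ledger = identity_run
        assert sorted(r.template_id for r in records) == sorted(p.id for p in probes)

    def test_determinism(self, identity_run):
        import numpy as np

        rng = np.random.default_rng(5)
        genome = GenomeAssembly(
            "g", {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}
        )
        probes = synthetic.simulate_probes(genome, spacing=1_000, seed=2,
                                           thermo_params=TPARAMS)
        records2, _ = migrate_probes(probes, genome, genome)
        _, records1, _ = identity_run
        assert [(r.template_id, r.status) for r in records1] == [
            (r.template_id, r.status) for r in records2
        ]

    def test_synthetic_divergence_recovers_truth_fates(self):
        tpl, tgt, truth = synthetic.simulate_genome_pair(
            n_chrom=2, lengths=40_000, substitution_rate=0.03,
            indel_rate=0.002, deleted_fraction=0.08,
            duplicated_fraction=0.05, seed=42,
        )
        probes = synthetic.simulate_probes(tpl, spacing=1_500, seed=1,
                                           thermo_params=TPARAMS)
        records, ledger = migrate_probes(probes, tpl, tgt)
        fates = [truth.expected_probe_fate(p) for p in probes]
        agree = sum(
            STATUS_TO_FATE[r.status] == f for r, f in zip(records, fates)
        )
        assert agree / len(probes) >= 0.95
        # ledger conservation and class arithmetic
        assert ledger.total == len(probes)
        assert ledger.candidates == (
            ledger.exact_match + ledger.direct_ortholog + ledger.adjusted
        )
        assert ledger.final_probes == ledger.candidates - ledger.ambiguous_map

    def test_emitted_probes_satisfy_contracts(self):
        tpl, tgt, _ = synthetic.simulate_genome_pair(
            n_chrom=1, lengths=30_000, substitution_rate=0.03,
            indel_rate=0.002, deleted_fraction=0.0, duplicated_fraction=0.0,
            seed=9,
        )
        probes = synthetic.simulate_probes(tpl, spacing=1_500, seed=3,
                                           thermo_params=TPARAMS)
        records, _ = migrate_probes(probes, tpl, tgt)
        for r, p in zip(records, probes):
            if r.target_probe is None:
                continue
            out = r.target_probe
            assert verify_unique(out.sequence, tgt) is not None
            assert out.sequence == tgt.fetch(out.interval)
            if r.status != "exact_match":
                assert abs(out.tm - p.tm) <= TPARAMS.tm_tolerance
                assert abs(out.gc - p.gc) <= TPARAMS.gc_tolerance


class TestLedger:
    def test_published_stage_arithmetic(self):
        ledger = Ledger(
            total=171_534, no_alignment=58_255, exact_match=1_512,
            direct_ortholog=83_488, adjusted=27_400, failed_adjust=879,
            ambiguous_map=1_944,
        )
        assert ledger.successful_alignments == 113_279
        assert round(100 * ledger.failure_rate) == 34
        assert ledger.candidates == 112_400
        assert ledger.adjust_attempted == 28_279
        assert ledger.final_probes == 110_456

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError, match="stage counts"):
            Ledger(total=100, no_alignment=10, exact_match=10,
                   direct_ortholog=10, adjusted=10, failed_adjust=10,
                   ambiguous_map=0)

    def test_ambiguous_bounded_by_candidates(self):
        with pytest.raises(ValidationError, match="ambiguous"):
            Ledger(total=40, no_alignment=10, exact_match=10,
                   direct_ortholog=10, adjusted=5, failed_adjust=5,
                   ambiguous_map=30)

    def test_record_invariant_probe_present_iff_success(self, tiny_genome):
        with pytest.raises(ValidationError):
            MigrationRecord("x", "no_alignment",
                            target_probe=_probe_at(tiny_genome, "chr1", 0, 60))
        with pytest.raises(ValidationError):
            MigrationRecord("x", "adjusted", target_probe=None)
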