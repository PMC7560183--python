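"""GC/Tm computation and the thermodynamic adjustment search."""

import math

import numpy as np
import pytest

from oacgh.core import GenomicInterval, Probe, ValidationError, reverse_complement
from oacgh.thermo import ThermoParams, adjust_probe, gc_content, melting_temperature

PARAMS = ThermoParams()


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 0.5), ("GGCC", 1.0), ("ATAT", 0.0)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_random_sequence_matches_character_count(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        by_hand = sum(1 for c in seq if c in "GC") / 60
        assert gc_content(seq) == pytest.approx(by_hand, abs=0)

    def test_reverse_complement_invariance(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            assert gc_content(seq) == pytest.approx(
                gc_content(reverse_complement(seq))
            )

    @pytest.mark.parametrize("bad", ["", "ACGN", "ACGX"])
    def test_rejects_empty_and_non_acgt(self, bad):
        with pytest.raises(ValidationError):
            gc_content(bad)


# Published unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K),
# used as an independent hand computation of the duplex Tm.
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    # reverse-complement equivalents
    "TT": (-7.9, -22.2), "TG": (-8.5, -22.7), "AC": (-8.4, -22.4),
    "AG": (-7.8, -21.0), "TC": (-8.2, -22.2), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)


def _nn_tm_by_hand(seq: str, params: ThermoParams) -> float:
    """Table-sum Tm: ΔH·1000 / (ΔS + R·ln k) − 273.15, with the
    0.368·(N−1)·ln[Na+] entropic salt correction."""
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        inc = _INIT_AT if end in "AT" else _INIT_GC
        dh += inc[0]
        ds += inc[1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(params.na_mM / 1000.0)
    k = (params.dnac1_nM - params.dnac2_nM / 2.0) * 1e-9
    return 1000.0 * dh / (ds + 1.987 * math.log(k)) - 273.15


class TestMeltingTemperature:
    def test_gc_raises_tm(self):
        assert melting_temperature("G" * 30 + "C" * 30) > melting_temperature(
            "A" * 30 + "T" * 30
        )

    def test_matches_hand_table_sum_on_20mer(self):
        seq = "ATGCAGGTCCTTAGCATGCA"  # fixed, non-self-complementary
        assert melting_temperature(seq, PARAMS) == pytest.approx(
            _nn_tm_by_hand(seq, PARAMS), abs=0.5
        )

    def test_matches_hand_table_sum_on_random_sequences(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 70))))
            assert melting_temperature(seq, PARAMS) == pytest.approx(
                _nn_tm_by_hand(seq, PARAMS), abs=0.5
            )

    def test_gc_rich_extension_does_not_decrease_tm(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            assert melting_temperature(seq + "GCGCGCGC") >= melting_temperature(seq) - 1e-9

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            assert melting_temperature(seq) == pytest.approx(
                melting_temperature(reverse_complement(seq)), abs=1e-6
            )

    def test_typical_60mers_fall_in_array_design_band(self, rng):
        """AT-rich ~36%-GC 60-mers should melt in the 71-85 °C band."""
        tms = []
        for _ in range(20):
            n_gc = int(rng.integers(19, 25))
            chars = ["G", "C"] * (n_gc // 2) + ["A", "T"] * ((60 - n_gc) // 2)
            rng.shuffle(chars)
            tms.append(melting_temperature("".join(chars[:60]), PARAMS))
        assert 71 <= np.mean(tms) <= 85

    def test_short_sequence_rejected(self):
        with pytest.raises(ValidationError):
            melting_temperature("ACGTACG")


def _template(seq: str) -> Probe:
    return Probe(
        "tpl", GenomicInterval("t", 0, len(seq), "+"), seq,
        tm=melting_temperature(seq, PARAMS), gc=gc_content(seq),
    )


def _brute_force_windows(core, context, template, params):
    """Every (start, end) window overlapping the core, within length
    bounds and N-free, that satisfies both tolerance predicates."""
    cs, ce = core
    feasible = []
    for start in range(0, ce):
        for end in range(max(cs + 1, start + params.min_len),
                         min(len(context), start + params.max_len) + 1):
            w = context[start:end]
            if "N" in w:
                continue
            tm = melting_temperature(w, params)
            gc = gc_content(w)
            if (
                abs(tm - template.tm) <= params.tm_tolerance
                and abs(gc - template.gc) <= params.gc_tolerance
            ):
                feasible.append((start, end))
    return feasible


class TestAdjustProbe:
    def test_core_within_tolerance_returned_unchanged(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        tpl = _template(seq)
        context = "".join(rng.choice(list("ACGT"), size=50)) + seq + "".join(
            rng.choice(list("ACGT"), size=50)
        )
        out = adjust_probe((50, 110), context, tpl, PARAMS)
        assert out is not None
        assert out.sequence == seq
        assert (out.interval.start, out.interval.end) == (50, 110)

    def test_at_only_context_cannot_match_hot_template(self, rng):
        """A GC-rich template has no thermodynamic match in AT-only
        sequence: the unadjustable-region failure class."""
        tpl = _template("GC" * 30)
        context = "".join(rng.choice(list("AT"), size=200))
        assert adjust_probe((70, 130), context, tpl, PARAMS) is None

    def test_result_agrees_with_exhaustive_enumeration(self, rng):
        params = ThermoParams(min_len=20, max_len=40)
        hits = 0
        for trial in range(8):
            context = "".join(rng.choice(list("ACGT"), size=120))
            template_seq = "".join(rng.choice(list("ACGT"), size=30))
            tpl = Probe(
                "t", GenomicInterval("t", 0, 30, "+"), template_seq,
                tm=melting_temperature(template_seq, params),
                gc=gc_content(template_seq),
            )
            core = (45, 75)
            feasible = _brute_force_windows(core, context, tpl, params)
            got = adjust_probe(core, context, tpl, params)
            if feasible:
                hits += 1
                assert got is not None
                w = (got.interval.start, got.interval.end)
                assert w in feasible
                if core in feasible:
                    # identity takes precedence: feasible core is unchanged
                    assert w == core
                else:
                    # optimality: no feasible window has smaller |dTm|
                    best_dtm = min(
                        abs(melting_temperature(context[s:e], params) - tpl.tm)
                        for s, e in feasible
                    )
                    assert abs(got.tm - tpl.tm) == pytest.approx(best_dtm, abs=1e-9)
            else:
                assert got is None
        assert hits > 0  # the comparison actually exercised feasible cases

    def test_never_extends_beyond_context_and_meets_tolerances(self, rng):
        for _ in range(5):
            context = "".join(rng.choice(list("ACGT"), size=200))
            tpl = _template(context[70:130])
            out = adjust_probe((72, 128), context, tpl, PARAMS)
            if out is None:
                continue
            assert 0 <= out.interval.start < out.interval.end <= len(context)
            assert abs(out.tm - tpl.tm) <= PARAMS.tm_tolerance
            assert abs(out.gc - tpl.gc) <= PARAMS.gc_tolerance

    def test_core_outside_context_is_an_error(self):
        tpl = _template("ACGT" * 15)
        with pytest.raises(ValidationError):
            adjust_probe((10, 80), "ACGTACGT", tpl, PARAMS)
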