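"""Degenerate-word semantics: compilation, matching, strandedness, rates."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from octsox.motifs import (
    IUPAC_SETS,
    compile_iupac,
    expected_hit_rate,
    matches_at,
    patterns_disjoint,
    reverse_complement,
    scan_sequence,
)

from conftest import PROBES

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


def naive_iupac_match(pattern: str, seq: str, offset: int) -> bool:
    """Independent position-by-position oracle using the IUPAC table."""
    if offset + len(pattern) > len(seq):
        return False
    return all(seq[offset + i] in IUPAC_SETS[c] for i, c in enumerate(pattern))


def naive_scan(pattern: str, seq: str):
    """Brute-force both-strand scan used as the oracle for the fast path."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(seq))
    L = len(pattern)
    hits = []
    for k in range(len(seq) - L + 1):
        if naive_iupac_match(pattern, seq, k):
            hits.append((k, "+"))
        if naive_iupac_match(pattern, rc, len(seq) - L - k):
            hits.append((k, "-"))
    return sorted(set(hits))


class TestCompile:
    def test_full_degeneracy(self):
        m = compile_iupac("N")
        assert m.length == 1 and m.allowed == (frozenset("ACGT"),)

    def test_composite_word_fixed_core(self, motifs):
        m = motifs["Hoxb1-like"]
        assert m.length == 15
        # the OCT half-site anchor ATG occupies positions 8-10 (1-based)
        assert m.allowed[7:10] == (frozenset("A"), frozenset("T"), frozenset("G"))

    def test_pattern_roundtrip_identity(self, motifs):
        for m in motifs.values():
            assert compile_iupac(m.pattern).pattern == m.pattern

    @pytest.mark.parametrize("bad,pos", [("ATGX", 4), ("U", 1), ("AC-G", 3)])
    def test_invalid_symbol_reports_position(self, bad, pos):
        with pytest.raises(ValueError, match=f"position {pos}"):
            compile_iupac(bad)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            compile_iupac("")


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expect", [("ATGC", "GCAT"), ("", ""),
                                            ("CTTTGTCATGCTAAT", "ATTAGCATGACAAAG")])
    def test_known_values(self, seq, expect):
        assert reverse_complement(seq) == expect

    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="'N'"):
            reverse_complement("ACGN")


class TestMatchesAt:
    def test_probe_core_matches_its_class(self, motifs):
        core = "CTTTGTCATGCTAAT"
        assert matches_at(motifs["Hoxb1-like"], core, 0)
        # Utf1-like requires G at the position where the core carries A
        assert not matches_at(motifs["Utf1-like"], core, 0)

    def test_out_of_range_offset_rejected(self, motifs):
        with pytest.raises(ValueError):
            matches_at(motifs["Hoxb1-like"], "ACGT", 0)

    @given(st.data())
    def test_sampled_expansion_matches_by_construction(self, motifs, data):
        m = motifs["Fgf4-like"]
        seq = "".join(data.draw(st.sampled_from(sorted(s))) for s in m.allowed)
        assert matches_at(m, seq, 0)
        assert naive_iupac_match(m.pattern, seq, 0)

    def test_non_acgt_position_never_matches(self, motifs):
        m = motifs["Hoxb1-like"]
        assert not matches_at(m, "CTTTGTCATGCTANT", 0)


class TestScanSequence:
    @pytest.mark.parametrize(
        "probe,cls,offset,matched",
        [
            ("HOXB1", "Hoxb1-like", 11, "CTTTGTCATGCTAAT"),
            ("UTF1", "Utf1-like", 18, "CATTGTTATGCTAGT"),
            ("FGF4", "Fgf4-like", 13, "CTTTGTTTGGATGCTAAT"),
        ],
    )
    def test_probe_single_hit(self, motifs, probe, cls, offset, matched):
        hits = scan_sequence(motifs[cls], PROBES[probe], strands="both")
        assert [(h.offset, h.strand, h.matched_seq) for h in hits] == [(offset, "+", matched)]
        assert naive_scan(motifs[cls].pattern, PROBES[probe]) == [(offset, "+")]

    def test_no_cross_class_probe_hits(self, motifs):
        assert scan_sequence(motifs["Utf1-like"], PROBES["HOXB1"], strands="both") == []

    def test_short_sequence_yields_no_hits(self, motifs):
        assert scan_sequence(motifs["Hoxb1-like"], "ACGT", strands="both") == []

    @given(dna)
    def test_matches_bruteforce_oracle(self, motifs, seq):
        for m in motifs.values():
            got = [(h.offset, h.strand) for h in scan_sequence(m, seq, strands="both")]
            assert got == naive_scan(m.pattern, seq)

    @given(st.text(alphabet="ACGT", min_size=15, max_size=80))
    def test_strand_equivalence(self, motifs, seq):
        """Minus-strand hits are forward hits on the reverse complement."""
        m = motifs["Hoxb1-like"]
        minus = [h.offset for h in scan_sequence(m, seq, strands="both") if h.strand == "-"]
        fwd_on_rc = [h.offset for h in scan_sequence(m, reverse_complement(seq), strands="forward")]
        assert sorted(minus) == sorted(len(seq) - m.length - k for k in fwd_on_rc)

    @given(st.text(alphabet="ACGT", min_size=3, max_size=40))
    def test_concrete_pattern_equals_substring_count(self, seq):
        m = compile_iupac("ATA")
        fwd = [h for h in scan_sequence(m, seq, strands="forward")]
        naive = sum(seq[k : k + 3] == "ATA" for k in range(len(seq) - 2))
        assert len(fwd) == naive

    @given(st.text(alphabet="ACGTN", min_size=15, max_size=60))
    def test_hoxb1_utf1_never_cooccur(self, motifs, seq):
        h = {(x.offset, x.strand) for x in scan_sequence(motifs["Hoxb1-like"], seq)}
        u = {(x.offset, x.strand) for x in scan_sequence(motifs["Utf1-like"], seq)}
        assert not (h & u)


class TestPatternsDisjoint:
    def test_hoxb1_utf1_disjoint(self, motifs):
        assert patterns_disjoint(motifs["Hoxb1-like"], motifs["Utf1-like"])

    def test_self_not_disjoint(self, motifs):
        assert not patterns_disjoint(motifs["Hoxb1-like"], motifs["Hoxb1-like"])

    def test_overlapping_degeneracy_not_disjoint(self):
        assert not patterns_disjoint(compile_iupac("AN"), compile_iupac("NT"))

    def test_unequal_lengths_rejected(self, motifs):
        with pytest.raises(ValueError):
            patterns_disjoint(motifs["Hoxb1-like"], motifs["Fgf4-like"])


class TestExpectedHitRate:
    def test_normalisation_and_closed_forms(self, motifs):
        uniform = [0.25] * 4
        assert expected_hit_rate(compile_iupac("N"), uniform) == 1.0
        assert expected_hit_rate(compile_iupac("ATG"), uniform) == pytest.approx(4.0**-3)
        assert expected_hit_rate(motifs["Hoxb1-like"], uniform) == pytest.approx(6912 / 4**15)

    def test_enumeration_oracle_biased_background(self):
        """Exhaustive enumeration over all 3-mers agrees with the product."""
        p = {"A": 0.1, "C": 0.2, "G": 0.3, "T": 0.4}
        m = compile_iupac("RYW")
        total = 0.0
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    if naive_iupac_match("RYW", a + b + c, 0):
                        total += p[a] * p[b] * p[c]
        assert expected_hit_rate(m, [p[b] for b in "ACGT"]) == pytest.approx(total)

    def test_malformed_probs_rejected(self, motifs):
        with pytest.raises(ValueError):
            expected_hit_rate(motifs["Hoxb1-like"], [0.5, 0.5, 0.5, -0.5])
        with pytest.raises(ValueError):
            expected_hit_rate(motifs["Hoxb1-like"], [0.3, 0.3, 0.3, 0.3])
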