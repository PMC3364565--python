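"""Codon-level impact, BLOSUM62 conservation, and the protein-level table."""

import itertools

import pytest

from mutspec.genome import GeneModel, GenomeModel, revcomp
from mutspec.protein import (
    ProteinImpactRecord,
    classify_conservation,
    codon_effect,
    protein_table,
)

# Independent oracle: the standard nuclear genetic code, hard-coded.
_AA = (
    "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLLEDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF"
)
_ORDER = "ACGT"
GENETIC_CODE = {
    a + b + c: _AA[16 * _ORDER.index(a) + 4 * _ORDER.index(b) + _ORDER.index(c)]
    for a in _ORDER
    for b in _ORDER
    for c in _ORDER
}


def test_oracle_table_sanity():
    assert GENETIC_CODE["ATG"] == "M"
    assert GENETIC_CODE["TAA"] == GENETIC_CODE["TAG"] == GENETIC_CODE["TGA"] == "*"
    assert GENETIC_CODE["TGG"] == "W"
    assert GENETIC_CODE["GGA"] == "G"


def _single_codon_genome(codon: str, strand: str = "+") -> tuple[GenomeModel, int]:
    """Genome whose only gene is ATG-<codon>-TAA; returns it and the genomic
    coordinate of the test codon's first base on the coding strand."""
    cds = "ATG" + codon + "TAA"
    flank = "A" * 20
    if strand == "+":
        seq = flank + cds + flank
        start = len(flank) + 1
        ivs = ((start, start + 8),)
        codon_start = start + 3
    else:
        seq = flank + revcomp(cds) + flank
        start = len(flank) + 1
        ivs = ((start, start + 8),)
        codon_start = start + 5  # genomic position pairing with coding pos 4
    gene = GeneModel("g1", "chr1", strand, ivs, promoter_length=5, terminator_length=5)
    return GenomeModel([("chr1", seq)], [gene]), codon_start


COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestCodonEffectExhaustive:
    def test_all_64x9_changes_match_genetic_code_oracle(self):
        """Every single-base change of every codon gets the oracle's effect."""
        for codon in GENETIC_CODE:
            genome, codon_start = _single_codon_genome(codon)
            for offset, alt in itertools.product(range(3), "ACGT"):
                ref = codon[offset]
                if alt == ref:
                    continue
                pos = codon_start + offset
                recp = codon_effect(("chr1", pos, ref, alt), genome)
                alt_codon = codon[:offset] + alt + codon[offset + 1 :]
                ref_aa, alt_aa = GENETIC_CODE[codon], GENETIC_CODE[alt_codon]
                if alt_aa == "*" and ref_aa != "*":
                    expected = "stop_gained"
                elif ref_aa == alt_aa:
                    expected = "preserved"
                else:
                    expected = "changed"
                assert recp.effect == expected, (codon, offset, alt)
                assert recp.ref_aa == ref_aa and recp.alt_aa == alt_aa
                assert recp.codon_index == 2
                assert recp.codon_position == offset + 1

    def test_minus_strand_matches_plus_strand(self):
        """Effect on a minus-strand gene equals the plus-strand computation
        after reverse-complementing the locus."""
        for codon in ("GGA", "TGG", "CTG", "TAT", "CCA"):
            plus, plus_start = _single_codon_genome(codon, "+")
            minus, minus_anchor = _single_codon_genome(codon, "-")
            for offset, alt in itertools.product(range(3), "ACGT"):
                ref = codon[offset]
                if alt == ref:
                    continue
                p_rec = codon_effect(("chr1", plus_start + offset, ref, alt), plus)
                # same coding change seen from the genome's plus strand
                g_pos = minus_anchor - offset
                m_rec = codon_effect(
                    ("chr1", g_pos, COMP[ref], COMP[alt]), minus
                )
                assert (m_rec.effect, m_rec.ref_aa, m_rec.alt_aa) == (
                    p_rec.effect, p_rec.ref_aa, p_rec.alt_aa,
                )
                assert m_rec.codon_position == p_rec.codon_position
                assert m_rec.ref_codon == p_rec.ref_codon


class TestCodonEffectExamples:
    def test_wobble_synonymy_preserved(self):
        genome, start = _single_codon_genome("GGA")
        rec = codon_effect(("chr1", start + 2, "A", "G"), genome)
        assert rec.effect == "preserved"
        assert rec.ref_aa == rec.alt_aa == "G"

    def test_trp_to_stop(self):
        genome, start = _single_codon_genome("TGG")
        rec = codon_effect(("chr1", start + 2, "G", "A"), genome)
        assert rec.effect == "stop_gained" and rec.alt_aa == "*"

    def test_stop_to_stop_is_preserved(self):
        genome, start = _single_codon_genome("GGA")
        # mutate the terminal TAA (codon 3) at wobble: TAA→TAG, stop→stop
        rec = codon_effect(("chr1", start + 5, "A", "G"), genome)
        assert rec.ref_aa == "*" and rec.alt_aa == "*"
        assert rec.effect == "preserved"

    def test_reference_mismatch_detected(self):
        genome, start = _single_codon_genome("GGA")
        with pytest.raises(ValueError, match="reference mismatch"):
            codon_effect(("chr1", start, "T", "C"), genome)

    def test_position_outside_cds_rejected(self):
        genome, _ = _single_codon_genome("GGA")
        with pytest.raises(ValueError, match="no CDS"):
            codon_effect(("chr1", 1, "A", "G"), genome)

    def test_strand_invariance_on_generated_genome(self, toy_genome):
        """Impacts are unchanged when the whole genome is reverse-complemented."""
        rc = toy_genome.reverse_complemented()
        n = len(toy_genome.contig_sequence("chr1"))
        gene = toy_genome.genes[0]
        s, e = gene.cds_intervals[0]
        seq = toy_genome.contig_sequence("chr1")
        for pos in range(s, min(s + 30, e + 1)):
            ref = seq[pos - 1]
            alt = "A" if ref != "A" else "G"
            fwd = codon_effect(("chr1", pos, ref, alt), toy_genome)
            rev = codon_effect(
                ("chr1", n - pos + 1, COMP[ref], COMP[alt]), rc
            )
            assert (fwd.effect, fwd.ref_aa, fwd.alt_aa, fwd.codon_position) == (
                rev.effect, rev.ref_aa, rev.alt_aa, rev.codon_position,
            )


class TestClassifyConservation:
    def test_leu_met_conservative(self):
        kind, score = classify_conservation("L", "M")
        assert kind == "conservative" and score > 0

    def test_gly_trp_nonconservative(self):
        kind, score = classify_conservation("G", "W")
        assert kind == "nonconservative" and score <= 0

    def test_identity_is_an_error(self):
        with pytest.raises(ValueError, match="not an amino-acid change"):
            classify_conservation("A", "A")

    def test_stop_is_an_error(self):
        with pytest.raises(ValueError, match="stop"):
            classify_conservation("A", "*")


def impact(effect, ref_aa="A", alt_aa="V", codon_position=1, conservation=None):
    if conservation is None:
        conservation = "not_applicable" if effect != "changed" else "nonconservative"
    return ProteinImpactRecord(
        gene_id="g", codon_index=1, codon_position=codon_position,
        ref_codon="NNN", alt_codon="NNN", ref_aa=ref_aa, alt_aa=alt_aa,
        effect=effect, blosum_score=None, conservation=conservation,
    )


class TestProteinTable:
    def test_percentage_denominators(self):
        records = (
            [impact("preserved", "G", "G")] * 2
            + [impact("changed", "L", "M", conservation="conservative")] * 4
            + [impact("changed", "D", "E", conservation="nonconservative")] * 18
            + [impact("changed", "G", "W", conservation="nonconservative")] * 2
            + [impact("stop_gained", "W", "*")] * 2
        )
        t = protein_table(records)
        p = t.percentages()
        assert t.total == 28
        assert p["changed"] == 85.7
        assert p["preserved"] == 7.1 and p["stop"] == 7.1
        assert p["nonconservative"] == 83.3
        # structure indicator over (changed + stop): (2 stops + 2 Gly/Pro)/26
        assert t.stop_and_glypro == 4
        assert p["stop_and_glypro"] == 15.4
        assert p["stop_of_indicator"] == 50.0 and p["glypro_of_indicator"] == 50.0

    def test_single_stop_record(self):
        t = protein_table([impact("stop_gained", "W", "*")])
        p = t.percentages()
        assert p["stop"] == 100.0 and p["stop_and_glypro"] == 100.0

    def test_empty_input_all_zero(self):
        t = protein_table([])
        assert t.total == t.changed == t.stop == t.stop_and_glypro == 0

    def test_glypro_direction_options(self):
        records = [impact("changed", "G", "W"), impact("changed", "W", "P"),
                   impact("changed", "L", "M", conservation="conservative")]
        assert protein_table(records, glypro_direction="either").stop_and_glypro == 2
        assert protein_table(records, glypro_direction="from").stop_and_glypro == 1
        assert protein_table(records, glypro_direction="to").stop_and_glypro == 1

    def test_percentage_blocks_sum_to_100(self):
        records = (
            [impact("preserved", "G", "G", codon_position=3)] * 7
            + [impact("changed", "A", "T", codon_position=1)] * 11
            + [impact("changed", "P", "S", codon_position=2)] * 5
            + [impact("stop_gained", "Q", "*", codon_position=1)] * 3
        )
        p = protein_table(records).percentages()
        assert p["preserved"] + p["changed"] + p["stop"] == pytest.approx(100, abs=0.2)
        assert (
            p["codon_position_1"] + p["codon_position_2"] + p["codon_position_3"]
            == pytest.approx(100, abs=0.2)
        )
        assert p["conservative"] + p["nonconservative"] == pytest.approx(100, abs=0.2)
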