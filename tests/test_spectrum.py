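"""Substitution-class pooling and gene-feature assignment."""

import itertools

import pytest

from mutspec.filtering import VariantRecord
from mutspec.genome import GeneModel, GenomeModel
from mutspec.spectrum import (
    CLASS_LABELS,
    FeatureAssignment,
    assign_feature,
    classify_substitution,
    feature_counts,
    spectrum_summary,
)

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def snv(ref, alt, contig="chr1", pos=1):
    return VariantRecord(
        contig=contig, pos=pos, ref=ref, alt=alt, depth=50,
        variant_quality=60.0, mapping_quality=50.0, variant_allele_fraction=1.0,
    )


class TestClassifySubstitution:
    def test_g_to_a_is_gc_at_transition(self):
        c = classify_substitution("G", "A")
        assert c.label == "G:C>A:T" and c.is_transition

    def test_complementary_changes_pool(self):
        assert classify_substitution("A", "C") == classify_substitution("T", "G")
        assert classify_substitution("A", "C").label == "A:T>C:G"

    def test_all_twelve_pairs_cover_six_classes_twice(self):
        counts = {}
        for ref, alt in itertools.permutations("ACGT", 2):
            label = classify_substitution(ref, alt).label
            counts[label] = counts.get(label, 0) + 1
        assert counts == dict.fromkeys(CLASS_LABELS, 2)

    def test_two_transitions_four_transversions(self):
        labels = [classify_substitution(r, a) for r, a in itertools.permutations("ACGT", 2)]
        ti = {c.label for c in labels if c.is_transition}
        tv = {c.label for c in labels if not c.is_transition}
        assert len(ti) == 2 and len(tv) == 4

    def test_complement_symmetry_for_all_pairs(self):
        for ref, alt in itertools.permutations("ACGT", 2):
            assert (
                classify_substitution(ref, alt)
                == classify_substitution(COMP[ref], COMP[alt])
            )

    @pytest.mark.parametrize("ref, alt", [("A", "A"), ("N", "A"), ("A", "N")])
    def test_invalid_input_raises(self, ref, alt):
        with pytest.raises(ValueError):
            classify_substitution(ref, alt)


class TestSpectrumSummary:
    def test_all_transition_set(self):
        calls = [snv("G", "A")] * 97 + [snv("A", "G")] * 3
        s = spectrum_summary(calls)
        assert s.transition_fraction == pytest.approx(1.0)
        assert s.counts["G:C>A:T"] == 97

    def test_one_of_each_class(self):
        calls = [snv("A", "G"), snv("G", "A"), snv("A", "T"),
                 snv("A", "C"), snv("G", "T"), snv("G", "C")]
        s = spectrum_summary(calls)
        assert all(f == pytest.approx(1 / 6) for f in s.frequencies.values())
        assert s.transition_fraction + s.transversion_fraction == pytest.approx(1.0)

    def test_empty_input_reports_not_available(self):
        s = spectrum_summary([])
        assert s.total == 0
        assert s.frequencies is None and s.transition_fraction is None

    def test_frequencies_sum_to_one(self):
        calls = [snv("G", "A")] * 5 + [snv("A", "C")] * 3
        assert sum(spectrum_summary(calls).frequencies.values()) == pytest.approx(1.0)

    def test_invariant_to_sample_pooling_order(self):
        a = [snv("G", "A"), snv("A", "C")]
        b = [snv("G", "T")]
        assert spectrum_summary(a + b).counts == spectrum_summary(b + a).counts


def _flat_genome():
    """Two plus/minus genes on an all-A backdrop with known geometry."""
    seq = ["A"] * 10_000
    # plus-strand gene: CDS 3001..3300; minus-strand gene: CDS 6001..6300
    orf = "ATG" + "GCT" * 98 + "TAA"
    seq[3000:3300] = list(orf)
    from mutspec.genome import revcomp

    seq[6000:6300] = list(revcomp(orf))
    genes = [
        GeneModel("plus", "chr1", "+", ((3001, 3300),),
                  promoter_length=1000, terminator_length=200),
        GeneModel("minus", "chr1", "-", ((6001, 6300),),
                  promoter_length=1000, terminator_length=200),
    ]
    return GenomeModel([("chr1", "".join(seq))], genes)


class TestAssignFeature:
    @pytest.fixture(scope="class")
    @staticmethod
    def genome():
        return _flat_genome()

    def test_inside_cds_is_exon(self, genome):
        assert assign_feature("chr1", 3150, genome) == FeatureAssignment("exon", "plus")

    def test_upstream_of_plus_gene_is_promoter(self, genome):
        a = assign_feature("chr1", 3001 - 500, genome)
        assert a == FeatureAssignment("promoter", "plus")

    def test_promoter_is_strand_aware_for_minus_gene(self, genome):
        # upstream of a minus-strand gene = to the right of its 3' end
        a = assign_feature("chr1", 6300 + 500, genome)
        assert a == FeatureAssignment("promoter", "minus")

    def test_downstream_is_terminator(self, genome):
        assert assign_feature("chr1", 3300 + 100, genome).feature == "terminator"
        assert assign_feature("chr1", 6001 - 100, genome) == FeatureAssignment(
            "terminator", "minus"
        )

    def test_far_away_is_intergenic(self, genome):
        assert assign_feature("chr1", 9999, genome).feature == "intergenic"

    def test_unknown_contig_raises(self, genome):
        with pytest.raises(KeyError):
            assign_feature("chrX", 100, genome)

    def test_intron_between_cds_intervals(self, intron_genome):
        gene = intron_genome.genes[0]
        (s1, e1), (s2, _) = gene.cds_intervals
        pos = (e1 + s2) // 2
        a = assign_feature(gene.contig, pos, intron_genome)
        assert a == FeatureAssignment("intron", gene.gene_id)

    def test_exon_beats_neighbouring_promoter(self):
        """Exonic position inside another gene's promoter margin → exon."""
        seq = ["A"] * 5000
        orf = "ATG" + "GCT" * 31 + "TAA"  # 99 bases
        seq[1000:1099] = list(orf)
        seq[1500:1599] = list(orf)
        genes = [
            GeneModel("a", "chr1", "+", ((1001, 1099),)),
            GeneModel("b", "chr1", "+", ((1501, 1599),)),
        ]
        genome = GenomeModel([("chr1", "".join(seq))], genes)
        # position inside gene a's CDS, also within 1 kb upstream of gene b
        assert assign_feature("chr1", 1050, genome) == FeatureAssignment("exon", "a")

    def test_overlapping_margins_nearest_gene_wins(self):
        seq = "A" * 5000
        orf_len = 99
        genes = [
            GeneModel("left", "chr1", "+", ((1001, 1001 + orf_len - 1),)),
            GeneModel("right", "chr1", "+", ((1401, 1401 + orf_len - 1),)),
        ]
        # between genes: left's terminator (1100..1299) overlaps right's
        # promoter (401..1400); promoter takes precedence over terminator
        genome = GenomeModel([("chr1", seq)], genes)
        a = assign_feature("chr1", 1150, genome)
        assert a.feature == "promoter" and a.gene_id == "right"

    def test_assignment_partitions_positions(self, toy_genome):
        positions = range(1, len(toy_genome.contig_sequence("chr1")) + 1, 97)
        assigns = [assign_feature("chr1", p, toy_genome) for p in positions]
        counts = feature_counts(assigns)
        assert sum(counts.values()) == len(assigns)


class TestStrandSymmetry:
    def test_spectrum_unchanged_under_reverse_complement(self, toy_genome):
        """Reverse-complementing genome and calls leaves the spectrum fixed."""
        from mutspec.simulate import MutagenProfile, sample_mutations

        muts = sample_mutations(toy_genome, MutagenProfile.mutator(), 300, seed=13)
        calls = [snv(ref, alt, contig, pos) for contig, pos, ref, alt in muts]
        n = len(toy_genome.contig_sequence("chr1"))
        rc_calls = [
            snv(COMP[c.ref], COMP[c.alt], c.contig, n - c.pos + 1) for c in calls
        ]
        assert spectrum_summary(calls).counts == spectrum_summary(rc_calls).counts

    def test_feature_counts_unchanged_under_reverse_complement(self, toy_genome):
        rc = toy_genome.reverse_complemented()
        n = len(toy_genome.contig_sequence("chr1"))
        positions = range(1, n + 1, 53)
        fwd = feature_counts(assign_feature("chr1", p, toy_genome) for p in positions)
        rev = feature_counts(
            assign_feature("chr1", n - p + 1, rc) for p in positions
        )
        assert fwd == rev
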