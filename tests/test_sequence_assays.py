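"""In-silico PCR and codon-level substitution annotation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.Seq import Seq

import phagerm as pm
from phagerm.genome import reverse_complement
from phagerm.sequence_assays import Consequence, TemplateOrientation


FWD = pm.OMLO707  # TGCATGGCTTGTTTTGCTAAAGC (23 nt)
REV = pm.OMLO708  # ACAAGCWGGACAACCGTCTTGGT (23 nt, degenerate W)


def template_from_parts(fwd_seq: str, insert: str, rev_seq: str) -> pm.GenomeRecord:
    return pm.GenomeRecord("t", fwd_seq + insert + reverse_complement(rev_seq))


class TestFindAmplicons:
    def test_constructed_353bp_product(self):
        """23-nt primers + 307-nt insert = the diagnostic 353-bp product."""
        t = pm.make_pcr_template(FWD, REV, insert_len=307, seed=5)
        (amp,) = pm.find_amplicons(t, FWD, REV)
        assert amp.length == 353

    def test_minimal_template_exact_arithmetic(self):
        fwd_seq = FWD.sequence
        rev_seq = REV.sequence.replace("W", "A")
        t = template_from_parts(fwd_seq, "C" * 307, rev_seq)
        (amp,) = pm.find_amplicons(t, FWD, REV)
        assert (amp.start, amp.end, amp.length) == (1, 353, 353)

    @pytest.mark.parametrize("w_base", ["A", "T"])
    def test_degenerate_w_position_accepts_both(self, w_base):
        rev_seq = REV.sequence.replace("W", w_base)
        t = template_from_parts(FWD.sequence, "ACGT" * 10, rev_seq)
        (amp,) = pm.find_amplicons(t, FWD, REV)
        assert amp.length == 23 + 40 + 23

    def test_degenerate_w_rejects_other_bases(self):
        for w_base in "CG":
            rev_seq = REV.sequence.replace("W", w_base)
            t = template_from_parts(FWD.sequence, "ACGT" * 10, rev_seq)
            assert pm.find_amplicons(t, FWD, REV) == []

    def test_no_product_when_primers_point_outward(self):
        # reverse footprint upstream of the forward footprint: no product
        rev_seq = REV.sequence.replace("W", "A")
        t = pm.GenomeRecord(
            "t", reverse_complement(rev_seq) + "ACGT" * 10 + FWD.sequence
        )
        assert pm.find_amplicons(t, FWD, REV) == []

    def test_reverse_complemented_template_found_with_flipped_orientation(self):
        t = pm.make_pcr_template(FWD, REV, insert_len=100, seed=3)
        rc = t.reverse_complement()
        (amp,) = pm.find_amplicons(rc, FWD, REV)
        assert amp.length == 146
        assert amp.template_orientation is TemplateOrientation.REVERSE_COMPLEMENTED

    def test_mismatch_allowance(self):
        fwd_seq = FWD.sequence
        mutated = "A" + fwd_seq[1:]  # one mismatch vs the primer (T->A)
        rev_seq = REV.sequence.replace("W", "T")
        t = template_from_parts(mutated, "C" * 50, rev_seq)
        assert pm.find_amplicons(t, FWD, REV, max_mismatch=0) == []
        (amp,) = pm.find_amplicons(t, FWD, REV, max_mismatch=1)
        assert amp.length == 23 + 50 + 23

    @given(insert_len=st.integers(0, 2000), seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_generated_template_yields_one_product_of_known_length(self, insert_len, seed):
        t = pm.make_pcr_template(FWD, REV, insert_len, seed=seed)
        amps = pm.find_amplicons(t, FWD, REV)
        assert [a.length for a in amps] == [23 + insert_len + 23]

    @given(insert_len=st.integers(0, 500), seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_orientation_symmetry(self, insert_len, seed):
        t = pm.make_pcr_template(FWD, REV, insert_len, seed=seed)
        lengths = [a.length for a in pm.find_amplicons(t, FWD, REV)]
        lengths_rc = [a.length for a in pm.find_amplicons(t.reverse_complement(), FWD, REV)]
        assert lengths == lengths_rc

    def test_invalid_primer_rejected(self):
        with pytest.raises(ValueError):
            pm.Primer("bad", "ACGTX")
        with pytest.raises(ValueError):
            pm.Primer("empty", "")


class TestAnnotateCdsSubstitution:
    def test_nonsense_truncation_arithmetic(self):
        """G>T at nt 1252 of a 1356-nt CDS: GGA(Gly418) -> TGA, 34 residues lost."""
        cds = pm.make_cds_with_codon(451, 418, "GGA", seed=7)
        ann = pm.annotate_cds_substitution(cds, 1252, "T")
        assert ann.codon_index == 418
        assert (ann.ref_codon, ann.alt_codon) == ("GGA", "TGA")
        assert (ann.ref_aa, ann.alt_aa) == ("G", "*")
        assert ann.consequence is Consequence.NONSENSE
        assert ann.residues_lost == 34

    def test_synonymous_third_position(self):
        cds = pm.make_cds_with_codon(10, 4, "GGA", seed=0)
        ann = pm.annotate_cds_substitution(cds, 12, "G")  # GGA -> GGG, both Gly
        assert ann.consequence is Consequence.SYNONYMOUS
        assert ann.residues_lost is None

    def test_missense(self):
        cds = pm.make_cds_with_codon(10, 4, "GGA", seed=0)
        ann = pm.annotate_cds_substitution(cds, 10, "A")  # GGA -> AGA, Gly -> Arg
        assert ann.consequence is Consequence.MISSENSE
        assert (ann.ref_aa, ann.alt_aa) == ("G", "R")

    @pytest.mark.parametrize("pos", [0, -3, 10_000])
    def test_position_out_of_range(self, pos):
        cds = pm.make_cds_with_codon(10, 4, "GGA", seed=0)
        with pytest.raises(ValueError):
            pm.annotate_cds_substitution(cds, pos, "T")

    def test_alt_equal_to_reference_rejected(self):
        cds = pm.make_cds_with_codon(10, 4, "GGA", seed=0)
        with pytest.raises(ValueError, match="10"):
            pm.annotate_cds_substitution(cds, 10, "G")

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            pm.annotate_cds_substitution("ATGGG", 2, "A")

    def test_missing_start_codon_warns(self):
        with pytest.warns(UserWarning):
            pm.annotate_cds_substitution("CCCGGATAA", 4, "T")

    @given(
        protein_length=st.integers(2, 200),
        codon_index=st.integers(2, 200),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_nonsense_truncates_translation_to_codon_index_minus_one(
        self, protein_length, codon_index, seed
    ):
        codon_index = min(codon_index, protein_length)
        cds = pm.make_cds_with_codon(protein_length, codon_index, "GGA", seed=seed)
        pos = (codon_index - 1) * 3 + 1
        ann = pm.annotate_cds_substitution(cds, pos, "T")  # GGA -> TGA
        assert ann.consequence is Consequence.NONSENSE
        mutated = cds[: pos - 1] + "T" + cds[pos:]
        protein = str(Seq(mutated).translate(table=11, to_stop=True))
        assert len(protein) == ann.codon_index - 1
        assert ann.residues_lost == protein_length - codon_index + 1
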