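"""Outcome enumeration, consequence annotation and mutagenesis coverage."""

import itertools

import numpy as np
import pytest

from bescan.editors import get_editor
from bescan.edit_prediction import (
    Consequence,
    PRIORITY_ORDER,
    PredictedOutcome,
    Variant,
    aa_coverage,
    annotate,
    enumerate_outcomes,
    prioritize,
)
from bescan.guide_design import Guide, enumerate_guides, profile_guide
from conftest import random_gene
from oracles import CODON_TABLE, oracle_revcomp

CBE = get_editor("BE3-NGG")
YE1 = get_editor("YE1-BE4max-NGN")


def mk_guide(protospacer, pam="AGG", start=0, strand="+", contig="c"):
    return Guide("g1", protospacer, pam, contig, start, strand)


class TestEnumerateOutcomes:
    def test_two_editable_cs_give_singles_plus_joint(self):
        g = mk_guide("ATTACTTCTTAAATTAAATT")  # Cs at 5 and 8 (window 4-9)
        outs = enumerate_outcomes(g, CBE)
        assert [sorted(o.edited_positions) for o in outs] == [[5], [8], [5, 8]]

    def test_single_editable_c(self):
        g = mk_guide("ATTACTTTTTAAATTAAATT")
        assert len(enumerate_outcomes(g, CBE)) == 1

    def test_ye1_narrow_window_excludes_position_8(self):
        g = mk_guide("ATTACTTCTTAAATTAAATT", pam="AGT")  # Cs at 5 and 8
        outs = enumerate_outcomes(g, YE1)
        assert len(outs) == 1
        assert all(o.edited_positions <= {5, 6, 7} for o in outs)

    @pytest.mark.parametrize("k", [0, 1, 2, 3, 4, 5, 6])
    def test_outcome_count_is_k_plus_joint(self, k):
        proto = list("ATTATTATTATTATTATTAT")
        for p in range(4, 4 + k):
            proto[p - 1] = "C"
        outs = enumerate_outcomes(mk_guide("".join(proto)), CBE)
        assert len(outs) == k + (1 if k >= 2 else 0)

    def test_combinatorial_flag_enumerates_all_subsets(self):
        g = mk_guide("ATTCCCTTTTAAATTAAATT")  # Cs at 4,5,6
        outs = enumerate_outcomes(g, CBE, combinatorial=True)
        assert len(outs) == 2**3 - 1

    def test_pam_incompatible_with_editor_raises(self):
        g = mk_guide("ATTACTTCTTAAATTAAATT", pam="ATT")
        with pytest.raises(ValueError, match="PAM"):
            enumerate_outcomes(g, CBE)

    def test_minus_strand_variants_are_g_to_a_on_reference(self):
        contigs = {"c": "T" * 60}
        seq = list(contigs["c"])
        # put a minus-strand guide at start=20 with a C at protospacer pos 5
        # → reference holds G at genomic position 20 + 20 - 5 = 35
        seq[35] = "G"
        contigs = {"c": "".join(seq)}
        proto = oracle_revcomp(contigs["c"][20:40])
        g = Guide("gm", proto, "AGG", "c", 20, "-")
        outs = enumerate_outcomes(g, CBE, contigs=contigs)
        assert len(outs) == 1
        (v,) = outs[0].variants
        assert (v.pos, v.ref, v.alt) == (35, "G", "A")


class TestPrioritize:
    def test_order_on_all_pairs(self):
        for a, b in itertools.combinations(PRIORITY_ORDER, 2):
            assert prioritize([a, b]) == a
            assert prioritize([b, a]) == a

    def test_associative_over_multiset_union(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            xs = list(rng.choice(PRIORITY_ORDER, 3))
            ys = list(rng.choice(PRIORITY_ORDER, 2))
            assert prioritize([prioritize(xs)] + ys) == prioritize(xs + ys)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            prioritize([])


class TestAnnotate:
    def test_caa_to_taa_is_stop_gained(self, toy_contigs, toy_gene):
        # CDS codon 4 is CAA at genomic [61,64); C→T makes TAA
        out = PredictedOutcome("g", frozenset({5}), (Variant("chr1", 61, "C", "T"),))
        ann = annotate(out, toy_gene, toy_contigs)
        assert ann.consequence == Consequence.STOP_GAINED
        assert [(c.residue, c.ref_aa, c.alt_aa) for c in ann.protein_changes] == [(4, "Q", "*")]

    def test_donor_plus_one_g_to_a_is_splice_variant(self, toy_contigs, toy_gene):
        # intron starts GT at genomic 41; G→A as seen from a minus-strand guide
        out = PredictedOutcome("g", frozenset({6}), (Variant("chr1", 41, "G", "A"),))
        ann = annotate(out, toy_gene, toy_contigs)
        assert ann.consequence == Consequence.SPLICE_VARIANT
        assert ann.protein_changes == ()

    def test_synonymous_third_position_edit(self, toy_contigs, toy_gene):
        # codon 5 GGG at [64,67); G→A at third base gives GGA, still Gly
        out = PredictedOutcome("g", frozenset({1}), (Variant("chr1", 66, "G", "A"),))
        ann = annotate(out, toy_gene, toy_contigs)
        assert ann.consequence == Consequence.SYNONYMOUS

    def test_start_codon_edit_is_start_lost(self, toy_contigs, toy_gene):
        out = PredictedOutcome("g", frozenset({1}), (Variant("chr1", 32, "A", "G"),))
        ann = annotate(out, toy_gene, toy_contigs)
        assert ann.consequence == Consequence.START_LOST

    def test_utr_edit(self, toy_contigs, toy_gene):
        out = PredictedOutcome("g", frozenset({1}), (Variant("chr1", 25, "T", "C"),))
        assert annotate(out, toy_gene, toy_contigs).consequence == Consequence.UTR

    def test_ref_mismatch_is_fatal(self, toy_contigs, toy_gene):
        out = PredictedOutcome("g", frozenset({1}), (Variant("chr1", 32, "C", "T"),))
        with pytest.raises(ValueError, match="out of sync"):
            annotate(out, toy_gene, toy_contigs)

    def test_protein_changes_match_retranslation_oracle(self):
        """200 random single/joint outcomes vs independent apply-and-retranslate."""
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 200:
            contigs, gene = random_gene(rng, n_codons=30)
            guides = enumerate_guides(contigs, gene.chrom, pam_pattern="NGN")
            for guide in guides:
                outs = enumerate_outcomes(guide, get_editor("BE3.9max-NGN"), contigs=contigs)
                for out in outs:
                    ann = annotate(out, gene, contigs)
                    expected = self._oracle_changes(contigs[gene.chrom], gene, out)
                    got = [(c.residue, c.ref_aa, c.alt_aa) for c in ann.protein_changes]
                    assert got == expected
                    checked += 1
                    if checked >= 200:
                        return

    @staticmethod
    def _oracle_changes(seq, gene, outcome):
        def protein_of(s):
            cds = ""
            for a, b in gene.exons:
                lo, hi = max(a, gene.cds_span[0]), min(b, gene.cds_span[1])
                if lo < hi:
                    cds += s[lo:hi]
            if gene.strand == "-":
                cds = oracle_revcomp(cds)
            return "".join(CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds) - 2, 3))

        mutant = list(seq)
        for v in outcome.variants:
            assert mutant[v.pos] == v.ref
            mutant[v.pos] = v.alt
        ref_p, alt_p = protein_of(seq), protein_of("".join(mutant))
        return [
            (i + 1, a, b) for i, (a, b) in enumerate(zip(ref_p, alt_p)) if a != b
        ]

    def test_annotation_self_consistency(self, toy_contigs, toy_gene):
        """Re-applying an annotated outcome's variants reproduces its
        protein changes (round-trip on every guide of the toy locus)."""
        guides = enumerate_guides(toy_contigs, "chr1", pam_pattern="NGG")
        for guide in guides:
            for out in enumerate_outcomes(guide, CBE, contigs=toy_contigs):
                ann = annotate(out, toy_gene, toy_contigs)
                again = annotate(out, toy_gene, toy_contigs)
                assert ann.protein_changes == again.protein_changes
                assert ann.consequence == again.consequence


class TestCoverage:
    def test_empty_guide_list_is_zero(self, toy_contigs, toy_gene):
        cov = aa_coverage(toy_gene, toy_contigs, {"CBE": (CBE, [])})
        assert cov["CBE"] == 0.0

    def test_union_is_monotone(self):
        rng = np.random.default_rng(23)
        contigs, gene = random_gene(rng, n_codons=30)
        cbe_g = enumerate_guides(contigs, gene.chrom, pam_pattern="NGN")
        abe = get_editor("ABE8e-NGN")
        cov = aa_coverage(
            gene, contigs,
            {"CBE": (get_editor("BE3.9max-NGN"), cbe_g), "ABE": (abe, cbe_g)},
        )
        assert cov["union"] >= max(cov["CBE"], cov["ABE"])
        assert cov["union"] <= cov["CBE"] + cov["ABE"] + 1e-12

    def test_coverage_matches_exhaustive_enumeration(self):
        """10-codon gene, all NGG guides: coverage equals a test-side
        enumeration of every guide × outcome with oracle translation."""
        rng = np.random.default_rng(31)
        contigs, gene = random_gene(rng, n_exons=1, n_codons=10)
        guides = enumerate_guides(contigs, gene.chrom, pam_pattern="NGG")
        cov = aa_coverage(gene, contigs, {"CBE": (CBE, guides)}, include_union=False)

        touched = set()
        for guide in guides:
            for out in enumerate_outcomes(guide, CBE, contigs=contigs):
                for res, ref, alt in TestAnnotate._oracle_changes(
                    contigs[gene.chrom], gene, out
                ):
                    if res <= 9:  # 10 codons incl. stop → 9 residues
                        touched.add(res)
        assert cov["CBE"] == pytest.approx(len(touched) / 9)
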