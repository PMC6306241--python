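import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import (
    deletion_placements,
    enumerate_semiglobal_score,
    insertion_placements,
    scalar_semiglobal_score,
)
from allelecrispr import (
    AmpliconAligner,
    IndelDescriptor,
    apply_indel,
    assign_allele,
    extract_indels,
    left_normalize_indel,
    normalize_alignment,
)
from allelecrispr.align import Alignment
from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=1)


class TestAligner:
    def test_exact_substring_is_all_match(self, target):
        read = target.reference[37:187]
        aln = AmpliconAligner(target.reference).align(read)
        assert aln.cigar == (("M", 150),)
        assert aln.ref_start == 37
        assert aln.score == 2 * 150

    def test_two_base_deletion_recovered(self, target):
        ref = target.reference
        mol = ref[:116] + ref[118:]
        read = mol[60:210]
        aligner = AmpliconAligner(ref)
        aln = aligner.align(read)
        assert [op for op, _ in aln.cigar].count("D") == 1
        assert dict(aln.cigar).get("D") == 2
        assert aln.score == scalar_semiglobal_score(read, ref)

    def test_unrelated_read_fails_score_floor(self, target, rng):
        junk = random_dna(rng, 150)
        assert AmpliconAligner(target.reference).align(junk) is None

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_score_matches_scalar_dp_oracle(self, data):
        """Exact optimality on random instances (read <= 30 nt, ref <= 60 nt)."""
        ref = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=60))
        mode = data.draw(st.sampled_from(["random", "derived"]))
        if mode == "random":
            read = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=30))
        else:  # mutated substring: realistic near-reference reads
            start = data.draw(st.integers(0, max(0, len(ref) - 25)))
            read = ref[start : start + 25]
            if len(read) >= 22 and data.draw(st.booleans()):
                cutpos = data.draw(st.integers(1, len(read) - 2))
                read = read[:cutpos] + read[cutpos + 2 :]
        aligner = AmpliconAligner(ref, floor_frac=float("-inf"))
        aln = aligner.align(read)
        assert aln.score == scalar_semiglobal_score(read, ref)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_score_matches_alignment_enumeration_on_tiny_inputs(self, data):
        ref = data.draw(st.text(alphabet="ACGT", min_size=3, max_size=8))
        read = data.draw(st.text(alphabet="ACGT", min_size=2, max_size=5))
        aln = AmpliconAligner(ref, floor_frac=float("-inf")).align(read)
        assert aln.score == enumerate_semiglobal_score(read, ref)

    def test_cigar_tiles_query_and_score_is_consistent(self, target, rng):
        ref = target.reference
        aligner = AmpliconAligner(ref, floor_frac=0.0)
        for _ in range(20):
            start = int(rng.integers(0, 50))
            read = list(ref[start : start + 120])
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(0, len(read)))
                read[i] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            aln = aligner.align(read)
            assert aln.query_span() == len(read)
            # recompute the score from the alignment itself
            score = 0
            for rp, qi in aln.columns():
                if rp is not None and qi is not None:
                    score += 2 if read[qi] == ref[rp] else -4
            for op, n in aln.cigar:
                if op in "ID":
                    score += -6 - n
            assert score == aln.score


class TestNormalization:
    def test_homopolymer_deletion_left_shifts(self):
        ref = "TTCAAAGTT"
        # delete the last A (position 5): equivalent to deleting the first (3)
        aln = Alignment("TTCAAGTT", 0, (("M", 5), ("D", 1), ("M", 3)), 0)
        norm = normalize_alignment(aln, ref)
        assert norm.indels() == (IndelDescriptor("del", 3, 1),)

    def test_no_indel_alignment_unchanged(self, target):
        aln = Alignment(target.reference[:50], 0, (("M", 50),), 100)
        assert normalize_alignment(aln, target.reference) is aln

    def test_idempotent_and_query_preserving(self, target, rng):
        ref = target.reference
        aligner = AmpliconAligner(ref)
        for _ in range(20):
            length = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                start = int(rng.integers(5, len(ref) - 160))
                mol = ref[:start] + ref[start + length :]
            else:
                start = int(rng.integers(5, len(ref) - 160))
                ins = random_dna(rng, length)
                mol = ref[:start] + ins + ref[start:]
            read = mol[:150]
            aln = aligner.align(read)
            once = normalize_alignment(aln, ref)
            twice = normalize_alignment(once, ref)
            assert once.cigar == twice.cigar
            assert once.query == aln.query
            assert "".join(
                read[qi] for _, qi in once.columns() if qi is not None
            ) == read

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_normalized_start_is_minimum_of_equivalence_class(self, data):
        """In repeat contexts the normalized indel equals the smallest-start
        placement among all placements yielding the same edited sequence."""
        # repeat-rich references make the equivalence classes non-trivial
        unit = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
        ref = ("ACGT" + unit * data.draw(st.integers(2, 5)) + "TGCA") * 2
        length = data.draw(st.integers(1, min(3, len(unit) * 2)))
        kind = data.draw(st.sampled_from(["del", "ins"]))
        if kind == "del":
            start = data.draw(st.integers(0, len(ref) - length))
            indel = IndelDescriptor("del", start, length)
            read = apply_indel(ref, indel)
            expected_start = min(deletion_placements(ref, read, length))
            expected = IndelDescriptor("del", expected_start, length)
        else:
            start = data.draw(st.integers(0, len(ref)))
            bases = data.draw(st.text(alphabet="ACGT", min_size=length, max_size=length))
            indel = IndelDescriptor("ins", start, length, bases)
            read = apply_indel(ref, indel)
            q, b = min(insertion_placements(ref, read, length))
            expected = IndelDescriptor("ins", q, length, b)
        assert left_normalize_indel(indel, ref) == expected
        # and the full alignment path agrees
        aln = AmpliconAligner(ref, floor_frac=0.0).align(read)
        norm = normalize_alignment(aln, ref)
        indels = norm.indels()
        if len(indels) == 1 and indels[0].length == length:
            assert indels[0] == expected


class TestPairExtraction:
    def _aln(self, target, mol, rc=False):
        from allelecrispr.targets import revcomp

        read = revcomp(mol)[:150] if rc else mol[:150]
        if rc:
            read = revcomp(read)  # pipeline orients mate 2 back to top strand
        aln = AmpliconAligner(target.reference).align(read)
        return normalize_alignment(aln, target.reference)

    def test_wild_type_pair_has_no_indels(self, target):
        hap = target.haplotype("B6")
        res = extract_indels(self._aln(target, hap), self._aln(target, hap, rc=True))
        assert res.indels == () and res.consistent

    def test_shared_insertion_reported_once(self, target):
        mol = apply_indel(target.haplotype("B6"), IndelDescriptor("ins", 117, 1, "A"))
        res = extract_indels(self._aln(target, mol), self._aln(target, mol, rc=True))
        assert res.consistent
        assert len(res.indels) == 1
        assert res.indels[0].kind == "ins" and res.indels[0].length == 1

    def test_conflicting_mates_flagged_inconsistent(self, target):
        hap = target.haplotype("B6")
        mol_del = apply_indel(hap, IndelDescriptor("del", 115, 3))
        a1 = self._aln(target, mol_del)  # mate 1 sees a deletion
        a2 = self._aln(target, hap, rc=True)  # mate 2 covers the interval, all matches
        res = extract_indels(a1, a2)
        assert not res.consistent
        assert res.conflicts


class TestAlleleAssignment:
    def _pair(self, target, mol):
        from allelecrispr.targets import revcomp

        aligner = AmpliconAligner(target.reference)
        a1 = aligner.align(mol[:150], "F" * 150)
        a2 = aligner.align(revcomp(revcomp(mol)[:150]), "F" * 150)
        return normalize_alignment(a1, target.reference), normalize_alignment(a2, target.reference)

    def test_b6_bases_in_bxj_give_maternal(self, target):
        call = assign_allele(*self._pair(target, target.haplotype("B6")), target)
        assert call.category == "maternal" and call.strain == "B6"

    def test_jf1_bases_in_bxj_give_paternal(self, target):
        call = assign_allele(*self._pair(target, target.haplotype("JF1")), target)
        assert call.category == "paternal"

    def test_phase_flips_in_reciprocal_cross(self, target_jxb):
        call = assign_allele(
            *self._pair(target_jxb, target_jxb.haplotype("B6")), target_jxb
        )
        assert call.category == "paternal"

    def test_uninformative_snps_give_ambiguous(self, target):
        # one SNP lost to a deletion, the other showing a third base
        hap = list(target.haplotype("B6"))
        s1, s2 = target.snps
        third = ({"A", "C", "G", "T"} - {s2.base_b6, s2.base_jf1, "C", "G"}).pop()
        hap[s2.position] = third
        mol = "".join(hap[: s1.position - 2] + hap[s1.position + 4 :])
        a1, a2 = self._pair(target, mol)
        call = assign_allele(a1, a2, target)
        assert call.category == "ambiguous"

    def test_conflicting_snps_give_discordant(self, target):
        hap = list(target.haplotype("B6"))
        snp2 = target.snps[1]
        hap[snp2.position] = snp2.base_jf1  # chimeric molecule
        a1, a2 = self._pair(target, "".join(hap))
        call = assign_allele(a1, a2, target)
        assert call.category == "discordant"

    def test_low_quality_snp_base_is_uninformative(self, target):
        hap = target.haplotype("B6")
        aligner = AmpliconAligner(target.reference)
        qual = ["F"] * 150
        for s in target.snps:
            if s.position < 150:
                qual[s.position] = "#"  # Q2
        a1 = aligner.align(hap[:150], "".join(qual))
        a2 = aligner.align(hap[:150], "".join(qual))
        call = assign_allele(a1, a2, target)
        assert call.category == "ambiguous"
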