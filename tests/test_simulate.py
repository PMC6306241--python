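import numpy as np
import pytest

from allelecrispr import (
    BisSimConfig,
    EditSimConfig,
    IndelDescriptor,
    OutcomeProbs,
    apply_indel,
    simulate_bisulfite_pairs,
    simulate_edited_pairs,
    write_fastq_pairs,
)
from allelecrispr.simulate import SimConfigError, left_normalize_indel


class TestApplyIndel:
    def test_deletion_removes_interval(self):
        seq = "ACGTACGTACGTACGTACGT"
        out = apply_indel(seq, IndelDescriptor("del", 5, 2))
        assert out == seq[:5] + seq[7:]
        assert len(out) == 18

    def test_insertion_at_origin_prepends(self):
        out = apply_indel("ACGT", IndelDescriptor("ins", 0, 1, "A"))
        assert out == "AACGT"

    def test_out_of_range_rejected(self):
        with pytest.raises(SimConfigError):
            apply_indel("ACGT", IndelDescriptor("del", 3, 2))

    def test_apply_then_align_round_trips_descriptor(self, target):
        from allelecrispr import AmpliconAligner, normalize_alignment

        ref = target.reference
        aligner = AmpliconAligner(ref)
        for raw in (
            IndelDescriptor("del", 116, 3),
            IndelDescriptor("ins", 117, 2, "AT"),
            IndelDescriptor("del", 110, 1),
        ):
            read = apply_indel(ref, raw)[:150]
            aln = normalize_alignment(aligner.align(read), ref)
            assert aln.indels() == (left_normalize_indel(raw, ref),)


class TestEditSim:
    def test_pure_wt_reads_match_haplotypes_exactly(self, target):
        cfg = EditSimConfig(
            n_pairs=50,
            maternal=OutcomeProbs(1, 0, 0),
            paternal=OutcomeProbs(1, 0, 0),
            error_rate=0.0,
            duplicate_rate=0.0,
            umi_length=0,
            seed=7,
        )
        pairs, truth = simulate_edited_pairs(target, cfg)
        from allelecrispr.targets import revcomp

        for pair, row in zip(pairs, truth.itertuples()):
            hap = target.haplotype(row.strain)
            assert pair.r1_seq == hap[:150]
            assert pair.r2_seq == revcomp(hap)[:150]
        assert (truth.outcome == "wt").all()

    def test_pure_nhej_single_insertion_in_every_pair(self, target):
        ins = IndelDescriptor("ins", target.cut_site, 1, "A")
        cfg = EditSimConfig(
            n_pairs=30,
            maternal=OutcomeProbs(0, 1, 0),
            paternal=OutcomeProbs(0, 1, 0),
            indel_spectrum=((ins, 1.0),),
            error_rate=0.0,
            duplicate_rate=0.0,
            umi_length=0,
            seed=7,
        )
        pairs, truth = simulate_edited_pairs(target, cfg)
        expected = apply_indel(
            target.haplotype(target.cross.maternal_strain),
            left_normalize_indel(ins, target.reference),
        )
        for pair, row in zip(pairs, truth.itertuples()):
            hap = apply_indel(
                target.haplotype(row.strain), left_normalize_indel(ins, target.reference)
            )
            assert pair.r1_seq == hap[:150]
        assert (truth.outcome == "nhej").all()
        assert set(truth.indel) == {str(left_normalize_indel(ins, target.reference))}

    def test_same_seed_gives_byte_identical_fastq(self, target, tmp_path):
        cfg = EditSimConfig(n_pairs=200, seed=11)
        for run in ("a", "b"):
            pairs, _ = simulate_edited_pairs(target, cfg)
            write_fastq_pairs(pairs, tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq")
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()

    def test_outcome_fractions_converge_to_configured_probabilities(self, target):
        cfg = EditSimConfig(n_pairs=10_000, duplicate_rate=0.0, seed=5)
        _, truth = simulate_edited_pairs(target, cfg)
        for allele, probs in (("maternal", cfg.maternal), ("paternal", cfg.paternal)):
            sub = truth[truth.allele == allele]
            n = len(sub)
            for outcome, p in (("wt", probs.wt), ("nhej", probs.nhej), ("hdr", probs.hdr)):
                frac = (sub.outcome == outcome).mean()
                sd = np.sqrt(p * (1 - p) / n)
                assert abs(frac - p) <= 3 * sd + 1e-12, (allele, outcome)

    def test_duplicate_fraction_matches_rate(self, target):
        cfg = EditSimConfig(n_pairs=10_000, duplicate_rate=0.15, seed=5)
        pairs, truth = simulate_edited_pairs(target, cfg)
        d = truth.is_duplicate.mean()
        sd = np.sqrt(0.15 * 0.85 / len(truth))
        assert abs(d - 0.15) <= 3 * sd
        # duplicates are byte-identical to their source pairs
        by_id = {p.pair_id: p for p in pairs}
        dups = truth[truth.is_duplicate]
        for row in dups.head(100).itertuples():
            src = by_id[row.source_id]
            cpy = by_id[row.pair_id]
            assert (src.r1_seq, src.r2_seq) == (cpy.r1_seq, cpy.r2_seq)

    def test_truth_alleles_agree_with_snp_bases_at_zero_error(self, target):
        cfg = EditSimConfig(n_pairs=300, error_rate=0.0, umi_length=0, seed=9)
        pairs, truth = simulate_edited_pairs(target, cfg)
        snp = target.snps[0]  # covered by R1
        for pair, row in zip(pairs, truth.itertuples()):
            if row.outcome != "wt":
                continue
            expected = snp.base_b6 if row.strain == "B6" else snp.base_jf1
            assert pair.r1_seq[snp.position] == expected

    def test_spectrum_outside_window_rejected(self, target):
        far = IndelDescriptor("del", 10, 2)
        cfg = EditSimConfig(indel_spectrum=((far, 1.0),))
        with pytest.raises(SimConfigError, match="window"):
            cfg.validate(target)

    def test_amplicon_must_fit_in_read_span(self, target):
        cfg = EditSimConfig(read_length=100)
        with pytest.raises(SimConfigError, match="longer"):
            cfg.validate(target)


class TestBisulfiteSim:
    def test_full_methylation_reads_all_cpgs_as_c(self, target):
        cfg = BisSimConfig(meth_maternal=1.0, meth_paternal=1.0, n_pairs=20,
                           umi_length=0, seed=2)
        pairs, truth = simulate_bisulfite_pairs(target, cfg)
        for pair, row in zip(pairs, truth.itertuples()):
            if row.strand != "top":
                continue
            for pos in target.cpg_sites:
                if pos < len(pair.r1_seq):
                    assert pair.r1_seq[pos] == "C"

    def test_no_methylation_reads_all_cpgs_as_t(self, target):
        cfg = BisSimConfig(meth_maternal=0.0, meth_paternal=0.0, n_pairs=20,
                           umi_length=0, seed=2)
        pairs, truth = simulate_bisulfite_pairs(target, cfg)
        for pair, row in zip(pairs, truth.itertuples()):
            if row.strand != "top":
                continue
            for pos in target.cpg_sites:
                if pos < len(pair.r1_seq):
                    assert pair.r1_seq[pos] == "T"

    def test_non_cpg_cytosines_always_convert(self, target):
        cfg = BisSimConfig(n_pairs=20, umi_length=0, seed=3)
        pairs, truth = simulate_bisulfite_pairs(target, cfg)
        cpgs = set(target.cpg_sites)
        for pair, row in zip(pairs, truth.itertuples()):
            if row.strand != "top":
                continue
            hap = target.haplotype(row.strain)
            for pos, base in enumerate(hap[:150]):
                if base == "C" and pos not in cpgs:
                    assert pair.r1_seq[pos] == "T"

    def test_imprinted_mixture_is_half_methylated(self, target):
        cfg = BisSimConfig(meth_maternal=1.0, meth_paternal=0.0, n_pairs=10_000, seed=4)
        _, truth = simulate_bisulfite_pairs(target, cfg)
        frac = truth.n_methylated.sum() / (len(truth) * len(target.cpg_sites))
        sd = 0.5 / np.sqrt(len(truth))
        assert abs(frac - 0.5) <= 3 * sd

    def test_bottom_strand_uses_ga_conversion(self, target):
        cfg = BisSimConfig(meth_maternal=1.0, meth_paternal=1.0, n_pairs=40,
                           umi_length=0, seed=6)
        pairs, truth = simulate_bisulfite_pairs(target, cfg)
        cpg_g = {p + 1 for p in target.cpg_sites}
        saw_bottom = False
        for pair, row in zip(pairs, truth.itertuples()):
            if row.strand != "bottom":
                continue
            saw_bottom = True
            hap = target.haplotype(row.strain)
            for pos, base in enumerate(hap[:150]):
                if base == "G":
                    assert pair.r1_seq[pos] == ("G" if pos in cpg_g else "A")
        assert saw_bottom

    def test_deterministic_given_seed(self, target):
        a = simulate_bisulfite_pairs(target, BisSimConfig(n_pairs=100, seed=8))
        b = simulate_bisulfite_pairs(target, BisSimConfig(n_pairs=100, seed=8))
        assert a[0] == b[0]
        assert a[1].equals(b[1])
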