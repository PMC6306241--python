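# allelecrispr

Allele-resolved quantification of CRISPR-Cas9 editing outcomes from
paired-end amplicon sequencing, with per-read CpG methylation analysis of
bisulfite amplicons from the same loci.

## The problem

In F1-hybrid cells (e.g. C57BL/6J × JF1/Ms mouse embryonic stem cells)
the two parental chromosomes carry identical target sites in different
chromatin states: at maternally methylated imprinted CpG islands the
maternal allele is heterochromatic and the paternal allele euchromatic,
while strain SNPs 40–100 bp from the cut site let every sequencing read
be traced to its chromosome of origin. This makes imprinted loci a
natural controlled experiment for asking how chromatin affects Cas9
mutagenesis. `allelecrispr` implements the complete analysis:

- **Preprocessing** — exact duplicate read-pair removal, random-hexamer
  (UMI) stripping, 3′ adapter trimming.
- **Alignment** — exact semi-global affine-gap alignment of each mate to
  the amplicon (read global, reference flanks free; match +2, mismatch
  −4, gap open −6, gap extend −1), with left-normalization of indels.
- **Phasing** — each pair is assigned MATERNAL / PATERNAL (or AMBIGUOUS /
  DISCORDANT) by unanimity voting over strain SNP bases.
- **Outcome classification** — NHEJ if any indel lies within 10 bp of
  the predicted cut site (3 bp 5′ of the PAM); otherwise HDR if every
  donor-programmed substitution (including the PAM-destroying edit) shows
  the donor base; otherwise wild type. Per-allele mutation frequency
  f = (n_NHEJ + n_HDR) / n_total, paternal fold bias f_pat / f_mat,
  HDR share n_HDR / (n_NHEJ + n_HDR), and top-5 InDel spectra.
- **Methylation** — conversion-aware strand-resolved alignment of
  bisulfite amplicon reads, per-pair CpG counting (each site once per
  pair), proportion binning, the >80% hypermethylated-strand call, and
  the 50% fully-imprinted baseline.
- **Statistics** — paired/unpaired t tests, one-way ANOVA + Tukey HSD on
  fold biases, Pearson correlation of methylation vs bias, Bonferroni
  correction for HDR comparisons, binomially propagated fold-bias
  confidence intervals.
- **Synthetic data** — paired-FASTQ generators with exact ground truth
  for edited and bisulfite amplicons (per-allele outcome probabilities,
  guide-specific indel spectra, donor edits, sequencing error, PCR
  duplicates, per-CpG methylation with imperfect conversion), so the
  whole pipeline is testable without any sequencing download.

## Worked example

```bash
python examples/simulate_and_quantify.py
```

```
locus: demo_locus (cut site 117, window +/-10 bp)
read accounting: {'input_pairs': 2000, 'duplicates_removed': 89, 'unaligned': 0, 'inconsistent': 0, 'classified': 1911}
maternal:   976 pairs | WT 854 NHEJ 104 HDR 18 | mutation frequency 0.125 | HDR share 0.15
paternal:   935 pairs | WT 574 NHEJ 293 HDR 68 | mutation frequency 0.386 | HDR share 0.19
paternal fold bias: 3.09
```

2,000 read pairs were simulated from the bundled demo locus (silenced
maternal allele mutating at 0.12, active paternal at 0.40); after
removing 89 PCR duplicates the pipeline phased and classified 1,911
pairs and recovered the allelic bias: the euchromatic paternal allele
carries ~3× more mutations than the heterochromatic maternal allele,
with the same HDR share on both — chromatin gates how often cutting
happens, not how breaks are repaired.

Other narrative examples:

- `examples/methylation_profile.py` — the 50% imprinting baseline and
  hypermethylated-strand fraction from a bisulfite simulation.
- `examples/indel_spectrum.py` — top-5 recurrent InDel recovery per allele.
- `examples/replicate_statistics.py` — paired t, Cas9-dose ANOVA + Tukey
  HSD, and 24 h/96 h kinetics percentages over replicates.

A thin CLI wraps the same functions
(`allelecrispr simulate|quantify|methylation`); run
`allelecrispr --help` for flags. Exit codes: 0 ok, 2 validation error,
3 runtime error.

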