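# Methods

## Locus model and coordinates

A target locus is an amplicon reference (uppercase ACGT) with 0-based
half-open coordinates. The cut site is a *between-base* integer c (the
break falls between positions c−1 and c), computed as 3 bp 5′ of the PAM
(blunt SpCas9 cut): `pam_start − 3` for a + strand guide, `pam_start + 6`
for a − strand guide whose PAM appears as CCN on the top strand. The
3-bp offset is the standard SpCas9 convention; it is exposed as
`cut_offset` in the config so alternative conventions remain testable.
Between-base cut coordinates remove every ±1 ambiguity from the
"indel within 10 bp" rule.

Validation enforces: all SNP/donor/CpG positions in range; donor
`ref_base` matching the reference; informative SNPs (B6 ≠ JF1); at least
one donor edit inside the PAM triplet (the donors are PAM-destroying by
design, which prevents re-cutting of repaired molecules); cut site
inside the protospacer; SNP and donor positions disjoint; CpG entries
pointing at the C of a genuine CG dinucleotide.

## Alignment

Each mate is aligned to the amplicon with an exact semi-global
affine-gap dynamic program: the read is aligned end-to-end, unaligned
reference flanks are free. Scoring defaults: match +2, mismatch −4, and
a gap of length L costs −6 − L (open −6, extend −1 per base, including
the first). The DP is integer-valued and row-vectorised; horizontal gap
scores use the prefix-max identity
E[j] = max_k (M[k] + open + extend·(j−k)), so each row is a handful of
numpy operations. Tie-breaking is deterministic: the leftmost maximal
end column, and match > deletion > insertion during traceback.

Two provably safe fast paths avoid the DP for most amplicon reads: an
exact-substring probe, and a sliding-window gapless scan accepted only
when its score exceeds the best any gapped alignment could achieve
(2·len + open + extend, i.e. at most one mismatch under the defaults).
Alignments are memoised by read sequence — amplicon libraries contain
few distinct molecules, so the cache turns deep runs from minutes into
seconds without changing any result. Pairs scoring below 40% of the
maximum attainable score are flagged unaligned and excluded (counted in
the log); mate 2 is reverse-complemented before alignment, with an
opposite-orientation retry if the expected orientation fails the floor.

Indels are left-normalized on the gapped alignment: a gap run shifts one
column left whenever the opposite string carries the same character at
the columns entering and leaving the run, which preserves the aligned
sequence pair and the score; iterated to a fixed point this yields the
minimum-start member of the indel's equivalence class (verified against
brute-force placement enumeration). Normalization makes the cut-window
test and spectrum identities representation-independent.

Pair-level indels are the union over mates; an indel reported by one
mate across positions the other mate covers without it marks the pair
INCONSISTENT (excluded, counted). Externally produced SAM/BAM
alignments can be ingested via pysam as an alternative entry point.

## Allele assignment

Every strain SNP covered by a match/mismatch column contributes a vote:
a base equal to the B6 (resp. JF1) allele votes for that strain; bases
matching neither, below Q20, or lost to a deletion are uninformative.
Unanimous votes assign the strain, mapped to MATERNAL/PATERNAL through
the cross phase (B×J: B6 maternal; J×B reciprocal); no informative SNP →
AMBIGUOUS; votes for both strains → DISCORDANT. Ambiguous and
discordant pairs are excluded from allele-specific rates and reported
separately — how the original analysis treated them is not documented,
so exclusion-with-accounting is this package's own (conservative)
choice.

## Outcome classification

NHEJ: any normalized indel whose reference footprint (insertion point
for insertions) lies within `window_bp` (default 10, inclusive) of the
cut. Otherwise HDR: every donor-programmed position shows the donor
base (`--hdr-min-edits` relaxes this). Otherwise WT. Substitutions at
non-donor, non-SNP positions never create an edit call, making the
classifier robust to sequencing error. Precedence for pairs with both
in-window indels and full donor evidence is NHEJ — an in-window indel is
taken as dominant evidence of end joining — and such pairs carry a
`conflict` flag so the alternative precedence can be quantified.
Out-of-window indels leave a pair HDR/WT-eligible but are logged.

Spectra group NHEJ pairs by exact normalized descriptor identity
(type, start, length, inserted bases); fractions are per allele over all
InDel-containing pairs, ties broken by (count desc, start asc, length
asc).

## Methylation

The reference is converted twice (C→T for the top strand, G→A for the
bottom). Each read pair is scored on both strand hypotheses with the
same aligner, using conversion-collapsed copies of the reads for scoring
only; the higher-scoring strand wins (tie → top). A collapsed read from
the true strand matches its converted reference exactly whenever it
carries no sequencing error, so strand resolution rarely needs the DP.
Methylation is then read from the original bases: C/T at the CpG
cytosine on the top strand, G/A at the CpG guanine on the bottom. Each
configured CpG is counted once per pair (mate 1 wins overlaps; the
original pipeline's overlap handling is undocumented, so once-per-pair
is this package's decision). Records with zero covered CpGs are
excluded and counted.

Per-pair proportions are binned into ten equal-width right-closed bins;
a pair with proportion strictly greater than 0.8 is hypermethylated.
With both alleles sequenced together a fully maintained imprint gives
50% overall methylation — reported as the `imprinted_baseline_percent`
reference line. Methylation is summarised across both alleles combined
(real amplicons do not always contain an informative SNP); the
non-CpG-cytosine non-conversion rate is reported as a QC metric, not a
filter.

## Synthetic data as study conditions

`EditSimConfig` defaults describe one imprinted-locus editing experiment
96 h post transfection: maternal (heterochromatic) outcome probabilities
(WT 0.88, NHEJ 0.10, HDR 0.02) and paternal (euchromatic) (0.60, 0.32,
0.08) — mutation frequencies 0.12 and 0.40, fold bias ≈3.3, HDR about a
fifth of mutant reads; a five-entry spectrum around the cut (−1, +1A,
−2, −4, +1T with weights 0.35/0.25/0.15/0.15/0.10, including two
distinct +1 insertions as seen in real spectra); substitution error
1e-3/base (MiSeq-like); 5% exact PCR duplicates; balanced alleles; 150-nt
mates carrying a random hexamer tag (see below). `BisSimConfig` defaults
describe a fully imprinted locus with perfect conversion chemistry
(maternal per-CpG probability 1.0, paternal 0.0, conversion 1.0,
failure 0.0).

Reads are two 150-nt mates that must jointly cover the amplicon
(amplicon length ≤ 2·(read length − tag length) is enforced), each
beginning with an independent random hexamer emulating the N-mer on the
first-round PCR primers of this library design. The tag is what makes
exact-pair deduplication meaningful on amplicons: distinct molecules
with identical inserts still differ in sequence, so dedup removes only
true PCR duplicates (which are exact copies, errors included). The
pipeline strips the tag after dedup and before alignment.

The bundled `demo_target()` is a deterministic synthetic 250-nt locus
(no genome corresponds to it) with a + strand guide, NGG PAM, two donor
edits (one in the PAM), two SNPs at realistic distances from the cut
(~77 and ~73 bp), and 13 configured CpGs; it is constructed so the only
CG dinucleotides in either haplotype are the configured ones, keeping
bisulfite simulations exactly interpretable.

What the simulator does not model: platform-specific error profiles or
quality variation (qualities are constant Q37), indel sequencing errors,
chimeric/primer-dimer artifacts, or PCR amplification bias between
alleles. Passing tests therefore demonstrate correctness of the
analytical machinery under clean study conditions, not robustness to
every artifact of real libraries.

## Statistics

Mutation frequency denominators count maternal + paternal assigned,
aligned, mate-consistent pairs. Fold bias is always paternal/maternal
(the paternal allele is the active one at these maternally methylated
loci); an infinite ratio (maternal frequency zero) is flagged rather
than reported as a number. Fold-bias confidence intervals are
binomially propagated, either by the delta method on the log ratio
(accurate at large counts) or conservatively from Bonferroni-split
Clopper–Pearson bounds on each frequency (guaranteed coverage at small
counts). Paired t tests compare allele frequencies across replicates
(all-zero differences report p = 1 with a degenerate flag; constant
non-zero differences report a diverging t with p = 0, flagged); the
one-way ANOVA + Tukey HSD operates on raw per-replicate fold biases
(legends describe fold differences; a log scale can be applied by the
caller, and the raw scale is the default choice here); Pearson
correlation relates per-experiment methylation to mean paternal
enrichment; Bonferroni correction is applied only to the per-guide HDR
comparisons, mirroring where the experimental analysis corrected.
50 ng of mouse gDNA corresponds to 8,333 diploid genomes at 6 pg per
diploid genome — the template bottleneck that bounds how many
independent molecules one replicate can sample.

## Problem sizes and numerical choices

Tests run the full pipeline at up to 10,000 pairs per allele for exact
truth recovery, 10,000 all-NHEJ pairs for spectrum recovery (3 binomial
SD), a 5×5 probability grid at 1,000 pairs/allele for fold-bias interval
coverage (≥95% of runs within conservative 99% intervals), and 10,000
bisulfite pairs for the 50% imprinting baseline (3 SD). The alignment
oracle compares 1,000 random instances against an independent scalar DP,
plus exhaustive alignment enumeration on tiny inputs. All simulations
are seeded; identical seeds give byte-identical FASTQ and report JSON.

## Known limitations

Large structural outcomes (big deletions beyond the amplicon,
translocations) are invisible to amplicon sequencing and out of scope;
microhomology annotation and off-target analysis are not implemented.
Allele-specific PCR efficiency differences would bias the allele mixture
and are not modelled. The aligner is amplicon-local by design and not a
general read mapper.
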