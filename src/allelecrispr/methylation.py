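"""Per-read-pair CpG methylation from bisulfite amplicon reads.

Reads are aligned conversion-aware: a C→T-collapsed copy of each read is
scored against the C→T-converted reference (top-strand hypothesis) and a
G→A-collapsed copy against the G→A-converted reference (bottom strand);
the higher-scoring strand wins, and methylation is then read from the
ORIGINAL read bases at the configured CpG positions.  Each CpG site is
counted once per pair (mate 1 wins overlap conflicts).  A read pair whose
methylated proportion exceeds 0.8 is called hypermethylated, matching the
">80% of CpGs" convention used for imprinted amplicons; with both
parental alleles sequenced together, a completely imprinted locus shows
50% overall methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .align import Alignment, AmpliconAligner, Scoring
from .fastq import ReadPairRecord
from .targets import AmpliconTarget, revcomp

logger = logging.getLogger(__name__)

HYPERMETHYLATED_THRESHOLD = 0.8
N_BINS = 10

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")


def convert_reference(target: AmpliconTarget) -> tuple[str, str]:
    """(top-strand C→T reference, bottom-strand G→A reference)."""
    return target.reference.translate(_CT), target.reference.translate(_GA)


@dataclass
class MethylationReadRecord:
    pair_id: str
    strand: str  # top | bottom
    n_cpg_covered: int
    n_methylated: int

    @property
    def proportion(self) -> float:
        return self.n_methylated / self.n_cpg_covered

    @property
    def bin_index(self) -> int:
        """Ten equal-width right-closed proportion bins; 0.0 falls in bin 0."""
        p = self.proportion
        return 0 if p == 0 else int(np.ceil(p * N_BINS)) - 1

    @property
    def hypermethylated(self) -> bool:
        return self.proportion > HYPERMETHYLATED_THRESHOLD


class BisulfiteAligner:
    """Strand-resolving conversion-aware aligner for one target."""

    def __init__(self, target: AmpliconTarget, scoring: Scoring | None = None,
                 floor_frac: float = 0.4):
        self.target = target
        top_ref, bottom_ref = convert_reference(target)
        self._top = AmpliconAligner(top_ref, scoring, floor_frac)
        self._bottom = AmpliconAligner(bottom_ref, scoring, floor_frac)
        self._max_per_base = (scoring or Scoring()).match

    def align_pair(
        self, pair: ReadPairRecord
    ) -> Optional[tuple[Alignment, Alignment, str]]:
        """(mate1 alignment, mate2 alignment, strand) or None if unalignable.

        Mate 2 is reverse-complemented onto top-strand coordinates first.
        The two strand hypotheses are scored on converted copies; ties go
        to the top strand.  A collapsed read from the true strand matches
        its converted reference exactly whenever it carries no sequencing
        error, so an exact-substring probe resolves most pairs before any
        dynamic programming.  Pairs failing the score floor on both
        strands are rejected.
        """
        r1, r2 = pair.r1_seq, revcomp(pair.r2_seq)
        q1, q2 = pair.r1_qual, pair.r2_qual[::-1]
        match = self._max_per_base

        def perfect_pair(aligner: AmpliconAligner, table) -> Optional[list[Alignment]]:
            alns = []
            for read, qual in ((r1, q1), (r2, q2)):
                conv = read.translate(table)
                pos = aligner.reference.find(conv)
                if pos < 0:
                    return None
                alns.append(Alignment(conv, pos, (("M", len(conv)),), match * len(conv), qual))
            return alns

        def full_pair(aligner: AmpliconAligner, table) -> Optional[list[Alignment]]:
            alns = []
            for read, qual in ((r1, q1), (r2, q2)):
                aln = aligner.align(read.translate(table), qual)
                if aln is None:
                    return None
                alns.append(aln)
            return alns

        alns = perfect_pair(self._top, _CT)
        strand = "top"
        if alns is None:
            alns = perfect_pair(self._bottom, _GA)
            strand = "bottom"
        if alns is None:
            top = full_pair(self._top, _CT)
            bottom = full_pair(self._bottom, _GA)
            t = sum(a.score for a in top) if top else None
            b = sum(a.score for a in bottom) if bottom else None
            if t is None and b is None:
                return None
            if b is None or (t is not None and t >= b):
                strand, alns = "top", top
            else:
                strand, alns = "bottom", bottom
        # restore original (unconverted) bases for methylation calling
        restored = [
            Alignment(read, a.ref_start, a.cigar, a.score, a.qual)
            for a, read in zip(alns, (r1, r2))
        ]
        return restored[0], restored[1], strand


def count_methylated(
    pair_id: str,
    a1: Alignment,
    a2: Alignment,
    strand: str,
    target: AmpliconTarget,
) -> Optional[MethylationReadRecord]:
    """Score each configured CpG once for this pair.

    Top strand reads the C of the CpG (C methylated, T unmethylated);
    bottom strand reads the G (G methylated, A unmethylated).  Any other
    base, or an indel over the site, leaves the site uncovered.  Returns
    None when no CpG is covered (pair excluded, caller counts it).
    """
    meth = unmeth = covered = 0
    for pos in target.cpg_sites:
        site = pos if strand == "top" else pos + 1
        call = None
        for aln in (a1, a2):  # mate 1 wins conflicts
            hit = aln.base_at(site)
            if hit is None:
                continue
            base = hit[0]
            if strand == "top":
                state = True if base == "C" else (False if base == "T" else None)
            else:
                state = True if base == "G" else (False if base == "A" else None)
            if state is not None:
                call = state
                break
        if call is None:
            continue
        covered += 1
        if call:
            meth += 1
    if covered == 0:
        return None
    return MethylationReadRecord(pair_id, strand, covered, meth)


@dataclass
class MethylationSummary:
    """Cohort-level methylation profile across both alleles."""

    n_pairs: int
    bin_counts: tuple[int, ...]  # ten right-closed proportion bins
    percent_hypermethylated: float
    mean_methylation_percent: float  # over all CpG calls
    imprinted_baseline_percent: float = 50.0

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "bin_counts": list(self.bin_counts),
            "percent_hypermethylated": self.percent_hypermethylated,
            "mean_methylation_percent": self.mean_methylation_percent,
            "imprinted_baseline_percent": self.imprinted_baseline_percent,
        }


def summarize_methylation(records: Iterable[MethylationReadRecord]) -> MethylationSummary:
    records = list(records)
    if not records:
        raise ValueError("no methylation records to summarise")
    bins = [0] * N_BINS
    meth_calls = total_calls = hyper = 0
    for rec in records:
        bins[rec.bin_index] += 1
        meth_calls += rec.n_methylated
        total_calls += rec.n_cpg_covered
        hyper += rec.hypermethylated
    return MethylationSummary(
        n_pairs=len(records),
        bin_counts=tuple(bins),
        percent_hypermethylated=100.0 * hyper / len(records),
        mean_methylation_percent=100.0 * meth_calls / total_calls,
    )


@dataclass
class MethylationResult:
    records: list[MethylationReadRecord]
    summary: MethylationSummary
    strands: dict[str, str] = field(default_factory=dict)
    n_unaligned: int = 0
    n_uncovered: int = 0
    nonconversion_qc: Optional[float] = None


def run_methylation(
    pairs: Iterable[ReadPairRecord],
    target: AmpliconTarget,
    dedup: bool = True,
    umi_length: int = 0,
) -> MethylationResult:
    """Full per-read methylation pipeline: dedup → align → count → summarise.

    Also reports a conversion-efficiency QC metric: the fraction of
    non-CpG cytosine positions still read as C (top) / G (bottom), which
    estimates bisulfite non-conversion.  It is reported, not filtered on.
    """
    from .preprocess import dedup_pairs, strip_umi

    if dedup:
        pairs = dedup_pairs(pairs)
    if umi_length:
        pairs = strip_umi(pairs, umi_length)
    aligner = BisulfiteAligner(target)
    ref = target.reference
    cpg_cols = set(target.cpg_sites) | {p + 1 for p in target.cpg_sites}
    non_cpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in cpg_cols]
    non_cpg_g = [i for i, b in enumerate(ref) if b == "G" and i not in cpg_cols]

    records: list[MethylationReadRecord] = []
    strands: dict[str, str] = {}
    n_unaligned = n_uncovered = 0
    nonconv = nonconv_total = 0
    for pair in pairs:
        hit = aligner.align_pair(pair)
        if hit is None:
            n_unaligned += 1
            continue
        a1, a2, strand = hit
        rec = count_methylated(pair.pair_id, a1, a2, strand, target)
        if rec is None:
            n_uncovered += 1
            continue
        records.append(rec)
        strands[pair.pair_id] = strand
        sites = non_cpg_c if strand == "top" else non_cpg_g
        unconverted_base = "C" if strand == "top" else "G"
        for pos in sites:
            hit2 = a1.base_at(pos) or a2.base_at(pos)
            if hit2 is None:
                continue
            nonconv_total += 1
            if hit2[0] == unconverted_base:
                nonconv += 1
    logger.info(
        "methylation: %d pairs scored, %d unaligned, %d without covered CpGs",
        len(records), n_unaligned, n_uncovered,
    )
    summary = summarize_methylation(records)
    qc = (nonconv / nonconv_total) if nonconv_total else None
    return MethylationResult(records, summary, strands, n_unaligned, n_uncovered, qc)
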