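"""Allelic-bias summaries and the experiment-level statistics.

The central quantities: per-allele mutation frequency
``f = (n_NHEJ + n_HDR) / n_total``, paternal fold bias
``f_paternal / f_maternal`` (paternal is the euchromatic, active allele at
maternally methylated imprinted loci), and HDR share
``n_HDR / (n_HDR + n_NHEJ)``.  Replicate-level inference uses the same
tests the experiments call for: two-tailed paired t between alleles,
one-way ANOVA with Tukey HSD across conditions on fold differences,
Pearson correlation of methylation against bias, and Bonferroni-corrected
paired t for HDR shares across guides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import AMBIGUOUS, DISCORDANT, MATERNAL, PATERNAL

#: mass of one diploid mouse genome in picograms
PG_PER_DIPLOID_GENOME = 6.0


@dataclass(frozen=True)
class AlleleCounts:
    n_total: int
    n_wt: int
    n_nhej: int
    n_hdr: int

    def __post_init__(self) -> None:
        if self.n_wt + self.n_nhej + self.n_hdr != self.n_total:
            raise ValueError("outcome counts do not partition the total")

    @property
    def n_mutant(self) -> int:
        return self.n_nhej + self.n_hdr

    @property
    def mutation_frequency(self) -> Optional[float]:
        return self.n_mutant / self.n_total if self.n_total else None

    @property
    def hdr_share(self) -> Optional[float]:
        return self.n_hdr / self.n_mutant if self.n_mutant else None

    @property
    def hdr_frequency(self) -> Optional[float]:
        return self.n_hdr / self.n_total if self.n_total else None


@dataclass
class EditSummary:
    """Per-target allele-resolved editing outcome summary."""

    maternal: AlleleCounts
    paternal: AlleleCounts
    n_ambiguous: int = 0
    n_discordant: int = 0
    n_unaligned: int = 0
    n_inconsistent: int = 0
    fold_bias_infinite: bool = False

    @property
    def fold_bias(self) -> Optional[float]:
        """Paternal over maternal mutation frequency; None when undefined."""
        f_m, f_p = self.maternal.mutation_frequency, self.paternal.mutation_frequency
        if f_m is None or f_p is None:
            return None
        if f_m == 0:
            return math.inf if f_p > 0 else None
        return f_p / f_m

    @property
    def overall_mutation_frequency(self) -> Optional[float]:
        n = self.maternal.n_total + self.paternal.n_total
        return (self.maternal.n_mutant + self.paternal.n_mutant) / n if n else None

    def to_dict(self) -> dict:
        fb = self.fold_bias
        return {
            "maternal": vars(self.maternal) | {
                "mutation_frequency": self.maternal.mutation_frequency,
                "hdr_share": self.maternal.hdr_share,
            },
            "paternal": vars(self.paternal) | {
                "mutation_frequency": self.paternal.mutation_frequency,
                "hdr_share": self.paternal.hdr_share,
            },
            "fold_bias": None if fb is None or math.isinf(fb) else fb,
            "fold_bias_infinite": fb is not None and math.isinf(fb),
            "overall_mutation_frequency": self.overall_mutation_frequency,
            "n_ambiguous": self.n_ambiguous,
            "n_discordant": self.n_discordant,
            "n_unaligned": self.n_unaligned,
            "n_inconsistent": self.n_inconsistent,
        }


def edit_summary(calls: pd.DataFrame, counters: Optional[Mapping] = None) -> EditSummary:
    """Build an :class:`EditSummary` from the per-pair call table.

    The mutation-frequency denominator counts maternal + paternal
    assigned, aligned, mate-consistent pairs; ambiguous and discordant
    pairs are tallied separately and excluded from allele-specific rates.
    """
    ok = calls[calls["status"] == "ok"]

    def allele_counts(label: str) -> AlleleCounts:
        sub = ok[ok["allele"] == label]
        return AlleleCounts(
            n_total=len(sub),
            n_wt=int((sub["outcome"] == "wt").sum()),
            n_nhej=int((sub["outcome"] == "nhej").sum()),
            n_hdr=int((sub["outcome"] == "hdr").sum()),
        )

    summary = EditSummary(
        maternal=allele_counts(MATERNAL),
        paternal=allele_counts(PATERNAL),
        n_ambiguous=int((ok["allele"] == AMBIGUOUS).sum()),
        n_discordant=int((ok["allele"] == DISCORDANT).sum()),
        n_unaligned=int((calls["status"] == "unaligned").sum()),
        n_inconsistent=int((calls["status"] == "inconsistent").sum()),
    )
    return summary


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def fold_bias_interval(
    summary: EditSummary, level: float = 0.99, method: str = "delta"
) -> tuple[float, float]:
    """Binomial-propagated confidence interval for the fold bias.

    ``method="delta"`` applies the delta method to the log ratio of the
    two allele frequencies; accurate when both mutant counts are large.
    ``method="conservative"`` combines Bonferroni-split Clopper-Pearson
    bounds on each frequency into a ratio interval with guaranteed
    >= ``level`` joint coverage, appropriate at small counts (the upper
    bound is infinite when the maternal lower bound is zero).
    """
    f_m, f_p = summary.maternal.mutation_frequency, summary.paternal.mutation_frequency
    n_m, n_p = summary.maternal.n_total, summary.paternal.n_total
    if method == "conservative":
        each = 1 - (1 - level) / 2
        lo_m, hi_m = _clopper_pearson(summary.maternal.n_mutant, n_m, each)
        lo_p, hi_p = _clopper_pearson(summary.paternal.n_mutant, n_p, each)
        if hi_m == 0:
            raise ValueError("fold-bias interval undefined: maternal frequency bounded at 0")
        return (lo_p / hi_m, math.inf if lo_m == 0 else hi_p / lo_m)
    if not f_m or not f_p:
        raise ValueError("fold-bias interval undefined with a zero allele frequency")
    se_log = math.sqrt(
        (1 - f_m) / (f_m * n_m) + (1 - f_p) / (f_p * n_p)
    )
    z = sps.norm.ppf(0.5 + level / 2)
    ratio = f_p / f_m
    return (ratio * math.exp(-z * se_log), ratio * math.exp(z * se_log))


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False  # all paired differences were zero


def paired_t(mat_freqs: Sequence[float], pat_freqs: Sequence[float]) -> TTestResult:
    """Two-tailed paired t test between allele frequencies across replicates.

    Identical vectors (all differences zero) cannot support a t statistic;
    the result is reported as p = 1 with the degenerate flag set.
    """
    a, b = np.asarray(mat_freqs, float), np.asarray(pat_freqs, float)
    if a.shape != b.shape:
        raise ValueError("paired t requires equal-length replicate vectors")
    if a.size < 2:
        raise ValueError("paired t requires >= 2 replicates")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0):
        if np.allclose(diffs.mean(), 0):
            return TTestResult(0.0, 1.0, degenerate=True)
        # constant nonzero difference: t diverges
        return TTestResult(math.copysign(math.inf, diffs.mean()), 0.0, degenerate=True)
    res = sps.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(res.pvalue))


def unpaired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-tailed two-sample t test (equal variances), e.g. on per-replicate
    fold differences between two conditions."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("unpaired t requires >= 2 values per group")
    if np.allclose(np.concatenate([x, y]).std(ddof=1), 0):
        return TTestResult(0.0, 1.0, degenerate=True)
    res = sps.ttest_ind(x, y)
    return TTestResult(float(res.statistic), float(res.pvalue))


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    pvalue: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way ANOVA across condition groups plus all-pairs Tukey HSD.

    ``groups`` maps a condition label (e.g. a Cas9-expression gate) to its
    per-replicate fold-bias values.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has < 2 values")
    labels = sorted(groups)
    arrays = [np.asarray(groups[g], float) for g in labels]
    flat = np.concatenate(arrays)
    if np.allclose(flat.std(ddof=1), 0):
        f_stat, pval = 0.0, 1.0
    else:
        f_stat, pval = sps.f_oneway(*arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    cond = np.concatenate([[g] * len(groups[g]) for g in labels])
    hsd = pairwise_tukeyhsd(values, cond)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )
    return AnovaTukeyResult(float(f_stat), float(pval), tukey)


def correlate_bias_methylation(
    methylation_percent: Sequence[float],
    mean_fold_bias: Sequence[float],
) -> tuple[float, float]:
    """Pearson r (and two-tailed p) between per-experiment methylation and
    mean paternal fold enrichment."""
    x, y = np.asarray(methylation_percent, float), np.asarray(mean_fold_bias, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation requires >= 3 paired points")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("correlation undefined with zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class KineticsPercent:
    percent: float
    exceeds_final: bool  # early frequency above the final one


def kinetics_percent(f_early: float, f_final: float) -> KineticsPercent:
    """Early mutation frequency as a percentage of the final frequency."""
    if f_final <= 0:
        raise ValueError("kinetics percentage undefined: final frequency is zero")
    pct = 100.0 * f_early / f_final
    return KineticsPercent(pct, pct > 100.0)


def hdr_comparison(
    shares_by_guide: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> dict[str, TTestResult]:
    """Bonferroni-corrected paired t on HDR shares, maternal vs paternal.

    ``shares_by_guide`` maps guide name to (maternal replicate shares,
    paternal replicate shares); each raw p is multiplied by the number of
    guides tested (capped at 1).
    """
    k = len(shares_by_guide)
    out = {}
    for guide, (mat, pat) in shares_by_guide.items():
        res = paired_t(mat, pat)
        out[guide] = TTestResult(res.statistic, min(1.0, res.pvalue * k), res.degenerate)
    return out


def diploid_genome_equivalents(
    nanograms: float, pg_per_genome: float = PG_PER_DIPLOID_GENOME
) -> float:
    """Number of diploid genome copies in a gDNA mass (mouse: ~6 pg each)."""
    if nanograms < 0:
        raise ValueError("mass must be non-negative")
    return nanograms * 1000.0 / pg_per_genome
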