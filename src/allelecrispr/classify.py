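"""WT / NHEJ / HDR outcome classification and indel spectrum tabulation.

A read pair carrying any indel within ``window_bp`` (default 10) of the
cut site is classified NHEJ; otherwise a pair showing the donor base at
every donor-programmed position is HDR; everything else is WT.  Isolated
substitutions at non-donor, non-SNP positions never create an edit call,
which makes the classifier tolerant of sequencing error.  Pairs with both
in-window indels and complete donor edits are NHEJ (end-joining evidence
dominates) and are counted as conflicting so the alternative precedence
can be quantified.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .align import Alignment, IndelDescriptor
from .targets import AmpliconTarget

WT = "wt"
NHEJ = "nhej"
HDR = "hdr"


def indel_in_window(indel: IndelDescriptor, cut_site: int, window_bp: int) -> bool:
    """True iff the indel's reference footprint lies within ``window_bp``
    of the cut site (inclusive; distance 0 when the footprint spans it).

    Both the cut site and insertion points are between-base coordinates,
    so distances are unambiguous in bases.
    """
    lo, hi = indel.footprint
    if lo <= cut_site <= hi:
        return True
    return min(abs(cut_site - lo), abs(cut_site - hi)) <= window_bp


@dataclass
class OutcomeCall:
    """Per-pair repair outcome with its supporting evidence."""

    outcome: str  # wt | nhej | hdr
    indels: tuple[IndelDescriptor, ...] = ()
    in_window_indels: tuple[IndelDescriptor, ...] = ()
    donor_edits_seen: int = 0
    donor_edits_total: int = 0
    conflict: bool = False  # in-window indel AND full donor evidence
    off_window_indels: tuple[IndelDescriptor, ...] = ()


def _pair_base(a1: Alignment, a2: Alignment, pos: int) -> Optional[str]:
    # mate 1 wins when both cover the position
    for aln in (a1, a2):
        hit = aln.base_at(pos)
        if hit is not None:
            return hit[0]
    return None


def classify_outcome(
    a1: Alignment,
    a2: Alignment,
    indels: Sequence[IndelDescriptor],
    target: AmpliconTarget,
    hdr_min_edits: Optional[int] = None,
) -> OutcomeCall:
    """Classify one aligned, indel-extracted pair.

    ``hdr_min_edits`` relaxes the HDR rule to "at least this many donor
    bases observed"; by default every donor-programmed substitution must
    show the donor base (and none may be unreadable).
    """
    cut, window = target.cut_site, target.window_bp
    in_win = tuple(i for i in indels if indel_in_window(i, cut, window))
    off_win = tuple(i for i in indels if i not in in_win)

    seen = 0
    readable = 0
    for ed in target.donor_edits:
        base = _pair_base(a1, a2, ed.position)
        if base is not None:
            readable += 1
            if base == ed.donor_base:
                seen += 1
    need = len(target.donor_edits) if hdr_min_edits is None else hdr_min_edits
    hdr_evidence = bool(target.donor_edits) and seen >= need

    if in_win:
        return OutcomeCall(
            NHEJ, tuple(indels), in_win, seen, len(target.donor_edits),
            conflict=hdr_evidence, off_window_indels=off_win,
        )
    if hdr_evidence:
        return OutcomeCall(
            HDR, tuple(indels), (), seen, len(target.donor_edits),
            off_window_indels=off_win,
        )
    return OutcomeCall(
        WT, tuple(indels), (), seen, len(target.donor_edits), off_window_indels=off_win
    )


@dataclass(frozen=True)
class SpectrumEntry:
    indel: IndelDescriptor
    count: int
    fraction: float  # of all indel-containing reads of that allele


def summarize_spectrum(
    calls: Iterable[tuple[str, OutcomeCall]], n_top: int = 5
) -> dict[str, list[SpectrumEntry]]:
    """Top recurrent indels per allele.

    ``calls`` yields (allele label, OutcomeCall).  NHEJ pairs are grouped
    by exact normalized indel identity; fractions are over all
    indel-containing pairs of that allele (not only the top ``n_top``).
    Ties break by (count desc, start asc, length asc, kind, bases).
    """
    per_allele: dict[str, Counter] = {}
    totals: dict[str, int] = {}
    for allele, call in calls:
        if call.outcome != NHEJ or not call.in_window_indels:
            continue
        c = per_allele.setdefault(allele, Counter())
        totals[allele] = totals.get(allele, 0) + 1
        for indel in call.in_window_indels:
            c[indel] += 1
    out: dict[str, list[SpectrumEntry]] = {}
    for allele, counter in per_allele.items():
        total = totals[allele]
        ranked = sorted(
            counter.items(),
            key=lambda kv: (-kv[1], kv[0].start, kv[0].length, kv[0].kind, kv[0].bases),
        )
        out[allele] = [
            SpectrumEntry(ind, n, n / total) for ind, n in ranked[:n_top]
        ]
    return out
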