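"""Amplicon-local alignment, indel normalization, and allele assignment.

Each mate is aligned to the amplicon reference with a semi-global
affine-gap dynamic program (read global, reference local: reference flanks
are free).  The DP is exact and integer-scored; a gapless fast path
handles the common case of reads that match the reference with at most one
mismatch, where no gapped alignment can score higher under the default
scoring.  Indels are left-normalized so that "distance to the cut site"
and spectrum identity are independent of how the aligner happened to place
a gap inside a repeat.

Gap scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(default -6 - L), so a single-base gap costs -7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .targets import AmpliconTarget, Snp

NEG = -(10**6)

MATERNAL = "maternal"
PATERNAL = "paternal"
AMBIGUOUS = "ambiguous"
DISCORDANT = "discordant"


@dataclass(frozen=True, order=True)
class IndelDescriptor:
    """A normalized insertion or deletion on amplicon coordinates.

    ``start`` is the leftmost affected reference position after
    left-normalization (the insertion point for insertions).  ``bases``
    holds the inserted sequence for insertions, empty for deletions.
    """

    kind: str  # "ins" | "del"
    start: int
    length: int
    bases: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del"):
            raise ValueError(f"indel kind must be 'ins' or 'del', got {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind == "ins" and len(self.bases) != self.length:
            raise ValueError("insertion bases must have the declared length")

    @property
    def footprint(self) -> tuple[int, int]:
        """Reference interval affected: [start, start+length) for deletions,
        the zero-width insertion point for insertions."""
        if self.kind == "del":
            return (self.start, self.start + self.length)
        return (self.start, self.start)

    def __str__(self) -> str:
        if self.kind == "del":
            return f"del{self.length}@{self.start}"
        return f"ins{self.bases}@{self.start}"


@dataclass
class Alignment:
    """A single mate aligned to the amplicon (CIGAR-style ops M/I/D)."""

    query: str
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    score: int
    qual: Optional[str] = None

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in "MD")

    def query_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MI")

    def columns(self) -> Iterator[tuple[Optional[int], Optional[int]]]:
        """Yield (ref_pos, query_index) per column; None marks a gap."""
        r, q = self.ref_start, 0
        for op, n in self.cigar:
            for _ in range(n):
                if op == "M":
                    yield (r, q)
                    r += 1
                    q += 1
                elif op == "D":
                    yield (r, None)
                    r += 1
                else:  # I
                    yield (None, q)
                    q += 1

    def base_at(self, ref_pos: int) -> Optional[tuple[str, Optional[int]]]:
        """Read base (and Phred quality, if any) aligned at ``ref_pos``.

        Returns None when the position is outside the aligned span or falls
        inside a deletion.
        """
        if not (self.ref_start <= ref_pos < self.ref_end):
            return None
        r, q = self.ref_start, 0
        for op, n in self.cigar:
            if op == "M":
                if r <= ref_pos < r + n:
                    qi = q + (ref_pos - r)
                    qual = None if self.qual is None else ord(self.qual[qi]) - 33
                    return (self.query[qi], qual)
                r += n
                q += n
            elif op == "D":
                if r <= ref_pos < r + n:
                    return None
                r += n
            else:
                q += n
        return None

    def indels(self) -> tuple[IndelDescriptor, ...]:
        out = []
        r, q = self.ref_start, 0
        for op, n in self.cigar:
            if op == "M":
                r += n
                q += n
            elif op == "D":
                out.append(IndelDescriptor("del", r, n))
                r += n
            else:
                out.append(IndelDescriptor("ins", r, n, self.query[q : q + n]))
                q += n
        return tuple(out)

    def gapped(self, reference: str) -> tuple[str, str]:
        """(query_aln, ref_aln) gapped strings over the aligned span."""
        qa, ra = [], []
        for rp, qi in self.columns():
            qa.append(self.query[qi] if qi is not None else "-")
            ra.append(reference[rp] if rp is not None else "-")
        return "".join(qa), "".join(ra)


@dataclass
class Scoring:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1


class AmpliconAligner:
    """Semi-global affine-gap aligner against one amplicon reference.

    The read is aligned end-to-end; unaligned reference flanks are free.
    Tie-breaking is deterministic: leftmost reference end among maximal
    scores, and match > deletion > insertion during traceback.  Alignments
    scoring below ``floor_frac`` of the maximum attainable score are
    rejected (returns None; callers count the pair as unaligned).
    """

    def __init__(self, reference: str, scoring: Scoring | None = None, floor_frac: float = 0.4):
        self.reference = reference
        self.scoring = scoring or Scoring()
        self.floor_frac = floor_frac
        self._ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
        # amplicon reads are massively repetitive (few distinct molecules),
        # so memoise by read sequence; None marks a floor rejection
        self._cache: dict[str, Optional[tuple[int, tuple, int]]] = {}
        self._cache_cap = 200_000

    # -- fast gapless path ----------------------------------------------
    def _gapless(self, read: str) -> Optional[Alignment]:
        s = self.scoring
        m, n = len(read), len(self.reference)
        if m > n:
            return None
        pos = self.reference.find(read)
        if pos >= 0:
            return Alignment(read, pos, (("M", m),), s.match * m)
        q_arr = np.frombuffer(read.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(self._ref_arr, m)
        mm = (windows != q_arr).sum(axis=1)
        best = int(np.argmin(mm))  # first minimum -> leftmost start
        score = s.match * (m - int(mm[best])) + s.mismatch * int(mm[best])
        # any alignment with >=1 gap scores at most match*m + gap_open + gap_extend
        if score > s.match * m + s.gap_open + s.gap_extend:
            return Alignment(read, best, (("M", m),), score)
        return None

    # -- full dynamic program -------------------------------------------
    def _dp(self, read: str) -> Alignment:
        s = self.scoring
        ref = self.reference
        m, n = len(read), len(ref)
        go, ge = s.gap_open, s.gap_extend
        q_arr = np.frombuffer(read.encode(), dtype=np.uint8)
        j_idx = np.arange(n + 1, dtype=np.int32)

        H = np.empty((m + 1, n + 1), dtype=np.int32)
        E = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in read (deletion)
        F = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in ref (insertion)
        H[0, :] = 0

        for i in range(1, m + 1):
            Hp = H[i - 1]
            sub = np.where(self._ref_arr == q_arr[i - 1], s.match, s.mismatch).astype(np.int32)
            Fi = np.maximum(Hp + (go + ge), F[i - 1] + ge)
            diag = np.full(n + 1, NEG, dtype=np.int32)
            diag[1:] = Hp[:-1] + sub
            M = np.maximum(diag, Fi)
            M[0] = Fi[0]
            # E[j] = max_{k<j} M[k] + go + ge*(j-k), via prefix max of M[k]-ge*k
            cm = np.maximum.accumulate(M - ge * j_idx)
            Ei = E[i]
            Ei[1:] = go + ge * j_idx[1:] + cm[:-1]
            Hi = np.maximum(M, Ei)
            H[i] = Hi
            F[i] = Fi

        j = int(np.argmax(H[m]))  # first max -> leftmost end
        score = int(H[m, j])

        # traceback (match > deletion > insertion on ties)
        ops: list[str] = []
        i = m
        state = "H"
        while i > 0:
            if state == "H":
                if j > 0:
                    sub = s.match if read[i - 1] == ref[j - 1] else s.mismatch
                    if H[i, j] == H[i - 1, j - 1] + sub:
                        ops.append("M")
                        i -= 1
                        j -= 1
                        continue
                    if H[i, j] == E[i, j]:
                        state = "E"
                        continue
                state = "F"
            elif state == "E":
                ops.append("D")
                if j >= 2 and E[i, j] == E[i, j - 1] + ge:
                    j -= 1
                else:
                    j -= 1
                    state = "H"
            else:  # F
                ops.append("I")
                if i >= 2 and F[i, j] == F[i - 1, j] + ge:
                    i -= 1
                else:
                    i -= 1
                    state = "H"
        ref_start = j
        ops.reverse()
        cigar: list[tuple[str, int]] = []
        for op in ops:
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + 1)
            else:
                cigar.append((op, 1))
        return Alignment(read, ref_start, tuple(cigar), score)

    def align(self, read: str, qual: Optional[str] = None) -> Optional[Alignment]:
        """Best alignment of ``read``, or None if it fails the score floor."""
        if not read:
            return None
        hit = self._cache.get(read, False)
        if hit is not False:
            if hit is None:
                return None
            ref_start, cigar, score = hit
            return Alignment(read, ref_start, cigar, score, qual)
        aln = self._gapless(read)
        if aln is None:
            aln = self._dp(read)
        if aln.score < self.floor_frac * self.scoring.match * len(read):
            aln = None
        if len(self._cache) < self._cache_cap:
            self._cache[read] = None if aln is None else (aln.ref_start, aln.cigar, aln.score)
        if aln is None:
            return None
        aln.qual = qual
        return aln


# -- indel normalization ----------------------------------------------------


def normalize_alignment(aln: Alignment, reference: str) -> Alignment:
    """Shift every gap run to its leftmost equivalent position.

    A gap run in one gapped string may move one column left whenever the
    other string carries the same character at the columns entering and
    leaving the run; the aligned sequence pair and the score are unchanged.
    Idempotent by construction (runs are shifted to a fixed point).
    """
    if not any(op in "ID" for op, _ in aln.cigar):
        return aln
    qa, ra = aln.gapped(reference)
    q, r = list(qa), list(ra)

    def shift(gapped: list[str], other: list[str]) -> bool:
        moved = False
        i, ncol = 0, len(gapped)
        while i < ncol:
            if gapped[i] != "-":
                i += 1
                continue
            a = i
            while i < ncol and gapped[i] == "-":
                i += 1
            b = i
            if a > 0 and gapped[a - 1] != "-" and other[a - 1] != "-" and other[a - 1] == other[b - 1]:
                gapped[b - 1] = gapped[a - 1]
                gapped[a - 1] = "-"
                moved = True
                i = max(a - 1, 0)
        return moved

    while shift(q, r) | shift(r, q):
        pass

    cigar: list[tuple[str, int]] = []
    for qc, rc in zip(q, r):
        op = "M" if qc != "-" and rc != "-" else ("D" if qc == "-" else "I")
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return Alignment(aln.query, aln.ref_start, tuple(cigar), aln.score, aln.qual)


# -- pair-level indel extraction --------------------------------------------


@dataclass
class PairIndels:
    indels: tuple[IndelDescriptor, ...]
    consistent: bool
    conflicts: tuple[IndelDescriptor, ...] = ()


def _covers(aln: Alignment, indel: IndelDescriptor) -> bool:
    lo, hi = indel.footprint
    if indel.kind == "ins":
        return aln.ref_start < indel.start < aln.ref_end
    return aln.ref_start <= lo and hi <= aln.ref_end


def extract_indels(a1: Alignment, a2: Alignment) -> PairIndels:
    """Union of normalized indels across mates with a conflict check.

    An indel reported identically by both overlapping mates counts once.
    An indel reported by one mate over reference positions that the other
    mate covers without it marks the pair inconsistent (excluded downstream).
    """
    s1, s2 = set(a1.indels()), set(a2.indels())
    conflicts = []
    for indel in s1 - s2:
        if _covers(a2, indel):
            conflicts.append(indel)
    for indel in s2 - s1:
        if _covers(a1, indel):
            conflicts.append(indel)
    union = tuple(sorted(s1 | s2))
    return PairIndels(union, not conflicts, tuple(sorted(conflicts)))


# -- allele assignment -------------------------------------------------------


@dataclass
class AlleleCall:
    """Per-pair parental-allele assignment from strain SNPs."""

    category: str  # maternal | paternal | ambiguous | discordant
    snp_bases: dict[int, str] = field(default_factory=dict)
    strain: Optional[str] = None


def assign_allele(
    a1: Alignment,
    a2: Alignment,
    target: AmpliconTarget,
    min_base_quality: int = 20,
) -> AlleleCall:
    """Vote each covered SNP base for its strain; unanimity wins.

    Bases matching neither strain, below the quality floor, or lost to a
    deletion are uninformative.  No informative SNP -> ambiguous; votes for
    both strains -> discordant.
    """
    votes: set[str] = set()
    observed: dict[int, str] = {}
    for snp in target.snps:
        for aln in (a1, a2):
            hit = aln.base_at(snp.position)
            if hit is None:
                continue
            base, qual = hit
            if qual is not None and qual < min_base_quality:
                continue
            observed.setdefault(snp.position, base)
            if base == snp.base_b6:
                votes.add("B6")
            elif base == snp.base_jf1:
                votes.add("JF1")
    if not votes:
        return AlleleCall(AMBIGUOUS, observed)
    if len(votes) > 1:
        return AlleleCall(DISCORDANT, observed)
    strain = votes.pop()
    return AlleleCall(target.cross.allele_of(strain), observed, strain)


# -- SAM ingestion -----------------------------------------------------------


def aligned_pairs_from_sam(
    path: str,
    reference_offset: int = 0,
) -> Iterator[tuple[str, Alignment, Alignment]]:
    """Read externally produced SAM/BAM alignments as (pair id, mate1, mate2).

    CIGAR M/=/X map to M; soft-clipped bases are trimmed from the query;
    ``reference_offset`` shifts genome coordinates onto amplicon
    coordinates.  Pairs with an unmapped mate are skipped.
    """
    import pysam

    by_name: dict[str, dict[int, Alignment]] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            qual = (
                "".join(chr(q + 33) for q in rec.query_qualities)
                if rec.query_qualities is not None
                else None
            )
            cigar: list[tuple[str, int]] = []
            qpos = 0
            lead_clip = 0
            for op, n in rec.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    cigar.append(("M", n))
                    qpos += n
                elif op == 1:
                    cigar.append(("I", n))
                    qpos += n
                elif op == 2:
                    cigar.append(("D", n))
                elif op == 4:  # soft clip: trim
                    if not cigar:
                        lead_clip = n
                    qpos += n
                elif op == 5:
                    continue
                else:
                    raise ValueError(f"unsupported CIGAR op {op} in {rec.query_name}")
            qlen = sum(n for o, n in cigar if o in "MI")
            query = seq[lead_clip : lead_clip + qlen]
            q = qual[lead_clip : lead_clip + qlen] if qual else None
            score = rec.get_tag("AS") if rec.has_tag("AS") else 0
            aln = Alignment(
                query,
                rec.reference_start - reference_offset,
                tuple(cigar),
                int(score),
                q,
            )
            slot = by_name.setdefault(rec.query_name, {})
            slot[2 if rec.is_read2 else 1] = aln
            if 1 in slot and 2 in slot:
                yield rec.query_name, slot[1], slot[2]
                del by_name[rec.query_name]
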