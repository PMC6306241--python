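"""End-to-end quantification: FASTQ pairs → per-pair allele and outcome calls.

Stages mirror the amplicon analysis workflow: exact-pair deduplication,
optional adapter trimming, semi-global alignment of each mate (mate 2 is
reverse-complemented first; a mate failing the score floor is retried in
the opposite orientation), indel left-normalization, pair-level indel
extraction with a mate-consistency check, SNP-based allele assignment,
and WT/NHEJ/HDR classification.  Read-count accounting for every
exclusion class is returned alongside the per-pair table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .align import (
    Alignment,
    AmpliconAligner,
    Scoring,
    assign_allele,
    extract_indels,
    normalize_alignment,
)
from .classify import classify_outcome
from .fastq import ReadPairRecord
from .preprocess import dedup_pairs, strip_umi, trim_adapters
from .targets import AmpliconTarget, revcomp

logger = logging.getLogger(__name__)


@dataclass
class QuantifyResult:
    """Per-pair call table plus per-stage read accounting."""

    calls: pd.DataFrame
    counters: dict = field(default_factory=dict)


def _align_mate(
    aligner: AmpliconAligner, seq: str, qual: str, expect_revcomp: bool
) -> Optional[Alignment]:
    read = revcomp(seq) if expect_revcomp else seq
    q = qual[::-1] if expect_revcomp else qual
    aln = aligner.align(read, q)
    if aln is None:  # orientation fallback
        aln = aligner.align(revcomp(read), q[::-1])
    return aln


def quantify_pairs(
    pairs: Iterable[ReadPairRecord],
    target: AmpliconTarget,
    adapter: Optional[str] = None,
    dedup: bool = True,
    umi_length: int = 0,
    scoring: Optional[Scoring] = None,
    hdr_min_edits: Optional[int] = None,
    min_base_quality: int = 20,
) -> QuantifyResult:
    """Run the full editing-outcome pipeline for one target.

    The returned table has one row per surviving pair with columns
    ``pair_id, allele, outcome, indels, n_donor_seen, conflict, status``;
    excluded pairs (unaligned / inconsistent mates) appear with their
    status and empty calls.  ``counters`` partitions every input pair.
    """
    counters: dict = {"input_pairs": 0}
    aligner = AmpliconAligner(target.reference, scoring)

    def counted(src):
        for p in src:
            counters["input_pairs"] += 1
            yield p

    stream: Iterable[ReadPairRecord] = counted(pairs)
    if dedup:
        stream = dedup_pairs(stream, counters)
    if umi_length:
        stream = strip_umi(stream, umi_length)
    if adapter:
        stream = trim_adapters(stream, adapter, counters=counters)

    rows = []
    n_unaligned = n_inconsistent = 0
    for pair in stream:
        a1 = _align_mate(aligner, pair.r1_seq, pair.r1_qual, expect_revcomp=False)
        a2 = _align_mate(aligner, pair.r2_seq, pair.r2_qual, expect_revcomp=True)
        if a1 is None or a2 is None:
            n_unaligned += 1
            rows.append(
                {"pair_id": pair.pair_id, "allele": "", "outcome": "",
                 "indels": "", "n_donor_seen": 0, "conflict": False,
                 "status": "unaligned"}
            )
            continue
        a1 = normalize_alignment(a1, target.reference)
        a2 = normalize_alignment(a2, target.reference)
        pair_indels = extract_indels(a1, a2)
        if not pair_indels.consistent:
            n_inconsistent += 1
            rows.append(
                {"pair_id": pair.pair_id, "allele": "", "outcome": "",
                 "indels": ";".join(map(str, pair_indels.conflicts)),
                 "n_donor_seen": 0, "conflict": False, "status": "inconsistent"}
            )
            continue
        allele = assign_allele(a1, a2, target, min_base_quality)
        call = classify_outcome(a1, a2, pair_indels.indels, target, hdr_min_edits)
        rows.append(
            {
                "pair_id": pair.pair_id,
                "allele": allele.category,
                "outcome": call.outcome,
                "indels": ";".join(map(str, call.in_window_indels)),
                "n_donor_seen": call.donor_edits_seen,
                "conflict": call.conflict,
                "status": "ok",
            }
        )

    calls = pd.DataFrame(
        rows,
        columns=["pair_id", "allele", "outcome", "indels", "n_donor_seen",
                 "conflict", "status"],
    )
    counters["unaligned"] = n_unaligned
    counters["inconsistent"] = n_inconsistent
    counters["classified"] = int((calls["status"] == "ok").sum()) if len(calls) else 0
    logger.info(
        "quantify[%s]: %d classified, %d unaligned, %d inconsistent",
        target.name, counters["classified"], n_unaligned, n_inconsistent,
    )
    return QuantifyResult(calls, counters)
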