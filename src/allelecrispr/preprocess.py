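"""Duplicate read-pair removal and 3' adapter trimming.

Deduplication keys on the exact (R1 sequence, R2 sequence) tuple — the
appropriate PCR-duplicate model for amplicon libraries, where every
molecule shares the same start coordinates.  Trimming removes the longest
3' read suffix that aligns to a prefix of the adapter with at most a
configurable mismatch fraction, with an N counting as a mismatch.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Optional

from .fastq import ReadPairRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 3
DEFAULT_MAX_MISMATCH_FRAC = 0.1


def dedup_pairs(
    pairs: Iterable[ReadPairRecord],
    counters: Optional[dict] = None,
) -> Iterator[ReadPairRecord]:
    """Keep the first pair of every identical (r1, r2) sequence tuple.

    Order is otherwise preserved; the number of removed pairs is logged
    and, if ``counters`` is given, stored under ``"duplicates_removed"``.
    """
    seen: set[tuple[str, str]] = set()
    removed = 0
    for pair in pairs:
        key = (pair.r1_seq, pair.r2_seq)
        if key in seen:
            removed += 1
            continue
        seen.add(key)
        yield pair
    if counters is not None:
        counters["duplicates_removed"] = removed
    logger.info("dedup: removed %d duplicate pairs", removed)


def strip_umi(
    pairs: Iterable[ReadPairRecord], umi_length: int
) -> Iterator[ReadPairRecord]:
    """Drop the random N-mer tag from the 5' end of both mates.

    Amplicon libraries built with random-hexamer primer extensions carry
    the tag at the start of each read; it must be kept for duplicate
    removal (it individualises molecules) and removed before alignment.
    """
    if umi_length < 0:
        raise ValueError("umi_length must be >= 0")
    for pair in pairs:
        if umi_length == 0:
            yield pair
            continue
        yield ReadPairRecord(
            pair.pair_id,
            pair.r1_seq[umi_length:],
            pair.r1_qual[umi_length:],
            pair.r2_seq[umi_length:],
            pair.r2_qual[umi_length:],
        )


def trim_read(
    seq: str,
    qual: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[str, str]:
    """Remove the longest admissible adapter-prefix suffix from one read."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    max_len = min(len(seq), len(adapter))
    for length in range(max_len, min_overlap - 1, -1):
        suffix = seq[len(seq) - length :]
        prefix = adapter[:length]
        mismatches = sum(1 for a, b in zip(suffix, prefix) if a != b or a == "N")
        if mismatches <= max_mismatch_frac * length:
            return seq[: len(seq) - length], qual[: len(qual) - length]
    return seq, qual


def trim_adapters(
    pairs: Iterable[ReadPairRecord],
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    counters: Optional[dict] = None,
) -> Iterator[ReadPairRecord]:
    """Adapter-trim both mates; pairs with an emptied mate are dropped."""
    trimmed = dropped = 0
    for pair in pairs:
        r1, q1 = trim_read(pair.r1_seq, pair.r1_qual, adapter, min_overlap, max_mismatch_frac)
        r2, q2 = trim_read(pair.r2_seq, pair.r2_qual, adapter, min_overlap, max_mismatch_frac)
        if len(r1) < len(pair.r1_seq) or len(r2) < len(pair.r2_seq):
            trimmed += 1
        if not r1 or not r2:
            dropped += 1
            continue
        yield ReadPairRecord(pair.pair_id, r1, q1, r2, q2)
    if counters is not None:
        counters["pairs_adapter_trimmed"] = trimmed
        counters["pairs_dropped_empty"] = dropped
    logger.info("trim: %d pairs trimmed, %d dropped empty", trimmed, dropped)
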