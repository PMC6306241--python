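"""Paired-end FASTQ records and plain/gzipped FASTQ I/O."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class ReadPairRecord:
    """One paired-end read: id, mate sequences and quality strings."""

    pair_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str

    def __post_init__(self) -> None:
        for seq, qual, mate in ((self.r1_seq, self.r1_qual, 1), (self.r2_seq, self.r2_qual, 2)):
            if len(seq) != len(qual):
                raise ValueError(f"pair {self.pair_id} mate {mate}: |seq| != |qual|")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"pair {self.pair_id} mate {mate}: non-ACGTN base")


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPairRecord]:
    """Stream read pairs from two synchronised FASTQ files."""
    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        it1, it2 = FastqGeneralIterator(fh1), FastqGeneralIterator(fh2)
        for (id1, seq1, q1), (id2, seq2, q2) in zip(it1, it2, strict=True):
            pid1, pid2 = id1.split()[0], id2.split()[0]
            # tolerate /1 and /2 mate suffixes
            if pid1.endswith(("/1", "/2")):
                pid1 = pid1[:-2]
            if pid2.endswith(("/1", "/2")):
                pid2 = pid2[:-2]
            if pid1 != pid2:
                raise ValueError(f"unsynchronised FASTQ files: {pid1!r} vs {pid2!r}")
            yield ReadPairRecord(pid1, seq1.upper(), q1, seq2.upper(), q2)


def write_fastq_pairs(
    pairs: Iterable[ReadPairRecord], r1_path: str | Path, r2_path: str | Path
) -> int:
    """Write pairs as standard 4-line FASTQ (gzip if the path ends in .gz)."""
    n = 0
    with _open(r1_path, "wt") as fh1, _open(r2_path, "wt") as fh2:
        for p in pairs:
            fh1.write(f"@{p.pair_id}/1\n{p.r1_seq}\n+\n{p.r1_qual}\n")
            fh2.write(f"@{p.pair_id}/2\n{p.r2_seq}\n+\n{p.r2_qual}\n")
            n += 1
    return n
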