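"""Synthetic paired-end reads with known ground truth.

Two generators emulate the study conditions of an F1-hybrid amplicon
editing experiment: :func:`simulate_edited_pairs` draws per-allele
WT/NHEJ/HDR outcomes with a guide-specific indel spectrum, donor-templated
PAM-destroying substitutions, per-base sequencing substitution error, and
exact PCR duplicate pairs; :func:`simulate_bisulfite_pairs` draws
per-allele per-CpG methylation states and applies strand-aware bisulfite
conversion with configurable efficiency and failure rates.

Both mates are 150 nt and the amplicon must fit within R1+R2 so the mates
overlap and jointly cover every SNP, donor edit, and CpG.  Identical seeds
give byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import IndelDescriptor
from .fastq import ReadPairRecord
from .targets import AmpliconTarget, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_Q37 = "F"  # constant Phred quality


class SimConfigError(ValueError):
    pass


def apply_indel(sequence: str, indel: IndelDescriptor) -> str:
    """Apply one insertion/deletion to a sequence (coordinates checked)."""
    if indel.kind == "del":
        if indel.start < 0 or indel.start + indel.length > len(sequence):
            raise SimConfigError(f"deletion {indel} outside sequence of length {len(sequence)}")
        return sequence[: indel.start] + sequence[indel.start + indel.length :]
    if indel.start < 0 or indel.start > len(sequence):
        raise SimConfigError(f"insertion {indel} outside sequence of length {len(sequence)}")
    return sequence[: indel.start] + indel.bases + sequence[indel.start :]


def left_normalize_indel(indel: IndelDescriptor, reference: str) -> IndelDescriptor:
    """Shift a descriptor to its leftmost equivalent reference position."""
    start, bases = indel.start, indel.bases
    if indel.kind == "del":
        while start > 0 and reference[start - 1] == reference[start + indel.length - 1]:
            start -= 1
        return IndelDescriptor("del", start, indel.length)
    while start > 0 and reference[start - 1] == bases[-1]:
        bases = reference[start - 1] + bases[:-1]
        start -= 1
    return IndelDescriptor("ins", start, indel.length, bases)


@dataclass(frozen=True)
class OutcomeProbs:
    """Per-allele repair-outcome probabilities (must sum to 1)."""

    wt: float
    nhej: float
    hdr: float

    def __post_init__(self) -> None:
        probs = (self.wt, self.nhej, self.hdr)
        if any(p < 0 or p > 1 for p in probs):
            raise SimConfigError(f"outcome probabilities out of [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise SimConfigError(f"outcome probabilities must sum to 1: {probs}")


def default_spectrum(target: AmpliconTarget) -> tuple[tuple[IndelDescriptor, float], ...]:
    """A five-entry guide-specific indel spectrum around the cut site.

    Mirrors the recurrent-mutation structure seen in amplicon editing data:
    small deletions flanking the cut plus two distinct +1 insertions.
    """
    c = target.cut_site
    ref = target.reference
    raw = (
        (IndelDescriptor("del", c - 1, 1), 0.35),
        (IndelDescriptor("ins", c, 1, "A"), 0.25),
        (IndelDescriptor("del", c - 1, 2), 0.15),
        (IndelDescriptor("del", c - 2, 4), 0.15),
        (IndelDescriptor("ins", c, 1, "T"), 0.10),
    )
    return tuple((left_normalize_indel(ind, ref), w) for ind, w in raw)


@dataclass
class EditSimConfig:
    """Study conditions for one simulated editing experiment.

    Defaults describe a maternally methylated imprinted locus 96 h post
    transfection: paternal (euchromatic) mutation frequency 0.40, maternal
    (silenced) 0.12 (fold bias 3.3), HDR about one fifth of mutant reads,
    MiSeq-like 1e-3 substitution error, 5% PCR duplicates, balanced alleles.
    """

    n_pairs: int = 2000
    maternal: OutcomeProbs = field(default_factory=lambda: OutcomeProbs(0.88, 0.10, 0.02))
    paternal: OutcomeProbs = field(default_factory=lambda: OutcomeProbs(0.60, 0.32, 0.08))
    indel_spectrum: Optional[tuple[tuple[IndelDescriptor, float], ...]] = None
    error_rate: float = 0.001
    read_length: int = 150
    duplicate_rate: float = 0.05
    allele_mixture: float = 0.5  # fraction of molecules from the maternal allele
    umi_length: int = 6  # random hexamer from the first-round primers
    seed: int = 0

    def resolved_spectrum(self, target: AmpliconTarget):
        spec = self.indel_spectrum or default_spectrum(target)
        total = sum(w for _, w in spec)
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"spectrum weights sum to {total}, expected 1")
        out = []
        c, w_bp, ref = target.cut_site, target.window_bp, target.reference
        for ind, w in spec:
            norm = left_normalize_indel(ind, ref)
            lo, hi = norm.footprint
            if norm.kind == "del" and (lo < 0 or hi > len(ref)):
                raise SimConfigError(f"spectrum indel {ind} extends outside the amplicon")
            dist = 0 if lo <= c <= hi else min(abs(c - lo), abs(c - hi))
            if dist > w_bp:
                raise SimConfigError(
                    f"spectrum indel {ind} lies outside the +/-{w_bp} bp window around cut {c}"
                )
            out.append((norm, w))
        return tuple(out)

    def validate(self, target: AmpliconTarget) -> None:
        if self.n_pairs < 1:
            raise SimConfigError("n_pairs must be >= 1")
        for rate, name in (
            (self.error_rate, "error_rate"),
            (self.duplicate_rate, "duplicate_rate"),
        ):
            if not (0 <= rate < 1):
                raise SimConfigError(f"{name} must be in [0,1)")
        if not (0 <= self.allele_mixture <= 1):
            raise SimConfigError("allele_mixture must be in [0,1]")
        if self.umi_length < 0:
            raise SimConfigError("umi_length must be >= 0")
        usable = 2 * (self.read_length - self.umi_length)
        if len(target.reference) > usable:
            raise SimConfigError(
                f"amplicon ({len(target.reference)} nt) longer than the usable "
                f"R1+R2 span ({usable} nt); mates would not overlap"
            )
        self.resolved_spectrum(target)


def _random_umi(length: int, rng: np.random.Generator) -> str:
    if length == 0:
        return ""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _mates(
    molecule: str, read_length: int, umi_length: int, rng: np.random.Generator
) -> tuple[str, str]:
    """Mate sequences: a random hexamer-style tag, then the molecule.

    The tag emulates the random N-mer carried on each first-round primer,
    which gives PCR duplicates of distinct molecules distinct sequences so
    exact-pair deduplication removes only true duplicates.
    """
    r1 = (_random_umi(umi_length, rng) + molecule)[:read_length]
    r2 = (_random_umi(umi_length, rng) + revcomp(molecule))[:read_length]
    return r1, r2


def simulate_edited_pairs(
    target: AmpliconTarget, cfg: EditSimConfig
) -> tuple[list[ReadPairRecord], pd.DataFrame]:
    """Simulate edited-amplicon read pairs plus a per-pair truth table.

    Each molecule derives from one parental haplotype (reference with that
    strain's SNP bases) and one outcome: WT unchanged, NHEJ with one
    spectrum indel applied, HDR with every donor edit applied; then per-base
    substitution error.  Duplicate pairs are exact copies of an earlier
    pair.  Truth columns: pair_id, allele, strain, outcome, indel,
    is_duplicate, source_id.
    """
    cfg.validate(target)
    rng = np.random.default_rng(cfg.seed)
    spectrum = cfg.resolved_spectrum(target)
    spec_indels = [ind for ind, _ in spectrum]
    spec_w = np.array([w for _, w in spectrum])
    spec_cum = np.cumsum(spec_w) / spec_w.sum()

    haps = {
        "maternal": target.haplotype(target.cross.maternal_strain),
        "paternal": target.haplotype(target.cross.paternal_strain),
    }
    strains = {
        "maternal": target.cross.maternal_strain,
        "paternal": target.cross.paternal_strain,
    }
    donors = {a: target.donor_sequence(strains[a]) for a in haps}

    pairs: list[ReadPairRecord] = []
    rows: list[dict] = []
    for i in range(cfg.n_pairs):
        pid = f"sim{i:06d}"
        if i > 0 and rng.random() < cfg.duplicate_rate:
            src = int(rng.integers(0, len(pairs)))
            tmpl, trow = pairs[src], rows[src]
            pairs.append(ReadPairRecord(pid, tmpl.r1_seq, tmpl.r1_qual, tmpl.r2_seq, tmpl.r2_qual))
            rows.append(
                dict(trow, pair_id=pid, is_duplicate=True, source_id=trow["pair_id"])
            )
            continue
        allele = "maternal" if rng.random() < cfg.allele_mixture else "paternal"
        probs = cfg.maternal if allele == "maternal" else cfg.paternal
        u = rng.random()
        indel_id = ""
        if u < probs.wt:
            outcome, molecule = "wt", haps[allele]
        elif u < probs.wt + probs.nhej:
            outcome = "nhej"
            k = int(np.searchsorted(spec_cum, rng.random(), side="right"))
            k = min(k, len(spec_indels) - 1)
            molecule = apply_indel(haps[allele], spec_indels[k])
            indel_id = str(spec_indels[k])
        else:
            outcome, molecule = "hdr", donors[allele]
        r1, r2 = _mates(molecule, cfg.read_length, cfg.umi_length, rng)
        r1 = _add_errors(r1, cfg.error_rate, rng)
        r2 = _add_errors(r2, cfg.error_rate, rng)
        pairs.append(ReadPairRecord(pid, r1, _Q37 * len(r1), r2, _Q37 * len(r2)))
        rows.append(
            {
                "pair_id": pid,
                "allele": allele,
                "strain": strains[allele],
                "outcome": outcome,
                "indel": indel_id,
                "is_duplicate": False,
                "source_id": "",
            }
        )
    return pairs, pd.DataFrame(rows)


@dataclass
class BisSimConfig:
    """Study conditions for one simulated bisulfite amplicon experiment.

    ``meth_maternal``/``meth_paternal`` are per-CpG methylation
    probabilities (scalar, or one value per configured CpG).  The defaults
    describe a fully imprinted maternally methylated locus read with
    perfect conversion chemistry.
    """

    meth_maternal: float | Sequence[float] = 1.0
    meth_paternal: float | Sequence[float] = 0.0
    conversion: float = 1.0  # P(unmethylated CpG C reads as T)
    failure: float = 0.0  # P(methylated CpG C reads as T)
    n_pairs: int = 2000
    read_length: int = 150
    allele_mixture: float = 0.5
    umi_length: int = 6  # random hexamer from the first-round primers
    seed: int = 0

    def _probs(self, value, n_cpg: int) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (n_cpg,))
        if ((arr < 0) | (arr > 1)).any():
            raise SimConfigError("methylation probabilities must be in [0,1]")
        return arr

    def validate(self, target: AmpliconTarget) -> None:
        if self.n_pairs < 1:
            raise SimConfigError("n_pairs must be >= 1")
        for rate, name in ((self.conversion, "conversion"), (self.failure, "failure")):
            if not (0 <= rate <= 1):
                raise SimConfigError(f"{name} must be in [0,1]")
        if not target.cpg_sites:
            raise SimConfigError("target has no configured CpG sites")
        if len(target.reference) > 2 * (self.read_length - self.umi_length):
            raise SimConfigError(
                "amplicon longer than the usable R1+R2 span; reads would not cover all CpGs"
            )
        self._probs(self.meth_maternal, len(target.cpg_sites))
        self._probs(self.meth_paternal, len(target.cpg_sites))


def simulate_bisulfite_pairs(
    target: AmpliconTarget, cfg: BisSimConfig
) -> tuple[list[ReadPairRecord], pd.DataFrame]:
    """Simulate bisulfite-converted read pairs from an unedited locus.

    Per molecule an allele, a strand (top/bottom, 50:50), and a per-CpG
    methylation state vector are sampled.  On the top strand every non-CpG
    C reads T; a CpG C reads T with probability ``conversion`` when
    unmethylated and ``failure`` when methylated.  Bottom-strand molecules
    are represented in top-strand coordinates via the mirrored G→A
    conversion.  Truth columns: pair_id, allele, strain, strand,
    meth_states (e.g. "1011…"), n_methylated.
    """
    cfg.validate(target)
    rng = np.random.default_rng(cfg.seed)
    n_cpg = len(target.cpg_sites)
    probs = {
        "maternal": cfg._probs(cfg.meth_maternal, n_cpg),
        "paternal": cfg._probs(cfg.meth_paternal, n_cpg),
    }
    strains = {
        "maternal": target.cross.maternal_strain,
        "paternal": target.cross.paternal_strain,
    }
    haps = {a: strains[a] for a in strains}
    haps = {a: target.haplotype(s) for a, s in haps.items()}
    cpg_c = {p: i for i, p in enumerate(target.cpg_sites)}  # top-strand C
    cpg_g = {p + 1: i for i, p in enumerate(target.cpg_sites)}  # top-strand G

    pairs: list[ReadPairRecord] = []
    rows: list[dict] = []
    for i in range(cfg.n_pairs):
        pid = f"bis{i:06d}"
        allele = "maternal" if rng.random() < cfg.allele_mixture else "paternal"
        strand = "top" if rng.random() < 0.5 else "bottom"
        states = rng.random(n_cpg) < probs[allele]
        seq = list(haps[allele])
        if strand == "top":
            for pos, base in enumerate(seq):
                if base != "C":
                    continue
                k = cpg_c.get(pos)
                if k is None:
                    seq[pos] = "T"
                elif states[k]:
                    if rng.random() < cfg.failure:
                        seq[pos] = "T"
                elif rng.random() < cfg.conversion:
                    seq[pos] = "T"
        else:
            for pos, base in enumerate(seq):
                if base != "G":
                    continue
                k = cpg_g.get(pos)
                if k is None:
                    seq[pos] = "A"
                elif states[k]:
                    if rng.random() < cfg.failure:
                        seq[pos] = "A"
                elif rng.random() < cfg.conversion:
                    seq[pos] = "A"
        molecule = "".join(seq)
        r1, r2 = _mates(molecule, cfg.read_length, cfg.umi_length, rng)
        pairs.append(ReadPairRecord(pid, r1, _Q37 * len(r1), r2, _Q37 * len(r2)))
        rows.append(
            {
                "pair_id": pid,
                "allele": allele,
                "strain": strains[allele],
                "strand": strand,
                "meth_states": "".join("1" if s else "0" for s in states),
                "n_methylated": int(states.sum()),
            }
        )
    return pairs, pd.DataFrame(rows)
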