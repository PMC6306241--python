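"""Locus configuration for allele-resolved amplicon analysis.

An :class:`AmpliconTarget` bundles everything the pipeline needs to know
about one edited locus: the amplicon reference sequence, the guide
(protospacer + PAM) and the inferred blunt cut site, the strain SNPs that
distinguish the parental chromosomes of an F1 hybrid, the donor-programmed
substitutions used to detect homology-directed repair, and the CpG
positions scored in bisulfite amplicons.

Coordinates are 0-based half-open along the amplicon.  Cut sites are
between-base integers: ``cut_site == c`` means the double-strand break
falls between reference positions ``c - 1`` and ``c``.  This removes every
+/-1 ambiguity from the "InDel within N bp of the cut" test downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: strain identifiers used throughout (C57BL/6J and JF1/Ms)
STRAIN_B6 = "B6"
STRAIN_JF1 = "JF1"

DEFAULT_PROTOSPACER_LEN = 20
#: SpCas9 blunt cut 3 bp 5' of the PAM
DEFAULT_CUT_OFFSET = 3


class TargetConfigError(ValueError):
    """A target configuration violates an invariant; message names the entry."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Snp:
    """A strain-distinguishing SNP inside the amplicon."""

    position: int
    base_b6: str
    base_jf1: str
    name: str = ""


@dataclass(frozen=True)
class DonorEdit:
    """One donor-templated substitution (HDR marker)."""

    position: int
    ref_base: str
    donor_base: str


@dataclass(frozen=True)
class CrossPhase:
    """Parental phase of an F1 hybrid cross.

    In a BxJ cross B6 is maternal and JF1 paternal; JxB is the reciprocal.
    """

    cross: str  # "BxJ" | "JxB"

    def __post_init__(self) -> None:
        label = self.cross.replace("×", "x")
        if label not in ("BxJ", "JxB"):
            raise TargetConfigError(f"unknown cross label {self.cross!r}; expected BxJ or JxB")
        object.__setattr__(self, "cross", label)

    @property
    def maternal_strain(self) -> str:
        return STRAIN_B6 if self.cross == "BxJ" else STRAIN_JF1

    @property
    def paternal_strain(self) -> str:
        return STRAIN_JF1 if self.cross == "BxJ" else STRAIN_B6

    def allele_of(self, strain: str) -> str:
        if strain == self.maternal_strain:
            return "maternal"
        if strain == self.paternal_strain:
            return "paternal"
        raise ValueError(f"unknown strain {strain!r}")


def compute_cut_site(
    protospacer_start: int,
    strand: str,
    pam_start: int,
    protospacer_len: int = DEFAULT_PROTOSPACER_LEN,
    cut_offset: int = DEFAULT_CUT_OFFSET,
) -> int:
    """Blunt cut position for an SpCas9 guide, ``cut_offset`` bp 5' of the PAM.

    All positions are on the top strand of the amplicon.  For a ``+`` guide
    the PAM triplet starts immediately after the protospacer; for a ``-``
    guide the PAM appears as CCN on the top strand immediately before the
    protospacer's top-strand interval.  The returned integer is a
    between-base coordinate inside the protospacer.
    """
    if strand == "+":
        if pam_start != protospacer_start + protospacer_len:
            raise TargetConfigError(
                f"+ strand PAM at {pam_start} not adjacent to protospacer "
                f"[{protospacer_start},{protospacer_start + protospacer_len})"
            )
        return pam_start - cut_offset
    if strand == "-":
        if protospacer_start != pam_start + 3:
            raise TargetConfigError(
                f"- strand PAM at {pam_start} not adjacent to protospacer "
                f"starting at {protospacer_start}"
            )
        return pam_start + 3 + cut_offset
    raise TargetConfigError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class AmpliconTarget:
    """One target locus and everything needed to interpret reads from it."""

    name: str
    reference: str
    protospacer: str
    strand: str
    protospacer_start: int
    pam_start: int
    snps: tuple[Snp, ...]
    donor_edits: tuple[DonorEdit, ...]
    cpg_sites: tuple[int, ...] = ()
    cross: CrossPhase = field(default_factory=lambda: CrossPhase("BxJ"))
    window_bp: int = 10
    cut_offset: int = DEFAULT_CUT_OFFSET

    def __post_init__(self) -> None:
        self.validate()

    # -- derived ---------------------------------------------------------
    @property
    def cut_site(self) -> int:
        return compute_cut_site(
            self.protospacer_start,
            self.strand,
            self.pam_start,
            len(self.protospacer),
            self.cut_offset,
        )

    @property
    def pam_triplet(self) -> str:
        return self.reference[self.pam_start : self.pam_start + 3]

    def haplotype(self, strain: str) -> str:
        """Reference with this strain's SNP bases substituted."""
        seq = list(self.reference)
        for snp in self.snps:
            seq[snp.position] = snp.base_b6 if strain == STRAIN_B6 else snp.base_jf1
        return "".join(seq)

    def donor_sequence(self, strain: str) -> str:
        """Strain haplotype with every donor edit applied (perfect HDR product)."""
        seq = list(self.haplotype(strain))
        for ed in self.donor_edits:
            seq[ed.position] = ed.donor_base
        return "".join(seq)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.reference)
        err = TargetConfigError
        if not self.reference or set(self.reference) - set("ACGT"):
            raise err(f"target {self.name}: reference must be non-empty uppercase ACGT")
        if self.strand not in "+-":
            raise err(f"target {self.name}: strand must be + or -")
        ps, pl = self.protospacer_start, len(self.protospacer)
        if pl < 17 or pl > 24:
            raise err(f"target {self.name}: protospacer length {pl} implausible")
        if not (0 <= ps and ps + pl <= n):
            raise err(f"target {self.name}: protospacer interval [{ps},{ps + pl}) out of range")
        top = self.reference[ps : ps + pl]
        observed = top if self.strand == "+" else revcomp(top)
        if observed != self.protospacer:
            raise err(
                f"target {self.name}: protospacer does not match reference at "
                f"[{ps},{ps + pl}) on strand {self.strand}"
            )
        if not (0 <= self.pam_start and self.pam_start + 3 <= n):
            raise err(f"target {self.name}: PAM triplet out of range at {self.pam_start}")
        pam = self.pam_triplet
        if self.strand == "+":
            if pam[1:] != "GG":
                raise err(f"target {self.name}: PAM {pam!r} at {self.pam_start} is not NGG")
        else:
            if pam[:2] != "CC":  # CCN on top strand == NGG on the guide strand
                raise err(f"target {self.name}: PAM {pam!r} at {self.pam_start} is not CCN")
        cut = self.cut_site  # raises if PAM not adjacent
        if not (ps < cut < ps + pl):
            raise err(f"target {self.name}: cut site {cut} outside protospacer [{ps},{ps + pl})")

        snp_positions = set()
        for snp in self.snps:
            if not (0 <= snp.position < n):
                raise err(f"target {self.name}: SNP {snp.name or snp.position} out of range")
            if snp.base_b6 == snp.base_jf1:
                raise err(
                    f"target {self.name}: SNP at {snp.position} is uninformative "
                    f"(B6 == JF1 == {snp.base_b6})"
                )
            snp_positions.add(snp.position)
        pam_range = range(self.pam_start, self.pam_start + 3)
        pam_hit = False
        for ed in self.donor_edits:
            if not (0 <= ed.position < n):
                raise err(f"target {self.name}: donor edit at {ed.position} out of range")
            if self.reference[ed.position] != ed.ref_base:
                raise err(
                    f"target {self.name}: donor edit at {ed.position} ref_base "
                    f"{ed.ref_base!r} != reference {self.reference[ed.position]!r}"
                )
            if ed.position in snp_positions:
                raise err(f"target {self.name}: donor edit at {ed.position} collides with a SNP")
            if ed.position in pam_range:
                pam_hit = True
        if self.donor_edits and not pam_hit:
            raise err(f"target {self.name}: no donor edit falls inside the PAM triplet")
        for pos in self.cpg_sites:
            if not (0 <= pos < n - 1):
                raise err(f"target {self.name}: CpG position {pos} out of range")
            if self.reference[pos : pos + 2] != "CG":
                raise err(
                    f"target {self.name}: position {pos} is not the C of a CpG "
                    f"({self.reference[pos:pos + 2]!r})"
                )
        if self.window_bp < 0:
            raise err(f"target {self.name}: window_bp must be >= 0")

    # -- (de)serialisation -----------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "reference": self.reference,
            "protospacer": self.protospacer,
            "strand": self.strand,
            "protospacer_start": self.protospacer_start,
            "pam_start": self.pam_start,
            "snps": [[s.position, s.base_b6, s.base_jf1, s.name] for s in self.snps],
            "donor_edits": [[e.position, e.ref_base, e.donor_base] for e in self.donor_edits],
            "cpg_sites": list(self.cpg_sites),
            "window_bp": self.window_bp,
            "cut_offset": self.cut_offset,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict, cross: CrossPhase) -> "AmpliconTarget":
        try:
            return cls(
                name=d["name"],
                reference=d["reference"],
                protospacer=d["protospacer"],
                strand=d["strand"],
                protospacer_start=int(d["protospacer_start"]),
                pam_start=int(d["pam_start"]),
                snps=tuple(Snp(int(p), b6, jf1, *rest) for p, b6, jf1, *rest in d.get("snps", [])),
                donor_edits=tuple(
                    DonorEdit(int(p), r, a) for p, r, a in d.get("donor_edits", [])
                ),
                cpg_sites=tuple(int(p) for p in d.get("cpg_sites", [])),
                cross=cross,
                window_bp=int(d.get("window_bp", 10)),
                cut_offset=int(d.get("cut_offset", DEFAULT_CUT_OFFSET)),
            )
        except KeyError as exc:
            raise TargetConfigError(
                f"target {d.get('name', '<unnamed>')}: missing field {exc.args[0]!r}"
            ) from None


def load_targets(config_path: str | Path) -> list[AmpliconTarget]:
    """Load and validate all targets from a YAML/JSON experiment config.

    The file holds a top-level mapping with keys ``cross`` (``BxJ`` or
    ``JxB``) and ``targets`` (list of target mappings).  Every invariant is
    checked; violations raise :class:`TargetConfigError` naming the entry.
    """
    path = Path(config_path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "targets" not in doc:
        raise TargetConfigError(f"{path}: config must be a mapping with a 'targets' list")
    cross = CrossPhase(doc.get("cross", "BxJ"))
    return [AmpliconTarget.from_dict(t, cross) for t in doc["targets"]]


def dump_targets(targets: Sequence[AmpliconTarget], config_path: str | Path) -> None:
    """Serialise targets back to a config file (inverse of :func:`load_targets`)."""
    doc = {
        "cross": targets[0].cross.cross if targets else "BxJ",
        "targets": [t.to_dict() for t in targets],
    }
    with open(config_path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)  # JSON is valid YAML


def read_snp_table(tsv_path: str | Path) -> tuple[Snp, ...]:
    """Import SNPs from a 4-column TSV: position, B6 base, JF1 base, name."""
    snps = []
    with open(tsv_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TargetConfigError(f"{tsv_path}: bad SNP row {line!r}")
            pos, b6, jf1 = parts[:3]
            name = parts[3] if len(parts) > 3 else ""
            snps.append(Snp(int(pos), b6, jf1, name))
    return tuple(snps)


def donor_edits_from_ssodn(reference: str, ssodn: str, ssodn_start: int) -> tuple[DonorEdit, ...]:
    """Diff a donor oligo against the amplicon to get explicit edit triplets.

    The ssODN is assumed substitution-only (as used for PAM-destroying
    donors); any length mismatch with the covered reference window raises.
    """
    if ssodn_start < 0 or ssodn_start + len(ssodn) > len(reference):
        raise TargetConfigError("ssODN window extends outside the amplicon")
    window = reference[ssodn_start : ssodn_start + len(ssodn)]
    return tuple(
        DonorEdit(ssodn_start + i, r, a)
        for i, (r, a) in enumerate(zip(window, ssodn))
        if r != a
    )
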