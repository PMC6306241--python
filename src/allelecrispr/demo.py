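"""A bundled synthetic example locus.

``demo_target()`` builds a deterministic 250-nt amplicon shaped like the
maternally methylated imprinted CpG-island targets this pipeline was
designed for: a + strand guide with an NGG PAM, two PAM-region donor
edits, two strain SNPs flanking the cut at realistic distances, and 13
configured CpG dinucleotides.  The sequence is synthetic (it corresponds
to no genome); it is constructed so that the only CG dinucleotides in
either parental haplotype are the 13 configured ones, which keeps
bisulfite simulations exactly interpretable.
"""

from __future__ import annotations

import numpy as np

from .targets import AmpliconTarget, CrossPhase, DonorEdit, Snp

AMPLICON_LEN = 250
_PROTOSPACER = "GATTACAGATTACAGATTAC"  # CG-free 20-mer
_PROTO_START = 100
_PAM = "TGG"
_CPG_POSITIONS = (10, 20, 30, 50, 60, 70, 80, 130, 140, 150, 160, 170, 180)
_SNP_POSITIONS = (40, 190)


def demo_target(name: str = "demo_locus", cross: str = "BxJ") -> AmpliconTarget:
    """Deterministic synthetic imprinted-locus target for examples and tests."""
    rng = np.random.default_rng(20180417)
    seq = list("".join(rng.choice(list("ACGT"), size=AMPLICON_LEN)))

    protected = set(range(_PROTO_START, _PROTO_START + len(_PROTOSPACER) + 3))
    seq[_PROTO_START : _PROTO_START + 20] = _PROTOSPACER
    seq[_PROTO_START + 20 : _PROTO_START + 23] = _PAM

    for p in _CPG_POSITIONS:
        seq[p], seq[p + 1] = "C", "G"
        protected.update((p, p + 1))

    snps = []
    for p in _SNP_POSITIONS:
        ref_base = seq[p]
        alt = "T" if ref_base != "T" else "A"
        snps.append(Snp(p, ref_base, alt, f"snp{p}"))
        protected.add(p)

    donor_positions = (_PROTO_START + 15, _PROTO_START + 21)  # in protospacer + in PAM
    protected.update(donor_positions)

    # scrub accidental CG dinucleotides outside the configured set
    for _ in range(3):
        for q in range(AMPLICON_LEN - 1):
            if seq[q] == "C" and seq[q + 1] == "G" and q not in _CPG_POSITIONS:
                if q not in protected:
                    seq[q] = "T"
                elif q + 1 not in protected:
                    seq[q + 1] = "A"

    reference = "".join(seq)
    donors = tuple(
        DonorEdit(p, reference[p], "T" if reference[p] != "T" else "A") for p in donor_positions
    )
    target = AmpliconTarget(
        name=name,
        reference=reference,
        protospacer=_PROTOSPACER,
        strand="+",
        protospacer_start=_PROTO_START,
        pam_start=_PROTO_START + 20,
        snps=tuple(snps),
        donor_edits=donors,
        cpg_sites=_CPG_POSITIONS,
        cross=CrossPhase(cross),
    )
    _check_cpg_exclusive(target)
    return target


def _check_cpg_exclusive(target: AmpliconTarget) -> None:
    for strain in ("B6", "JF1"):
        hap = target.haplotype(strain)
        found = {i for i in range(len(hap) - 1) if hap[i : i + 2] == "CG"}
        if found != set(target.cpg_sites):
            raise AssertionError(
                f"demo locus CG set mismatch on {strain}: {sorted(found)}"
            )
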