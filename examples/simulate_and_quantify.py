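"""Simulate one editing experiment and quantify allele-specific outcomes.

Builds the bundled demo locus (an imprinted CpG island with a + strand
guide, two strain SNPs and two PAM-destroying donor edits), simulates
2,000 read pairs under the default study conditions, and runs the full
pipeline: dedup -> UMI strip -> align -> phase -> classify.
"""

from allelecrispr import EditSimConfig, demo_target, edit_summary, quantify_pairs, simulate_edited_pairs

target = demo_target()
cfg = EditSimConfig(n_pairs=2000, seed=1)
pairs, truth = simulate_edited_pairs(target, cfg)
result = quantify_pairs(pairs, target, umi_length=cfg.umi_length)
summary = edit_summary(result.calls)

print(f"locus: {target.name} (cut site {target.cut_site}, window +/-{target.window_bp} bp)")
print(f"read accounting: {result.counters}")
for allele in ("maternal", "paternal"):
    c = getattr(summary, allele)
    print(
        f"{allele:>8}: {c.n_total:5d} pairs | WT {c.n_wt} NHEJ {c.n_nhej} HDR {c.n_hdr} "
        f"| mutation frequency {c.mutation_frequency:.3f} | HDR share {c.hdr_share:.2f}"
    )
print(f"paternal fold bias: {summary.fold_bias:.2f}")
print(
    "-> the silenced maternal allele accumulates fewer mutations than the"
    " active paternal allele; the fold bias measures that chromatin effect."
)
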