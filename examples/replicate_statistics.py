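"""Replicate-level statistics: paired t, Cas9-dose ANOVA, kinetics.

Simulates three biological replicates at each of three Cas9-expression
levels (fold bias shrinking as Cas9 rises), then runs the tests an
experimentalist would: paired t between alleles, one-way ANOVA + Tukey
HSD on fold biases across doses, and the 24 h / 96 h kinetics percentage.
"""

from allelecrispr import (
    EditSimConfig,
    OutcomeProbs,
    anova_tukey,
    demo_target,
    edit_summary,
    kinetics_percent,
    paired_t,
    quantify_pairs,
    simulate_edited_pairs,
)

target = demo_target()


def run(p_mat, p_pat, seed, n_pairs=1500):
    cfg = EditSimConfig(
        n_pairs=n_pairs,
        maternal=OutcomeProbs(1 - p_mat, 0.8 * p_mat, 0.2 * p_mat),
        paternal=OutcomeProbs(1 - p_pat, 0.8 * p_pat, 0.2 * p_pat),
        seed=seed,
    )
    pairs, _ = simulate_edited_pairs(target, cfg)
    return edit_summary(quantify_pairs(pairs, target, umi_length=cfg.umi_length).calls)


doses = {"low": (0.06, 0.32), "intermediate": (0.12, 0.31), "high": (0.25, 0.30)}
fold_biases, mat_f, pat_f = {}, [], []
for dose, (pm, pp) in doses.items():
    fold_biases[dose] = []
    for rep in range(3):
        s = run(pm, pp, seed=100 + rep + 10 * len(fold_biases))
        fold_biases[dose].append(s.fold_bias)
        if dose == "low":
            mat_f.append(s.maternal.mutation_frequency)
            pat_f.append(s.paternal.mutation_frequency)

print("fold biases by Cas9 dose:",
      {d: [round(x, 2) for x in v] for d, v in fold_biases.items()})
t = paired_t(mat_f, pat_f)
print(f"paired t, maternal vs paternal at low Cas9: t = {t.statistic:.2f}, p = {t.pvalue:.4f}")
res = anova_tukey(fold_biases)
print(f"one-way ANOVA across doses: F = {res.f_statistic:.1f}, p = {res.pvalue:.2e}")
print(res.tukey.to_string(index=False))

s24 = run(0.12 * 0.23, 0.40 * 0.78, seed=7, n_pairs=4000)
s96 = run(0.12, 0.40, seed=8, n_pairs=4000)
for allele in ("paternal", "maternal"):
    k = kinetics_percent(
        getattr(s24, allele).mutation_frequency, getattr(s96, allele).mutation_frequency
    )
    print(f"{allele}: {k.percent:.0f}% of final mutations present at 24 h")
print(
    "-> allelic bias is strongest at low Cas9 dose and early time points:"
    " heterochromatin slows cutting rather than blocking it outright."
)
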