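"""Per-gene two-group statistics with empirical-Bayes variance moderation.

Fits the pooled-variance two-sample t gene by gene, then shrinks the
per-gene variances toward a fitted scaled-inverse-chi-square prior, which
stabilizes t statistics at small sample sizes (7 vs 7 here).
"""

import bigsea as bg

config = bg.SimConfig(
    n_genes=500,
    set_specs=[bg.SetSpec("responders", 25, "up", effect_size=2.5)],
    seed=1,
)
x, groups, _, _ = bg.simulate_expression(config)

raw = bg.fit_gene_linear_models(x, groups, reference_group="control")
moderated = bg.moderate_variances(raw)

table = moderated.to_frame().sort_values("p_adj")
print(table.head(8).round(4))
print()
n_raw = int((raw.p_adj < 0.05).sum())
n_mod = int((moderated.p_adj < 0.05).sum())
print(f"genes with BH-adjusted p < 0.05: {n_raw} (raw t) vs {n_mod} (moderated t)")
print(
    "log_fc is the treated-minus-control mean difference on the log2 scale;\n"
    "moderation typically recovers a few extra true responders by damping\n"
    "unstable small-variance genes."
)
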