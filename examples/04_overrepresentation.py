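"""Fisher's-exact pathway overrepresentation among selected genes.

Given a gene universe, a selected subset, and pathway membership, tests
each pathway for more selected members than proportional sampling predicts
(hypergeometric upper tail).
"""

import bigsea as bg

universe = [f"g{i:03d}" for i in range(200)]
sets = bg.GeneSetCollection(
    {
        "selenoamino_like": universe[:17],       # heavily selected below
        "background_pathway": universe[50:84],   # proportionally selected
        "untouched_pathway": universe[100:120],  # barely selected
    }
)
selected = universe[:8] + universe[50:57] + [universe[150], universe[151]]

table = bg.fisher_overrepresentation(selected, universe, sets, sided="greater")
print(table.round(4))
print()
print(
    "actual_count vs expected_count shows the enrichment; the odds ratio is\n"
    "the conditional-MLE estimate from the 2x2 table, and p_value the\n"
    "one-sided Fisher/hypergeometric tail."
)
print("\nHOMA-IR for glucose 90 mg/dl, insulin 10 uU/ml:", bg.homa_ir(90, 10))
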