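"""Hypergeometric gene-set enrichment of a target list.

For each pathway, the p-value is the upper tail of a hypergeometric draw
(overlap at least as large as observed, given the pathway size, target set
size and universe size), BH-adjusted across pathways.
"""

import numpy as np

from targetrank import enrich_pathways

rng = np.random.default_rng(0)
universe = [f"G{i:03d}" for i in range(300)]
gene_sets = {
    "cytokine_signaling": set(universe[:25]),
    "jak_stat": set(universe[20:45]),
    "toll_like_receptor": set(universe[50:70]),
    "random_background": set(rng.choice(universe, 30, replace=False).tolist()),
}

# A target list deliberately enriched for the first two pathways.
targets = universe[:15] + universe[30:35] + universe[200:210]

table = enrich_pathways(targets, gene_sets, universe)
print(table.to_string(index=False))
# Small adjusted p-values flag pathways whose members are over-represented
# among the targets; the overlap column is the raw shared-gene count.
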