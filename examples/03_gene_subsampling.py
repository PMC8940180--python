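"""Rank loci by phylogenetic usefulness and apply the sampling schemes.

Simulates 30 loci with varying discordance from the species tree,
computes the seven per-locus properties, locates the PCA axis along
which signal rises while bias falls, and selects loci under each scheme.
"""

import numpy as np

from chronospace import (
    compute_gene_properties,
    select_loci,
    simulate_loci,
    simulate_tree,
    usefulness_axis,
)

species = simulate_tree(16, root_age=400.0, seed=6)
moves = list(np.random.default_rng(6).integers(0, 5, 30))
loci = simulate_loci(species, 30, nni_moves_per_locus=moves,
                     alignment_length=150, seed=6, taxon_dropout=0.1)

table = compute_gene_properties(
    {k: v["alignment"] for k, v in loci.items()},
    {k: v["tree"] for k, v in loci.items()},
    species.to_newick(),
)
print("per-locus properties (first 3 loci):")
print(table.head(3).round(3).to_string())

axis = usefulness_axis(table)
print(f"\nusefulness axis: {axis.component}, "
      f"{100 * axis.variance_share:.1f}% of property variance")
print("loadings:", axis.loadings.round(2).to_dict())
print("signal properties (bootstrap, RF) load positively; bias properties")
print("(rate, root-to-tip variance, RCFV) negatively — high scores mark loci")
print("that are informative without being systematically biased.\n")

for scheme in ("usefulness", "signal", "clocklike", "occupancy", "random"):
    picked = select_loci(table, scheme, 5, seed=6, usefulness_scores=axis.scores)
    print(f"{scheme:>10}: {picked}")
print("\nclocklike selection first drops loci whose rate is more than one sd")
print("from the mean (ultra-conserved genes carry little dating information),")
print("then takes the smallest root-to-tip variances.")
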