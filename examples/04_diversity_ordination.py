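"""Describe and test community differences between two treatment groups.

Rarefies two groups of communities to a common depth, ordinates their
Jaccard distances with PCoA, and tests the group difference with PERMANOVA.
"""

import numpy as np

import ecoassembly as ea
from ecoassembly.core import CommunityTable

hom = ea.scenario_dataset(ea.ScenarioConfig.for_process(
    "homogeneous_selection", seed=11, n_samples=6))[0]
het = ea.scenario_dataset(ea.ScenarioConfig.for_process(
    "heterogeneous_selection", seed=11, n_samples=6))[0]

table = CommunityTable(
    [f"hom_{s}" for s in hom.sample_ids] + [f"het_{s}" for s in het.sample_ids],
    hom.taxon_ids,
    np.vstack([hom.counts, het.counts]),
)
table = ea.rarefy(table, depth=4000, seed=0)
print("Shannon diversity by group:")
h = ea.shannon(table)
print(f"  shared-filter group:   {h[:6].mean():.2f}")
print(f"  distinct-niche group:  {h[6:].mean():.2f}")

dm = ea.jaccard_matrix(table)
ordination = ea.pcoa(dm, n_axes=2)
print("\nPCoA of Jaccard distances (first two axes, "
      f"{100 * ordination.proportion_explained[:2].sum():.0f}% of positive "
      "inertia):")
print(ordination.to_dataframe().round(3).to_string())

groups = ["shared"] * 6 + ["distinct"] * 6
res = ea.permanova(dm, groups, n_perm=999, seed=5)
print(f"\nPERMANOVA: pseudo-F {res.pseudo_f:.2f}, p {res.p_value:.3f} "
      f"({res.n_permutations} permutations)")
print("A small p confirms the two assembly regimes produce distinct "
      "community compositions.")
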