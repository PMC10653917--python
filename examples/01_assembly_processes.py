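"""Quantify the ecological processes structuring a set of communities.

Generates twelve communities assembled under homogeneous selection (a
shared niche filter acting on a phylogenetically conserved trait), then
runs the two-step null-model framework: betaNTI for phylogenetic turnover,
RC_bray for taxonomic turnover, and the five-way process partition.
"""

import ecoassembly as ea

cfg = ea.ScenarioConfig.for_process("homogeneous_selection", seed=42)
table, tree, niche = ea.scenario_dataset(cfg)
print(f"communities: {table.n_samples} samples x {table.n_taxa} taxa, "
      f"{table.totals[0]} reads each, mean richness {table.richness.mean():.1f}")

pairs = ea.pairwise_assembly(table, tree, n_null=999, seed=1)
print("\nfirst pairs (betaNTI < -2 indicates homogeneous selection):")
print(pairs.head(5).round(3).to_string(index=False))

fractions = ea.process_fractions(pairs)
print(f"\nprocess fractions over {fractions.n_pairs} assigned pairs "
      f"({fractions.n_unassigned} unassigned):")
for process, frac in sorted(fractions.fractions.items(), key=lambda kv: -kv[1]):
    if frac:
        print(f"  {process:24s} {100 * frac:5.1f}%")
print("\nA dominant homogeneous_selection fraction means pairwise phylogenetic "
      "turnover is consistently lower than the tip-shuffling null expects -- "
      "the signature of a shared selective environment.")
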