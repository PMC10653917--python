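# ecoassembly

Null-model quantification of the ecological processes that structure
microbial communities, and a trait-based link from community structure to
community function.  Built for dilution-culturing experiments on
nitrate-mediated sulfur-oxidizing enrichments (sample × ASV count tables,
a 16S phylogeny, per-strain activity measurements), but applicable to any
sample × taxon table with a tree and optional trait data.

## What it computes

**Assembly processes.**  For every pair of communities the package
computes the β-mean-nearest-taxon distance

βMNTD = ½ [ Σ_{i∈k} w_ik · min_{j∈m} d(i,j) + Σ_{j∈m} w_jm · min_{i∈k} d(i,j) ],

with d the cophenetic (patristic) distance and w relative abundances, and
standardizes it against a null that reassigns taxa to tree tips uniformly
at random:

βNTI = (βMNTD_obs − mean_null) / sd_null.

βNTI < −2 ⇒ **homogeneous selection**; βNTI > 2 ⇒ **heterogeneous
selection**.  Remaining pairs are split by a Raup–Crick test on
Bray–Curtis: null communities preserve each sample's richness (taxa drawn
without replacement ∝ occurrence frequency) and read total (reads drawn ∝
pool relative abundance); RC_bray = 2·(P(BC_null < BC_obs) +
½ P(BC_null = BC_obs) − ½) ∈ [−1, 1].  RC_bray > 0.95 ⇒ **dispersal
limitation**; RC_bray < −0.95 ⇒ **homogenizing dispersal**; otherwise
**undominated** (mainly drift).  Per-group process fractions summarize the
pair-level labels.

**Structure–function linkage.**  Community function is estimated as the
abundance-weighted sum of species' functional activities,
F(e) = Σ_i f(x_i)·a(x_i), and tested against measured function by ordinary
least squares.  Strains can be classified into the three thiosulfate-
oxidation types (I: high sulfate yield with high nitrate consumption,
II: tetrathionate producers, III: low activity).

**Supporting pieces.**  TSV/CSV/Newick I/O with strict validation,
rarefaction by exact without-replacement subsampling, Shannon diversity,
Jaccard/Bray–Curtis distances, PCoA, PERMANOVA, and a synthetic-data
generator that assembles communities under each of the five processes
(Yule trees, Brownian niches, multinomial sampling, serial 10-fold
dilution), so every stage of the pipeline is testable end to end with
known ground truth.

## Worked example

```python
import ecoassembly as ea

cfg = ea.ScenarioConfig.for_process("homogeneous_selection", seed=42)
table, tree, niche = ea.scenario_dataset(cfg)
pairs = ea.pairwise_assembly(table, tree, n_null=999, seed=1)
print(ea.process_fractions(pairs).fractions)
```

This assembles 12 communities of 5,000 reads from a 64-taxon pool under a
shared niche filter and recovers the generating process
(`examples/01_assembly_processes.py` prints the full table):

```
sample_i sample_j  beta_mntd  beta_nti  bray_curtis  rc_bray               process
     S01      S02      0.740    -2.584        0.773    0.533 homogeneous_selection
     S01      S03      0.157    -2.135        0.260   -0.872 homogeneous_selection

process fractions over 66 assigned pairs (0 unassigned):
  homogeneous_selection     93.9%
  undominated                6.1%
```

βNTI below −2 for nearly every pair says phylogenetic turnover is much
lower than the tip-shuffling null expects — the signature of a shared
selective environment.  The other scripts in `examples/` cover the
structure–function regression, the dilution series, and
ordination/PERMANOVA.

A thin CLI mirrors the library:
`ecoassembly simulate|validate|diversity|assembly|function --help`.

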