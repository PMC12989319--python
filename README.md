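# microassembly

Community-assembly analysis for longitudinal 16S amplicon surveys:
preprocessing of an ASV count table (taxonomy filtering, rarefaction,
TMM normalisation), alpha/beta diversity with PCoA ordination and
PERMANOVA, and the null-model framework that partitions bacterial
community assembly into deterministic and stochastic processes — with a
synthetic-data generator so the whole pipeline runs and is tested
without any external data.

It is written for microbial ecologists who have an ASV table, a
phylogeny over the ASVs, a taxonomy and a sample design (here:
location × replicate line × generation × reproductive mode, as in
host–endosymbiont studies where *Wolbachia*-infected hosts reproduce
asexually), and who want to know not just *whether* communities differ
but *which assembly process* drives the differences.

## The statistics at the core

For every pair of samples (k, m):

* **βMNTD**, the abundance-weighted β mean nearest taxon distance,

  βMNTD(k,m) = ½ [ Σ_{i∈k} f_ik · min_{j∈m} d_ij + Σ_{j∈m} f_jm · min_{i∈k} d_ij ],

  where d is patristic distance and f relative abundance;
* **βNTI** = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null, the
  deviation from a taxa-shuffle null in null-standard-deviation units;
* **RCbray** = 2(p − ½), where p is the fraction of 999 null community
  pairs (preserving each sample's richness and read total, taxa drawn
  by occupancy, reads allocated by dataset-wide abundance) whose
  Bray–Curtis dissimilarity falls below the observed one.

Pairs are classified: βNTI < −2 homogeneous selection, βNTI > +2
variable selection; otherwise RCbray > 0.95 dispersal limitation,
RCbray < −0.95 homogenising dispersal, else undominated.

## Worked example

Simulate a 12-sample community assembled by homogenising dispersal
(all samples are multinomial resamples of one shared species pool) and
ask the null models which process they see:

```python
import numpy as np
from collections import Counter
from microassembly import (
    NullModelConfig, beta_nti, classify_pair, raup_crick_bray,
    simulate_scenario,
)
from microassembly.synthetic import recovery_scenario

bundle = simulate_scenario(recovery_scenario("homogenising_dispersal", seed=7))
cfg = NullModelConfig(n_null=999, seed=7)
nti = beta_nti(bundle.table, bundle.tree, cfg)
rc = raup_crick_bray(bundle.table, cfg)

iu = np.triu_indices(bundle.table.n_samples, 1)
bnti, rcv = nti.bnti.to_numpy()[iu], rc.to_numpy()[iu]
classes = Counter(classify_pair(b, r) for b, r in zip(bnti, rcv))
print(f"mean bNTI   = {bnti.mean():+.2f}")
print(f"mean RCbray = {rcv.mean():+.2f}")
for cls, n in classes.most_common():
    print(f"{cls:>24s}: {n}/{len(bnti)} pairs")
```

prints

```
mean bNTI   = +0.02
mean RCbray = -1.00
  homogenising_dispersal: 65/66 pairs
      variable_selection: 1/66 pairs
```

Phylogenetic turnover is indistinguishable from the null (|βNTI| ≤ 2 —
no selection), but compositional turnover sits far *below* the
Raup–Crick null (RCbray ≈ −1): the samples are more similar than chance
assembly allows, the signature of homogenising dispersal. 65 of 66
pairs are classified accordingly.

The same analysis runs end-to-end from files via the CLI:

```sh
microassembly simulate --scenario study --seed 1 --out fixture/
microassembly run --config run.cfg      # filter → rarefy → diversity → assembly
microassembly score --pairs results/pairs_full.tsv --truth fixture/truth.json
```

`run` executes both dataset tracks (full, and reduced with the
endosymbiont genus removed), writes tidy TSVs for alpha diversity,
Bray–Curtis matrices, PCoA coordinates, PERMANOVA, per-pair processes
and per-group process fractions, plus a manifest with SHA-256 digests —
two runs with the same config are byte-identical.

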