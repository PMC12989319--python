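# Methods

`microassembly` implements the community-analysis workflow of a
longitudinal 16S amplicon survey — preprocessing of an ASV count table,
alpha/beta diversity with ordination and PERMANOVA, and a null-model
partition of community assembly processes — together with a synthetic
generator that produces study-shaped data under known assembly regimes.

## Preprocessing

**Taxonomy filtering.** Contaminant lineages are removed by
case-insensitive exact label match at a single rank (default rules:
order Chloroplast, family Mitochondria, domain Archaea, and taxa with a
blank phylum, matched by the label "uncharacterised"). Substring
matching is deliberately rejected: accidental removals on partial names
are a worse failure mode than missing a synonym. Taxa absent from the
taxonomy table are treated as uncharacterised at every rank.

**Shallow-sample exclusion and rarefaction.** Samples whose total reads
fall below the rarefaction depth (default 1196) are excluded; a sample
at exactly the threshold is retained. Each remaining sample is then
subsampled once, without replacement, to exactly the threshold — a
multivariate hypergeometric draw per sample, seeded, with the seed
recorded in the run provenance. A single draw (rather than an average
over repeated draws) matches the single-table workflow the rest of the
pipeline consumes; all-zero taxon rows left behind are dropped and
counted.

**TMM normalisation.** Between-sample scaling factors follow the
trimmed mean of M-values exactly as in edgeR: M-values are log2 ratios
of library-size-normalised counts against a reference sample (the
sample whose 75th-percentile count/library-size ratio is closest to the
mean of those ratios), the extreme 30% of M-values and 5% of average
log-abundances are trimmed on each tail, the surviving M-values are
averaged with inverse delta-method variances as weights, and the
factors are rescaled to geometric mean 1. The test suite checks the
implementation against edgeR's `calcNormFactors` to 1e-8. Normalised
abundances are counts divided by effective library size (library size ×
factor), rescaled by the mean effective library size. A wholesale
doubling of a column therefore changes its library size, not its factor
— both factors stay 1 and normalisation equalises the column sums.

The pipeline runs two dataset tracks, mirroring the full/reduced design
of endosymbiont studies: the rarefied table (full), and the same table
with the endosymbiont genus removed (reduced; TMM-normalised for
diversity and ordination, integer counts for the Raup–Crick null).
Endosymbiont reads themselves are extracted from the TMM-normalised
*unrarefied* table as a separate per-sample count track.

## Diversity

Alpha diversity is observed taxon count and Shannon entropy
−Σ pᵢ ln pᵢ over non-zero relative abundances (natural log by default;
base configurable). Beta diversity is Bray–Curtis on raw (or
normalised) abundances. PCoA is the classical eigendecomposition of the
Gower-centred −½D² matrix; axes with positive eigenvalues are kept,
coordinates are scaled by √λ, negative eigenvalues are counted and
reported but not corrected (no Cailliez/Lingoes), and proportions of
variation are relative to the positive-eigenvalue total. PERMANOVA is
one-way per term: pseudo-F from squared-dissimilarity sums of squares,
significance from seeded label permutations with the observed
arrangement counted, so p ≥ 1/(permutations+1); 999 permutations by
default. Sequential multi-term decomposition is intentionally out of
scope — terms are tested independently.

## Assembly null models

**βMNTD.** For samples k, m with within-sample relative abundances f:

    βMNTD(k,m) = ½ [ Σ_{i∈k} f_ik · min_{j∈m} d_ij
                   + Σ_{j∈m} f_jm · min_{i∈k} d_ij ]

with d the patristic distance and minima over taxa present in the other
community. A shared taxon contributes 0 (its nearest neighbour is
itself); excluding conspecifics would change results materially, so the
convention is pinned and tested against picante's `comdistnt`
(abundance-weighted) to 1e-8. The unweighted variant replaces f by
1/richness, i.e. it averages the two per-sample means — when the two
samples differ in richness this is not identical to pooling all
nearest-taxon distances.

**βNTI.** The null shuffles the taxon↔tip assignment across the whole
tree (equivalently, permutes rows/columns of the patristic matrix).
Each of the 999 iterations yields the full pairwise βMNTD matrix, so
all pairs share each shuffle — the standard and dramatically cheaper
choice. βNTI = (obs − null mean)/null sd with the n−1 denominator
(pinned for byte-reproducibility). Permutations are drawn against a
canonical (sorted) taxon order, so results are invariant to the input
order of taxa. Pairs with zero null variance (e.g. a single effective
taxon) are reported missing with a warning and excluded from summaries.

**RCbray.** For a sample pair, null communities preserve each sample's
observed richness and read total: richness-many distinct taxa are drawn
with probability proportional to occupancy (Gumbel top-k), seeded with
one read each, and the remaining reads are allocated multinomially with
probability proportional to dataset-wide relative abundance among the
drawn taxa. Occupancy and abundance are computed from the table handed
to the operation (post-filter, post-rarefaction). With p the fraction
of null Bray–Curtis values below the observed one (ties within 1e-10
counting half — exact float equality is fragile), RCbray = 2(p − ½) ∈
[−1, 1]. Null communities are drawn per distinct (richness, depth)
combination from two independent banks shared across pairs: each pair
still compares two independent null streams with exactly the per-pair
null distribution, while the whole table costs one bank per
combination instead of one per pair. This mirrors the shared-shuffle
design of the βNTI null and keeps the 163-sample run in minutes.
Raup–Crick requires integer counts; the reduced track therefore feeds
it the rarefied-minus-endosymbiont table rather than the normalised one.

**Classification.** βNTI < −2 → homogeneous selection; βNTI > +2 →
variable selection; otherwise RCbray > 0.95 → dispersal limitation,
RCbray < −0.95 → homogenising dispersal, else undominated. Thresholds
are strict inequalities. Process summaries report per-group fractions
over within-group pairs only (same reproductive mode × generation),
matching how per-generation percentages are usually displayed;
cross-group pairs are available behind a flag.

Null iteration counts default to 999 for both nulls and are
configurable; 99 is the enforced minimum.

## Synthetic data

The generator produces a phylogeny, Brownian tip traits, a taxonomy, a
sample design and count tables under five regimes, each a generative
recipe targeting the construct the classifier measures — not a claim
about any real host system.

*Tree.* Pure-birth with exponential waiting times. Because Brownian
traits on a plain Yule tree are nearly uninformative about patristic
distance at community scale (most pairs coalesce near the root), an
optional clade-structured variant joins many small pure-birth clades by
long stems (stem length 4, clade depth rescaled to 0.1–1): traits then
carry clade-level signal, which is the situation in which
nearest-taxon metrics are informative at all.

*Communities.* Expected relative abundance combines a shared lognormal
baseline, per-sample lognormal noise, an optional Gaussian trait filter
exp(−(zᵢ − env)²/2σ²) with optima anchored at traits of actual tips,
per-sample Bernoulli occupancy thinning (ASV tables are sparse; without
thinning every community contains the whole pool and βMNTD degenerates
to 0), and multinomial read sampling at a lognormal per-sample depth.
Regimes: homogeneous selection (one shared optimum), variable selection
(optima cycled over 4 trait quantiles), dispersal limitation (no
selection, per-sample lognormal drift with sd 3), homogenising
dispersal (all samples multinomial resamples of one shared pool),
neutral (noise only). The documented recovery parameters are in
`synthetic.RECOVERY_PARAMS`; the 900-taxon study-scale analogues in
`synthetic.STUDY_PARAMS`.

*Study fixture.* 6 locations (3 sexual, 3 asexual) × 7 replicate lines
× 4 generations = 168 samples; ~900 taxa in 30 clades; lognormal read
depths (mean 3000, sdlog 0.45) so a handful of samples fall below the
1196-read threshold; two endosymbiont ASVs (genus *Wolbachia*, split
4:1) at an expected joint share of 0.55 in every asexual-location
sample; 12 contaminant taxa covering all four removal rules; and a
60-taxon ubiquitous core community (30% of host weight) — whole-body
insect surveys share common taxa, and TMM normalisation is undefined
for disjoint libraries. Each mode × generation group is assembled under
a fixed regime mapping stored in the truth record.

What passing tests show — and don't. The generator realises each
regime's defining mechanism in idealised form: clean clade structure,
exact pool sharing, no sequencing error, no compositional bias, no
host-genetic covariates. Recovery of regimes here demonstrates that the
statistics respond to the constructs they claim to measure, not that
any particular real dataset would be partitioned correctly. The
Raup–Crick null in particular is sensitive to how much between-sample
abundance variance the "neutral" background carries: tree-independent
data with strong per-sample noise is classified as dispersal
limitation, which is a property of the metric, not a bug in the
implementation; the neutral control is therefore scored on the
selection classes, which the βNTI null calibrates well (pooled mean ≈
0, sd ≈ 1, ~5% beyond ±2).

## Numerical and design choices

* Problem sizes: recovery scenarios use 200 taxa × 12 samples × 999
  null iterations; the calibration fixture 20 taxa × 10 samples × 50
  replicates; the end-to-end fixture 900 taxa × 168 samples. These keep
  the whole suite and the acceptance script desk-scale while leaving
  every statistic well resolved.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; Raup–Crick bank streams are spawned via `SeedSequence(seed,
  spawn_key=(bank, richness, depth))`, so results are independent of
  pair evaluation order.
* Result TSVs are written with sorted rows, fixed column order and
  floats at 12 significant digits; manifests record SHA-256 digests, so
  identical configurations produce byte-identical outputs.
* Missing Newick branch lengths are rejected rather than defaulted:
  every downstream metric is meaningless without lengths.
* PCoA eigenvalue tolerance: axes with λ ≤ 1e-10·max|λ| are treated as
  null space and omitted.

## Known limitations

* The PERMANOVA is one-way per term; confounded designs (here: mode and
  location are confounded by construction) yield marginal, not
  adjusted, R² values.
* RCbray on tables with unequal depths compares samples against nulls
  of matching depth, but Bray–Curtis itself is depth-sensitive; rarefy
  first.
* The taxa-shuffle βNTI null assumes trait–phylogeny signal; on trees
  without it (the plain Yule default) selection is undetectable by
  construction.
* The simulator does not model sequencing error, chimeras, primer bias
  or host genetics.
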