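# Methods

## The statistical problem

Single-nucleus SMART-seq of sorted meristem nuclei produces an
`N × F` integer count matrix with two dominant nuisance structures:
per-nucleus sequencing depth varying over more than an order of magnitude,
and tie-dominated sparsity (most entries zero).  Under these conditions
raw pairwise correlation between features is confounded: any two features
whose detection tracks depth appear positively correlated.  The package's
central statistic removes this confound by explicit null subtraction
rather than by normalizing counts, because normalization cannot fix rank
statistics on zero-inflated data.

## Adjusted correlation

For features *i, j* observed over nuclei `1..N`:

* **observed** — Spearman correlation with average ranks (midranks).  The
  tie convention is part of the definition: with sparse counts most ranks
  are ties at zero, and alternative conventions change the statistic.
* **expected** — the mean Spearman correlation over `n_null` Monte-Carlo
  replicates in which every feature's observed total count `T_i` is
  independently redistributed across nuclei as
  `Multinomial(T_i, d / Σd)`, with `d` the vector of per-nucleus total
  depths over all features.  Each replicate preserves the two marginals
  that define the confound — the pair's expression levels and the depth
  profile — while destroying all real co-variation.
* **adjusted** = observed − expected, elementwise.

Default `n_null = 100`; the per-entry Monte-Carlo standard error is
reported alongside, and a replicate in which a feature happens to come out
constant contributes nothing to that entry's average (nan-aware
accumulation).  `n_null < 10` is rejected as unstable.  Pairs involving a
feature with zero observed variance are not-applicable (NaN) and are
excluded from clustering and summaries rather than imputed; the diagonal
is always excluded.

The null is a resampling construction.  An analytic expectation (e.g. by
binning features on abundance) would be faster but requires distributional
assumptions the resampling avoids; the Monte-Carlo route is exact in the
limit and its error is quantified.

Calibration, checked by the test suite: on a 200-nuclei × 200-feature
matrix of independent features with lognormal depth (σ = 0.6), mean
observed off-diagonal Spearman is ≈ +0.74 while |mean adjusted| < 0.01.
Signal preservation: feature pairs sharing a planted program remain
positively correlated after adjustment and exceed cross-program pairs
(one-sided Mann–Whitney p < 0.01).

## Seed-anchored clustering

Each target feature is summarized by its vector of adjusted correlations
against a fixed seed panel.  Two panels are used: the planted stem-cell
seed genes alone (when clustering the seed genes themselves), and seeds
plus the three cell-cycle markers (when profiling TEs) — cell-cycle
covariation is a real, dominant axis in these data and anchoring on it
lets cycle-coupled TE programs form coherent clusters.

Distance is `1 − Pearson` between profile vectors, computed
pairwise-complete over NaN entries; linkage is average; the tree is cut at
k with `scipy.cluster.hierarchy.fcluster(criterion="maxclust")`.  These
choices are deterministic, scale-free, and standard for correlation
profiles; they are defaults, not constants.  Features whose profile has
zero variance are excluded before distance computation (correlation
distance undefined).  Cluster indices are relabeled in order of first
appearance, so the partition is invariant to input permutation up to
labeling.

k is either fixed by the caller or selected as the maximizer of mean
silhouette width over k = 2..6 (ties toward smaller k).  On planted
structure the best silhouette is ≥ ~0.85; pure-noise profiles reach at
most ~0.3 for short (8-seed) panels and ~0.1 for 30+-seed panels.  The
low-confidence threshold of 0.35 separates the regimes; below it the
smallest candidate k is returned with a warning rather than a spurious
optimum.

## Nucleus classification and group tests

* **Marker groups** — a nucleus expresses a marker when its count
  ≥ 2 reads (configurable).  AGO5+AGO9 double positives proxy the L2
  (subepidermal) layer, AGO9-only the L1.  AGO5-only nuclei are
  biologically unexpected; they are reported as their own group, never
  merged or dropped.  "none" means < 2 reads of each marker — the
  inclusion threshold is read as applying to the AGO-positive groups.
* **Cell cycle** — phase of the strictly maximal marker
  (HTR13 → S-G2, CDT1A → G1, CYCB1.1 → G2-M) with ≥ 1 read; ties and
  all-zero profiles stay unassigned.  The strict-argmax rule is a
  reconstruction; only the marker-to-phase mapping is given by the
  experimental design.
* **Per-nucleus TE-cluster expression** — mean depth-normalized count
  (counts per 10,000) over the cluster's member TEs.  The normalization
  scale is a documented choice; rank-based tests downstream are invariant
  to it.
* **Mann–Whitney U** — when both groups have ≤ 8 observations the
  two-sided p is computed by full enumeration of all C(n+m, n)
  assignments of the pooled midranks (correct under ties); otherwise by
  the normal approximation with tie correction and *no* continuity
  correction.  The continuity correction makes null p-values visibly
  conservative at the group sizes typical here (10–100 nuclei); without
  it the null p distribution is uniform (KS-checked in the suite).
* **Set overlap** — hypergeometric upper tail
  `P(X ≥ |A∩B|)` for `X ~ Hypergeom(|U|, |A|, |B|)`, with fold =
  observed/expected overlap.  Verified against exhaustive enumeration for
  all universes up to size 12.
* **Multiple testing** — group comparisons report raw p and
  Benjamini–Hochberg q side by side.

## sRNA cargo summaries

Reads are records (feature, length 18–26 nt, 5′ nucleotide as RNA,
relative 5′-end position in [0,1), weight).  Multimapping is handled by
fractional weights (1/n mappings); every summary is weight-aware.

* The size × 5′-bias table reports per-length and overall proportions.
* Metaplots scale each TE body to `body_bins` bins (default 100) and add
  each read's weight to `floor(rel_pos · bins)`; minus-strand features
  are flipped so bin 0 is the biological 5′ end.  Flanks are off by
  default (pure scaled-body plot); when `flank_bp > 0`, out-of-body reads
  map onto `body_bins // 10` flank bins per side and reads beyond the
  flank are out of scope.  In raw mode total matrix mass equals total
  in-scope read weight exactly.
* Cargo-vs-input enrichment is a per-feature two-sided binomial test of
  the cargo count against the input proportion (library-size normalized),
  BH-corrected, with the conventional thresholds q < 0.05 and
  log2 fold-change > 1, after removing features under 5 reads-per-million
  in both libraries.  This is a deliberate replacement for a
  replicate-aware negative-binomial model: with single libraries there is
  no dispersion to estimate, and the binomial test is exactly calibrated
  under the no-enrichment null (KS-checked).  Enriched sets can also be
  supplied externally and fed straight into the overlap statistics.
  A zero input count is handled with a half-read pseudo-proportion, which
  keeps the swapped-library antisymmetry of log2FC exact.

## The synthetic-data generator

The generator exists so that every pipeline stage has planted ground
truth.  It emulates, at desk scale, a sorted-nuclei SMART-seq experiment:

* **Count model** — per-nucleus multinomial over a fixed rate vector.
  This is the load-bearing choice: multinomial sampling at heterogeneous
  depth produces the depth-induced spurious correlation the adjusted
  statistic removes, so the null-calibration tests are meaningful.  Row
  sums equal the drawn depths exactly.
* **Depth** — lognormal, median 8000 reads, σ = 0.6, mirrored by a
  DAPI-like covariate (depth × 20% lognormal noise).  The real study's
  depth distribution is not published; these are modeling choices exposed
  in the config.
* **Populations** — niches L1 0.2 / L2 0.3 / other 0.5; cycle G1 0.5 /
  S-G2 0.3 / G2-M 0.2, independent of niche.
* **Programs** — a member feature has rate `base` inside its program's
  compartment and `base/effect` outside, so `effect` is the in/out fold
  change, `effect = ∞` gives exactly zero outside, and `effect = 1`
  disables the program entirely — including its shared activity factor —
  which makes the `te_program_effect = 1` configuration a true negative
  control.  Active programs additionally carry a shared lognormal
  activity factor (σ = 0.8) drawn per nucleus, producing within-program
  co-fluctuation beyond the binary niche indicator.
* **Planted structure** — markers CLV3 (all nuclei), AGO5 (L2),
  AGO9 (L1+L2), HTR13/CDT1A/CYCB1.1 (by phase, effect 50); two 15-gene
  seed programs (general stem = L1+L2, L2-specific), sharing their
  activity factors with TE programs; three TE programs (effect 8):
  a cycle-coupled background program (elevated in S-G2/G2-M, genome-like
  superfamily mix, short, mostly chromosome arms) and two LTR/Gypsy-
  dominated, long, mostly pericentromeric programs — one spanning L1+L2
  (the AGO9 domain, factor shared with the general-stem seeds) and one
  strictly L2 (the AGO5 domain, factor shared with the L2 seeds).

Two design points deserve emphasis.  First, the background TE program is
niche-uniform but cycle-coupled: a program with no co-fluctuation at all
has a flat, noise-dominated seed profile and is unrecoverable by any
clustering method, whereas replication-coupled background TE expression
is both realistic (nuclear DNA content is the dominant covariate of
detection in these experiments) and gives the program a coherent identity
against the cell-cycle seeds.  Second, the two Gypsy programs differ in
layer breadth (L1+L2 vs L2): when both are strictly L2 their profiles
share the single dominant "L2-ness" axis and merge under average linkage
for an appreciable fraction of random seeds; the layer contrast — the
same contrast the marker-group analysis measures — makes recovery robust
(k = 3 and ARI ≥ 0.97 across all tested seeds).

What the generator does **not** emulate: UMIs, doublets, ambient RNA,
amplification noise beyond multinomial sampling, the real gene count
(21k), or the real sparsity — at default depth the median nucleus detects
~57% of features, denser than a real SMART-seq run (~13%).  Sparser
settings (median depth ≤ 5000) make planted-structure recovery unreliable
at 200 nuclei, so the default favors a clean testbed over realistic
sparsity; `depth_lognormal_mu` is the knob.  Consequently, passing tests
demonstrate the statistics' correctness and calibration, not performance
on data sparser or noisier than the simulation.

* **Cargo sets** — drawn at a requested Jaccard overlap with the union of
  the two niche TE programs (overlap count solved from
  `J = o / (s + p − o)`, then sampled uniformly); infeasible size/overlap
  combinations are rejected with a message.
* **sRNA reads** — lengths and 5′ nucleotides from user distributions;
  positions uniform or end-biased (0.4 Beta(1,6) + 0.2 uniform +
  0.4 Beta(6,1)), concentrating ~42% of mass in the outer deciles.

## Reproducibility

A single integer seed drives one named RNG stream per operation
(`SeedSequence(seed, spawn_key=crc32(name))`), so stages can be re-run
independently with identical draws.  The pipeline manifest records
config, seed, selected k values and a sha256 per output file; re-running
an identical config reproduces the manifest byte for byte.

## Problem sizes

Defaults throughout — 200 nuclei, 2000 genes + 500 TEs, 30 seed genes,
100 null replicates — run the full pipeline in seconds and the complete
test suite in well under a minute of compute per module, while keeping
every statistic in its intended regime (hundreds of nuclei, tie-dominated
counts).

## Known limitations

* The adjusted-correlation null assumes features are independent given
  depth under H0; structured technical noise (plate, batch) would need an
  extended null.
* `flag_high_variance` is a reproducible stand-in for a curated exclusion
  list; on real data the curated list should be preferred.
* The binomial enrichment test ignores biological replicate dispersion;
  with replicated libraries a negative-binomial model is the better tool
  and its output can be supplied directly.
* Exact Mann–Whitney enumeration is limited to groups of ≤ 8; beyond that
  the normal approximation is used (within 10% of exact p at sizes 8–20
  in the suite's checks).
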