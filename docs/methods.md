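# Methods

## The ratio-matrix screen

The screen targets a two-environment common-garden design: the same species
grown at a near-native site (JH) and a stress site (QG), with expression
(FPKM) and a physiological trait (WUE = A/E) measured on disjoint individual
sets at each site. Because no individual is measured in both environments,
per-individual plasticity is not observable; instead, for each quantity we
form the matrix of all cross-environment ratios QGᵢ/JHⱼ. The trait ratio
matrix and each gene's expression ratio matrix are then compared by a
Mantel-type permutation test using the Spearman rank correlation of the
flattened cells.

Two properties of this construction matter:

* A multiplicative factor applied to all of a gene's values at one site
  (an environment main effect, or any per-gene scale) multiplies every cell
  equally and therefore cannot change the cell ranks. The screen is blind to
  uniform environmental shifts by design; it detects whether *which
  individuals* deviate up or down in expression matches which individuals
  deviate in the trait.
* The matrix is not a distance matrix: rows and columns index different
  individuals and there is no diagonal. All n₁ × n₂ cells are used.

### Permutation null and p-value

The null relabels the gene matrix's axes. The default scheme draws an
independent permutation of the rows (QG individuals) and of the columns
(JH individuals), reflecting their disjointness; a `joint` scheme (one
shared permutation on both axes, square matrices only) is provided because
distance-matrix Mantel implementations permute a single individual set, and
comparisons against such tools need it. Both schemes are exchangeable under
the null hypothesis of no individual-level association.

p = (1 + #{r_perm ≥ r_obs − 1e−12}) / (n_perm + 1), upper tail by default
(positive association is the scientific hypothesis), two-sided by flag. The
1e−12 guard treats float-identical statistics as ties rather than letting
rounding decide an exceedance. The smallest attainable p is 1/(n_perm + 1);
with the 10,000-permutation default that is ≈ 1e−4. An exhaustive
enumerator over all row × column relabelings serves as the oracle for small
matrices (3×3 → 36 relabelings) and in tests.

When no cells are masked, a permutation only permutes the precomputed rank
matrix, so each draw reduces to a gather and a dot product; 500 genes ×
199 permutations at 39×39 run in ~2 s on one core. With masked cells
(zero denominators under the `mask` policy) the jointly defined cell set
changes per permutation and ranks are recomputed — correct but slower.
Permutations with fewer than 3 jointly defined cells or zero rank variance
are skipped and not counted as exceedances, which can only make p
conservative.

### Filtering, zeros, degeneracy

Genes whose median FPKM over all samples (sites pooled) is zero are removed
before screening. For surviving genes, cells with a zero denominator are
masked by default; a pseudocount policy ((x+c)/(y+c), default c = 0.5) is
available for heavily zero-inflated data. Genes whose ratio matrix has
fewer than 3 usable cells or constant ranks (e.g. expression constant
within each site) are reported with r = p = NaN, never as candidates, and
never abort a run.

### Determinism

Each gene draws permutations from an independent child stream of the master
seed, keyed by the gene's rank in the sorted gene-id list. Screen output is
therefore bitwise identical for a given seed regardless of the order genes
appear or are processed in; output rows are sorted by descending r with
gene id as the tie-break.

## Synthetic data

The generator reproduces the statistical skeleton the screen assumes, at
the field design's scale: two sites × 39 individuals from 14 source
populations (no population structure is modelled — none was detected in the
source study system). For gene g, individual i, site s:

log xᵍᵢ = μ_g + G_g(genotype) + E_g·1[s=QG] + GE_g(genotype)·1[s=QG] + ε

with μ_g ~ N(2.5, 1) (FPKM scale ~e^2.5 ≈ 12), genotype classes uniform over
`n_genotypes_per_gene`, G ~ N(0, σ_g²), E_g ~ N(0, σ_e²),
GE ~ N(0, σ_gxe²), ε ~ N(0, σ_noise²). Defaults σ_g = 0.3, σ_e = 0.5,
σ_gxe = 0.2, σ_noise = 0.5 give realistic log-scale dispersion and
multiplicative between-site shifts mostly within ±e. FPKM = exp(log x);
zero inflation replaces a given fraction of entries with 0 after
exponentiation — the simplest mechanism that exercises the median-zero
filter and the zero-denominator policy, not a model of dropout biology.

The trait is WUE-like: baseline β₀ = 3.6 (between the two sites' observed
means), plus `effect_size` times the sum of the causal genes' standardized
latent log expression, plus N(0, σ_trait²) noise, truncated at 0.05 to keep
the ratio positive. The trait loads on the *latent* (pre-zeroing)
expression, so ground truth is unambiguous even under heavy zero inflation.

`causal_cor` routes a fraction of the causal genes' noise variance through a
shared per-individual latent factor, making them co-expressed like genes of
one regulated pathway. This is the knob that creates a genuinely strong
per-gene signal: with n_c independent causal genes, each gene's correlation
with the trait is capped at 1/√n_c regardless of `effect_size` (ten
independent causal genes cap at r ≈ 0.32, which is inside the null Mantel
noise band of a 200-gene screen), whereas co-expressed causal genes can each
explain most of the trait variance. The recovery experiments use
causal_cor = 0.6.

What the generator does not emulate: count-level sampling noise,
gene-length and library-size artefacts of FPKM, correlated null genes,
linkage between SNPs, and population structure. Passing tests demonstrate
the screen's statistical behaviour (calibration, power, invariances) under
the assumed generative structure, not robustness to those real-data
features.

`perturb_trait` shuffles a chosen fraction of trait values within each
site — the negative control: it preserves both marginal trait distributions
while destroying individual-level association, collapsing the candidate
rate to ≈ α.

## Expression profiles

* Fold change: arithmetic mean FPKM per site, ratio QG/JH; log₂ of ±1
  bounds the 2-fold classes. Exact log₂ = 0 (within 1e−12) is reported as a
  separate `unchanged` class rather than forced into up/down; a zero JH
  mean gives an undefined record excluded from class fractions.
* Differential expression: Shapiro–Wilk at α = 0.05 on each site's values
  gates between Welch's t-test (both normal-looking) and the Wilcoxon
  rank-sum test. Welch rather than pooled-variance because between-site
  variance equality has no justification here. A constant group is treated
  as non-normal; a gene constant and equal in both groups gets p = 1.
  BH adjustment runs across the tested gene set; significance at adjusted
  p < 0.05.
* Normalization: each gene divided by its pooled-sample SD (n−1
  denominator). Mean-centering is optional and off by default — the
  normalization is deliberately scale-only, and the `center` flag exists
  because either convention is defensible.
* Clustering: average-linkage agglomerative clustering on Pearson
  correlation distance (1 − r), cut to k = 4 by default (configurable);
  correlation distance makes the result invariant to per-gene affine
  rescaling, so it groups profile *shapes*. Constant profiles are rejected
  (undefined correlation).

## Genetic variation and G×E

Haplotypes (the concatenated alleles at a gene's SNP positions) act as
alleles; a genotype is an individual's unordered haplotype pair. Phasing is
upstream: panels enter as data.

π = n/(n−1) · Σ_{i<j} 2xᵢxⱼd(i,j) / L over the n haplotype copies of the
individuals considered (one site, or pooled), d the SNP-position Hamming
distance, L the transcript length in bp. This is the unbiased (Nei) form;
algebraically it equals the plain average pairwise difference over all
C(n,2) copy pairs divided by L, which is how the test oracle computes it.
Per-bp scaling is the default because published per-transcript diversities
(~1e−4–1e−3 over ~1.6 kb transcripts) are only consistent with it; per-SNP
scaling is a flag.

For the ANOVA, genotype groups with fewer than `min_n = 3` individuals
(pooled over sites) are dropped; a gene with fewer than two surviving
groups is skipped as uninformative. Step 1 fits
FPKM ~ genotype + site + genotype:site with type-II sums of squares — the
groups are unbalanced across sites by construction, and type II tests each
main effect adjusted for the other without ordering artefacts. If the
interaction is significant at α = 0.05 the gene is classified GEI; otherwise
the additive model is refitted and main effects decide between G+E, G, E and
none. An empty genotype × site cell makes the interaction inestimable; the
gene falls back to the additive model with a warning. The ANOVA runs on raw
FPKM by default (a log flag exists) — the classification is of the measured
transcriptional level itself.

Expected accuracy: with effect SD ≥ 3× noise SD the designed-class recovery
rate is ~0.9; the residual errors are dominated by α-level false positives
on null genes (each null gene has ≈ 14% chance of tripping one of three
tests at α = 0.05), which is inherent to the two-step procedure rather than
an implementation artefact.

## Summary statistics and rounding

Per-category means of screen coefficients are rounded half-up to 3
decimals, percentages half-up to 2; half-up is chosen over banker's
rounding to match conventional table reporting, and only differs at exact
.0005 boundaries. All percentages are 100·k/n over the candidate count. The
fold-change-vs-coefficient correlation is Pearson's r on (ratio,
coefficient) pairs.

## Problem sizes in the test suite

The suite and the acceptance script favour many small, decisive
experiments: null calibration uses 500 genes × 199 permutations at the full
39+39 design; recovery uses 200 genes × 5 seeds; the exact-enumeration
oracle uses 3×3 matrices (36 relabelings); ANOVA accuracy uses 40 genes per
class. These sizes give stable statistics while keeping a full run in tens
of seconds on one core.

## Known limitations

* The screen's null assumes exchangeable individuals within each site; site
  substructure (e.g. family effects) would inflate apparent associations.
* Masked-cell permutation p-values are conservative, not exact.
* The DE stage tests mean/location shifts only; variance changes between
  sites are not flagged.
* The fixture of published candidate statistics carries two documented
  source-table discrepancies (one gene id, one category assignment),
  flagged in the fixture's note column with the candidate list and the
  categorization table taken as authoritative respectively.
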