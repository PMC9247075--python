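# Methods

This note documents the statistical machinery of `survnet`: what each
stage computes, the conventions and defaults it uses, what the synthetic
cohort generator does and does not emulate, and the design choices made
where the literature leaves the details open.

## Cohort model and the synthetic generator

The design is a two-group survival cohort: short-term (ST, overall
survival ≤ 12 months) versus long-term (LT, ≥ 36 months) survivors,
default 10 ST and 9 LT. The generator simulates raw RNA-seq counts

x_ij ~ NB(s_j · 2^(m_ij), α_i),  Var = μ + α μ²,

with per-gene baseline means log-normal (log-mean 4.0, log-SD 1.5, i.e. a
median of ~55 counts with a long right tail), per-gene dispersions
α_i ~ Gamma(shape 2, scale 0.05) (mean 0.1, typical of bulk tissue), and
per-sample library-size factors s_j log-normal (σ = 0.25) clipped to
[0.5, 2]. Deeper technical artifacts (batch, GC, degradation) are out of
scope.

The log2-scale mean m_ij is the sum of the gene's baseline and the
planted effects:

* **Group effect (DEGs).** n_deg genes (default 50) get a log2 fold
  change of random sign, |log2FC| ~ U(2.5, 4), applied to the LT samples.
* **Co-expression modules.** Each planted module adds
  c_i · f_j, where f is the module's latent factor over samples and
  c_i = s_i λ / √(1 − λ²) scales the effect so that the gene–factor
  correlation is the loading λ (default 0.8) given the gene's
  delta-method log2-scale noise SD s_i = √(1/μ_i + α_i)/ln 2. The latent
  factors of all modules are drawn jointly and **orthonormalized
  in-sample** (QR of a centered Gaussian matrix): with only 19 samples,
  independently drawn factors can correlate up to ~0.7 by chance, which
  makes the planted partition genuinely unidentifiable; orthogonal
  factors define distinct modules, the same convention as planting
  distinct seed eigengenes in the standard WGCNA simulation framework.
  Real cohorts can of course contain correlated expression programs — the
  eigengene merge step exists precisely to fuse those — so module
  recovery results on synthetic data are an upper bound in that respect.
  One module's factor is tied to a continuous clinical trait
  (trait = ρ·factor + √(1−ρ²)·noise, ρ = 0.8 by default).
* **Individual perturbations.** Each LT sample receives n_private
  (default 30) genes shifted by ±δ·s_i on the log2 scale (δ = 4 reference
  SDs by default — the generator's benchmarking choice, not a literature
  estimate), and n_shared genes (default 10) are each planted in k
  (default 5) of the 9 LT samples. With this scaling a perturbed gene is
  expected to score z ≈ δ in a perturbation profile.
* All planted effects are placed on genes whose baseline mean is ≥ 20
  counts: an effect planted on a gene the assay cannot measure (a few
  counts, dominated by discreteness) is not a meaningful benchmark of any
  downstream method.

Survival times are independent of expression given the group label
(ST ~ U(3, 12) months, all deceased; LT ~ 36 + Exp(12) months, event
probability 0.5) unless planted prognostic genes are enabled, in which
case a proportional-hazards draw links them to survival within each
group's window.

The interaction network is a preferential-attachment (Barabási–Albert)
graph — default 2,000 nodes at m = 10, i.e. ~20,000 edges, a ~1:10
scale-down of the ~373,000-link, ~19,000-gene physical interactomes used
in practice — with a planted disease neighborhood grown by BFS (hence
connected), densified internally, and containing the seed genes. Two
dedicated benchmark generators exist for the prioritization methods: a
hub-decoy variant (planted neighborhood drawn from low-degree nodes, seed
genes additionally wired to the top hubs, so raw diffusion is deliberately
confounded) and a directed two-layer variant with one node wired between
every sample's perturbed genes and the group-level gene set.

Everything derives from one integer seed through `numpy.random
.SeedSequence` children; identical seeds give byte-identical outputs.

## Group-level statistics

**Normalization** is DESeq-style median-of-ratios: s_j = median over
all-positive genes of x_ij / geometric-mean_i; log-normalized expression
is log2(x_ij/s_j + 1).

**Differential expression** is a self-contained NB Wald test, not a
re-implementation of any published tool: group means of normalized
counts, a pooled method-of-moments dispersion α̂ = (s² − m̄)/m̄² floored at
1e-8, log2FC = log2((m_LT + 1)/(m_ST + 1)) (the pseudocount avoids
infinities on zero means), and SE via the delta method from
Var(mean) = (m + α̂ m²)/n. The Wald statistic is referred to a
**t distribution with n − 2 df** rather than the normal: with ~10
samples per group the plug-in variance is noisy and the normal reference
is anti-conservative. There is no dispersion or fold-change shrinkage;
the validation target is calibration and recovery on synthetic cohorts
(null type-I rate 0.049 ± 0.004 in a 40-replicate pre-registered
simulation), not agreement with any specific tool's output. Direction
calls use |log2FC| ≥ 2 and unadjusted p < 0.05 by default, and the screen
deliberately applies no multiple-testing correction.

**Survival screening** is a per-gene two-group log-rank test (1 df,
hypergeometric variance) after a median split of expression, ties to the
low group — which reproduces a deterministic 10/9 split on 19 distinct
values. A tertile option (high vs low third, middle dropped) is
available; the two-group median split is the default because the
three-group wording in parts of the literature is internally
inconsistent. The Kaplan–Meier estimator is the standard product-limit
form. All samples are pooled for the screen by default.

**Centroid classification** correlates each sample with reference
subtype centroids (Pearson, on the gene intersection, minimum 10 genes)
and assigns the argmax, ties broken by subtype name order.

## Perturbation profiles (PEEPs)

z_ij = (x_ij − μ̂_i)/σ̂_i against the reference group, with σ̂ using the
n − 1 denominator; input is log2-normalized expression, where SD-unit
thresholds are well behaved. |z| ≥ 2 flags a perturbation; positive z is
up-regulation. Genes with zero reference SD get z = 0 and are listed in a
QC field instead of producing infinities. With n_ref = 10 the null call
rate is not 2Φ(−2) ≈ 0.0455 but the √(1 + 1/n) t_{n−1} tail,
2·P(t₉ ≥ 2/√1.1) ≈ 0.089 — reference-estimation inflation that a 200-
replicate simulation bounds at [0.070, 0.108] per cohort; the calibration
test asserts that band, and the permutation-null p-values are uniform
(KS p ≈ 0.98 across 20 cohorts).

The permutation null reshuffles the ST/LT labels B = 500 times preserving
group sizes, recomputes the permuted-target perturbed-gene counts, and
assigns each observed LT sample the add-one empirical p
(1 + #{null ≥ obs})/(B·n_target + 1), which cannot be zero. The summary is
reported but does not gate any downstream step. PEEPs are computed for LT
against ST by default; the symmetric direction is a flag.

## Co-expression modules

Adjacency a_ij = |cor|^β (unsigned default; signed ((1+cor)/2)^β via
config). β is the smallest candidate in 1..20 whose scale-free fit
reaches R² = 0.85, else the argmax with a warning. The fit regresses
log10 empirical density on log10 mean connectivity over 10
equal-occupancy bins — density, not raw bin frequency, because
equal-occupancy bins hold equal counts by construction — and the R² is
negated when the slope is positive. TOM follows the standard form
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij), unit
diagonal. Genes constant across samples are removed before this stage.

Module detection is average-linkage hierarchical clustering of
dissTOM = 1 − TOM with a **static cut at a quantile of the merge
heights** (a deliberate simplification of dynamic tree cutting; a
deepSplit-style refinement is out of scope). The default quantile is
0.90: merges between unrelated genes concentrate in a narrow band just
below the maximum height, so cutting at the very top (e.g. the 0.99
quantile) provably fuses distinct modules, while any cut in the 0.8–0.95
quantile range recovers planted modules robustly (ARI ≥ 0.93 across
seeds). Clusters below min_module_size (30) are labeled 0 (unassigned);
modules are numbered by decreasing size.

Eigengenes are the first principal component of the module's standardized
expression, standardized to mean 0/SD 1 and sign-oriented to correlate
non-negatively with the module's average expression. Modules whose
eigengene dissimilarity 1 − cor falls below 0.25 are merged, eigengenes
recomputed, and the step iterated to a fixed point — so merging is
idempotent by construction. Module–trait association uses Pearson for
continuous and Spearman for categorical/ordinal traits on complete cases,
p from the t approximation with n − 2 df (an exact-permutation option
would be preferable below n ≈ 10 but is unnecessary at n = 19), and
Bonferroni correction jointly across all module × trait pairs. Module
significance is the mean absolute gene–trait correlation over members.
Correlation effect sizes are reported as r, never r² (a squared quantity
cannot be negative, so signed "r²" values in parts of the literature are
r mislabeled).

## Network prioritization

The random walk with restart iterates p ← (1 − r)·Wᵀp + r·p₀ with W the
out-degree-normalized transition matrix, dangling-node mass redistributed
to the restart distribution (guaranteeing a proper stationary
distribution), restart probability r = 0.4, and L1 tolerance 1e-10. The
result matches the direct linear solve to 1e-8 on random graphs.

The **degree-aware ranking** divides the seeded-walk score by the score
under uniform restart on all nodes — the latter tracks what degree alone
earns every node — and ranks the ratio. This is a degree-corrected
variant in the spirit of published hybrid statistics whose exact form is
not reproduced here; the validation target is the hub-decoy benchmark
(the correction must beat raw diffusion in top-1% precision), not output
equality with any tool. Seeds absent from the network are dropped with a
log entry.

The **two-layer ranking** computes one reverse diffusion from the
group-level differential genes (edge-reversed network) and, per patient,
a forward diffusion from that patient's PEEP genes; the fields are
combined elementwise (product by default, sum via config), each patient's
nodes are ranked, and ranks are aggregated across patients (median by
default; mean/sum via config). Undirected networks are symmetrized with a
warning. Genes absent from the network are reported separately with rank
N + 1, never silently dropped.

The disease module is the top ceil(0.01·N) of a ranking, boundary ties
all included (so 19,117 genes yield 192, more if tied). The candidate
universe for the cut is an explicit parameter, since reported top-1%
counts in the literature depend on an unstated universe.

## Biclustering and enrichment

`bimax` enumerates **all** inclusion-maximal all-ones submatrices of the
binary call matrix by a deterministic close-by-one recursion over columns
(each closed column set is generated exactly once via a canonicity test);
branches whose row support falls below min_rows are pruned, which is safe
because row support only shrinks along a branch. Output is filtered by
min_rows/min_cols (2/2) and sorted by area. At the pipeline's scale (nine
LT columns) the enumeration is exact and fast; the original divide-and-
conquer heuristic ordering is unnecessary at desk scale. In the pipeline,
rows are restricted to genes perturbed in ≥ 2 samples before
biclustering. Superclusters cut an average-linkage tree of pairwise
Jaccard distances between bicluster gene sets at similarity 0.5.

Enrichment is the exact hypergeometric upper tail (one-sided default;
two-sided by doubling the smaller tail, since the exact two-sided
convention of common enrichment tools is unspecified), with BH or
Bonferroni adjustment. Curated pathway/domain databases are data supplied
as GMT files, not code.

## Evidence integration

The evidence matrix lines up, per gene: DEG status and direction,
membership of a module with Bonferroni-significant trait association,
PEEP sharing count, and presence in each top-1% list; plus all pairwise
Venn counts and the 8-cell partition of (DEG, clinical module, PEEP). No
combined meta-score is defined — the streams answer different questions —
but an optional sum-of-flags ordering is available and labeled heuristic.
Sharing-count report cuts (≥1 default; ≥2, ≥3, 7-of-9) are options.

## Problem sizes and what passing means

The default end-to-end run uses 2,000 genes, 19 samples, a 2,000-node /
~20,000-edge network and 500 permutations (seconds on one CPU); the
recovery batteries use 500–1,000 genes so that many seeds can be run. A
passing suite shows the pipeline recovers the structures the generator
plants under realistic count noise at the study's sample sizes. It does
not show robustness to batch effects, tumor purity, correlated expression
programs, annotation mismatches, or any other feature of real cohorts the
generator does not model; headline results from any specific cohort
depend on that cohort and are not reproduced here.

## Known limitations

* The NB test uses plug-in method-of-moments dispersions; for very low
  counts or n < 4 per group its calibration degrades.
* The static quantile tree cut needs a sensible min_module_size and can
  fragment modules whose size is near that minimum; the eigengene merge
  heals fragments only above the size cutoff.
* Bimax is exponential in the number of columns in the worst case; it is
  intended for cohort-sized (tens of columns) call matrices.
* Exact-string gene identifiers: no symbol/alias harmonization is
  attempted across expression, network, and gene sets.
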