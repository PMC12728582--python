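# Methods

This note documents the models, conventions, and numerical choices behind
`rhizofun`, and what the synthetic tests do and do not establish about real
data.

## Multifunctionality indices

Every function column is standardised across samples with
`STD = (X − X_min)/(X_max − X_min)`, so each column attains both 0 and 1. A
constant column makes the denominator zero; the default is to abort (a
silent drop would invisibly change the AMI denominator), with
`on_degenerate="drop"` available to remove it with a warning.

* **AMI** is the per-sample mean of the standardised columns. Group AMIs
  average within element-cycling groups; the default membership —
  C = {SOC, MBC, SSC}, N = {TN, AN, NN, MBN, Ure}, P = {TP, AP, MBP, ALP} —
  assigns each function to the element it measures or cycles and is fully
  overridable, since different panels group differently.
* **PMI** takes the first five PCoA axes of Bray–Curtis distances between
  *standardised* profiles. Raw measurements are in incommensurate units
  (g/kg vs enzyme activities), which would make Bray–Curtis meaningless, so
  standardised profiles are the only defensible input. PCoA axis signs are
  arbitrary; each axis is flipped, if needed, so its correlation with AMI is
  non-negative (ties broken by orienting the largest-magnitude coordinate
  positive), which makes PMI.1 increase with overall multifunctionality.
* Bray–Curtis is non-Euclidean, so the PCoA Gram matrix can have negative
  eigenvalues. They are dropped and logged; no Lingoes/Cailliez correction
  is applied, because the retained leading axes are unaffected and the
  correction would change eigenvalue interpretation.

## Diversity and community structure

Rarefaction is a single seeded multivariate-hypergeometric draw per sample
(subsampling without replacement), not an average over draws — one leveled
table is the common convention and the average is available by looping
seeds. Faith's PD is rooted: the branch-length sum of the minimal subtree
spanning the present tips and the root. The combined microbial diversity
index averages the standardised bacterial and fungal *richness* values only;
PD is reported alongside but does not enter the index. Genus abundances pool
ASVs whose lineage reaches genus and report truncated lineages as
`unclassified_<deepest rank>`.

PERMANOVA is the standard one-way distance partition: with total squared
distance `SS_T` and within-group `SS_W`,
`F = (SS_A/(a−1))/(SS_W/(n−a))`, labels permuted whole,
`p = (#{F* ≥ F} + 1)/(n_perm + 1)`. Only the single-factor design is
implemented. One-way ANOVA with LSD post-hoc is provided as a thin routine
utility.

## Co-occurrence networks

The recipe: keep core ASVs (mean per-sample relative abundance > 0.5%,
computed jointly across all samples in the network's scope), Spearman-test
all unordered pairs (cross-kingdom pairs included in the combined network),
BH-adjust within the network, keep edges with |r| > 0.70 and adjusted
p < 0.01. Although the filter is often phrased as "positive edges", the sign
is retained and positive edges are counted separately, because positive-edge
counts are reported as their own topology metric; a `positive_only` flag
gives the stricter reading.

Two scopes are supported. A *pooled* network treats all samples as one
community. *Per-treatment* networks estimate co-occurrence within each
treatment's samples. Only the latter can express treatment-dependent
connectivity: in the generative model the marginal abundance distribution of
every ASV is identical across treatments (only the *joint* block structure
differs), so pooled correlation estimates average the per-treatment block
correlations and presence/absence carries no treatment signal. Treatment
contrasts therefore use per-treatment networks; the pooled scope remains the
default for single-community analyses.

**Edge-gate power at desk scale.** With n samples, the Spearman t
approximation gives p ≈ 1e-4 only for |r| ≳ 0.9 when n ≈ 10 — and that is
the raw p a BH-adjusted 0.01 gate demands among thousands of pairs. A block
correlation of 0.5 (Gaussian-rank correlation ≈ 0.48) can then never
produce edges, making moderate-connectivity conditions invisible. The
pipeline-level default for desk-scale studies is therefore the raw-p gate
(|r| > 0.70 and p < 0.01 unadjusted, `p_adjust="none"`), chosen from this
power calculation; `build_network` itself defaults to the BH gate, and both
are configurable. With ~2,000 pairs per network and a per-pair false-edge
rate of ~1%, the raw gate admits a bounded number of spurious edges that is
constant across treatments and does not bias treatment contrasts.

Topology conventions (fixed so results are testable): mean local clustering
counts degree<2 nodes as 0; average path length on a disconnected graph
averages over connected pairs only (keeping the metric finite, as common
network tools do); betweenness is normalised by (n−1)(n−2)/2 and averaged
over nodes so it is comparable across subnetworks of different sizes; an
empty graph scores zeros and is flagged.

The complexity score z-scores the topology metrics across subnetworks
(constant metrics dropped with a warning), runs PCoA on Euclidean distances
(equivalent to PCA; Bray–Curtis is ill-suited to signed z-scores), and takes
axis 1 oriented to correlate positively with average degree. If every
subnetwork is identical (typically all empty), the ordination is degenerate
and the pipeline reports zero scores with a warning rather than failing.

## Linking statistics

All correlation p-values use the two-sided t approximation with n−2 df;
|r| = 1 maps to the smallest positive double rather than zero. Mantel
correlates the vectorised upper triangles and permutes rows and columns of
the second matrix jointly; its p, like PERMANOVA's, has minimum
1/(n_perm+1) and can never be 0. Random-forest importance is out-of-bag
permutation %IncMSE (mean over trees of the relative OOB-MSE increase when
one predictor is permuted), hand-rolled over scikit-learn trees because
scikit-learn exposes no OOB permutation importance; 500 trees by default,
fully seeded.

The path model is piecewise: each endogenous variable is OLS-regressed on
its parents after z-scoring (coefficients are standardised estimates), and
model fit is Fisher's C over the d-separation basis — every non-adjacent
ordered pair tested as the partial regression p of the earlier variable in
the later variable's equation given the union of both parent sets. C = −2 Σ
ln pᵢ ~ χ²(2k) under correct structure. Effects decompose by path tracing:
direct = edge coefficient, indirect = sum over directed paths of coefficient
products, total = direct + indirect. Collinear parent sets (design condition
number > 1e8) are rejected. How "community structure" enters the linking
layer is a free choice; the default is ordination axis 1 of genus-level
Bray–Curtis per kingdom, configurable.

## Synthetic generator

The generator emulates the study design the pipeline targets: treatments ×
replicates (default 3 × 3, labels CK/SBSH/SBSF), two kingdoms (default 150
bacterial and 60 fungal ASVs at library sizes 20,000 and 8,000), guild
blocks spanning both kingdoms (round-robin assignment, default 5 blocks),
per-treatment within-block latent correlation ρ_t (default 0.2/0.5/0.8),
and twelve function variables. Per sample, ASV log-abundances are
`a_i + dev·(√ρ_t f_b + √(1−ρ_t) e_i)` with `a_i ~ N(0,1)` baselines and unit
normal factors/noise, so within-block correlation is exactly ρ_t; counts are
multinomial at the library size from the softmaxed log-abundances
(Dirichlet overdispersion optional; plain multinomial is the default so the
expected relative abundance has an exact oracle). Latent connectivity is
`c_s = ρ_t + N(0, 0.02)` — the jitter gives within-treatment variation so
sample-level regressions are possible — and each function is
`μ_j + β_c c_s σ_j + N(0, noise·σ_j)` with β_c = 2 and noise 0.2 by default.
The per-function scales μ_j, σ_j are order-of-magnitude values plausible for
black-soil topsoil (e.g. SOC ≈ 19.2 g/kg); they are cosmetic and never
fitted.

What the generator does **not** emulate: sequencing error and chimeras,
realistic taxonomies, zero-inflation beyond multinomial sampling,
phylogenetic signal in abundances, or temporal/spatial autocorrelation.
Passing tests therefore establish that the statistical machinery recovers
known structure of this form at desk scale — not that any particular field
result is correct, nor that the edge filter has power at n = 3 replicates
(it largely does not; see the power note above).

## Problem sizes and tolerances

Oracle comparisons run on instances small enough for explicit enumeration
(≤ 10-node graphs, ≤ 15-sample matrices) at 1e-10–1e-12 tolerances.
Calibration checks use 500–1000 simulated nulls with 199 permutations each
and accept rejection rates in [0.03, 0.07] at α = 0.05 (binomial
tolerance). End-to-end recovery uses 3 × 10-replicate designs over 50–100
seeds — large enough for stable Monte-Carlo rates while keeping the full
suite under a few minutes on one core. Seeds are fixed throughout; every
stochastic routine takes an explicit seed and is reproducible.
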