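# Methods

## Model and procedure

`phenonet` analyses a subjects × variables table in which each variable is
declared numerical or categorical. The pipeline is a fixed sequence:

1. **Pairwise effect sizes.** Every unordered pair is tested on its
   pairwise-complete subjects. The statistic depends on the pair's type
   composition (Spearman/t, χ²/Cramér, Kruskal–Wallis/Dunn); in all three
   cases the effect size is bounded in [0, 1] and is treated as a common
   scale R². Nonparametric tests are used throughout so that no
   distributional assumptions are made about the marginals.
2. **Thresholding.** A pair is significant when p ≤ α/[N(N−1)/2]. The
   Bonferroni divisor is the count of *all* unordered pairs, not only the
   testable ones — a deliberate, conservative choice that makes the
   threshold independent of the missingness pattern.
3. **Network, giant component, MST.** Significant pairs with R² > 0 form
   the effect-size network; each edge carries R² and the distance
   d = (1 − R²)/R². Only the largest connected component is analysed
   further; the minimum spanning tree under d (Kruskal) retains the
   strongest associations that still connect every variable.
4. **Clustering.** Louvain with weight R² (closeness, not distance),
   resolution 1, run on both the giant component and the MST.
5. **Induced cluster network and centrality.** Contracting each MST
   cluster to a node yields the cluster tree; normalized betweenness
   centrality under d-weighted shortest paths classifies clusters as
   central (BC ≥ 0.5), noncentral, or peripheral (BC = 0).
6. **Correspondence.** MST clusters are matched to full-network clusters
   by minimum Jaccard distance; the subset similarity index j = J/J_max
   and AMI quantify how far the MST partition refines the full one.

## Statistical details

**Spearman.** Average ranks; r is the Pearson correlation of ranks; the
two-sided p-value uses t = r√((n−2)/(1−r²)) on n−2 df, with p = 0 at
|r| = 1. Requires n ≥ 3 and non-constant inputs.

**Corrected Cramér.** With an r × c table over observed levels, Pearson
χ² without continuity correction, φ² = χ²/n, the Bergsma bias correction
φ̃² = max(0, φ² − (r−1)(c−1)/(n−1)) with shrunk dimensions
r̃ = r − (r−1)²/(n−1), c̃ = c − (c−1)²/(n−1), and effect
φ̃²/min(r̃−1, c̃−1) clipped to [0, 1]. For a perfect 2×2 association the
correction cancels exactly and the effect is 1. The p-value is from χ²
with (r−1)(c−1) df; the correction affects only the effect size.

**Kruskal–Wallis / Dunn.** The p-value is from tie-corrected H on k−1 df.
Dunn's z for groups i, j uses the tie-corrected pooled variance
(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j); the effect is
Z²max/N with Z_max the largest **absolute** z over group pairs — absolute
because an effect size must be sign-free. Dunn p-values are not used for
edge inclusion; the Kruskal–Wallis p decides significance.

**Minimum sample size.** The Fisher-z closed form
n = ⌈((z_{1−α/2} + z_power)/atanh(ρ))² + 3⌉ gives 783 for ρ = 0.1,
80% power, α = 0.05. The pipeline's default cutoff is nevertheless 790,
the conventional figure for this calculation in the applied literature;
both the formula and the default are exposed and configurable.

## Numerical and design choices

- **p ≤ α_eff (inclusive)** counts as significant; a pair exactly at the
  threshold gains an edge.
- **R² = 0 edges are dropped** rather than given infinite distance,
  keeping all weights finite.
- **Giant-component ties** (equal sizes) go to the component containing
  the lexicographically smallest variable name. **Kruskal ties** are
  broken by canonical edge order (var_a, var_b): edges are inserted in
  sorted name order and the algorithm's stable sort preserves it, so the
  MST is deterministic even with duplicated distances.
- **Louvain** is seeded; cluster ids are renumbered 1..k by decreasing
  size (ties by smallest member name) so outputs are reproducible and
  comparable across runs. The reported Q is recomputed independently
  from the partition.
- **Contraction fallback:** if a Louvain cluster is disconnected within
  the MST, two clusters can be linked by several parent edges; the
  minimum distance is kept and a warning logged, since a clean tree
  contraction has exactly one linking edge.
- **Centrality boundary:** BC exactly 0.5 is central. BC is normalized by
  (n−1)(n−2)/2 pairs; induced networks with fewer than 3 clusters have
  all-zero BC.
- **Match ties** (two full clusters at equal Jaccard distance) are broken
  by larger intersection, then smaller cluster id.
- **AMI normalization** is the arithmetic mean of entropies, configurable
  (`average_method`), and recorded in the correspondence summary, because
  published AMI values are ambiguous about this variant.
- **Missing markers** on disk are the empty string and `NA`,
  configurable in `read_cohort`.

## The synthetic generator

The generator emulates the one feature of phenome tables that the
pipeline is designed to exploit — groups of variables driven by shared
latent causes, weakly chained into a backbone — and nothing else.
A latent chain f_b = γ·f_{b−1} + √(1−γ²)·ε_b (standard-normal ε) keeps
every factor marginally N(0, 1) with corr(f_b, f_{b+1}) = γ; variable i
in block b is x_i = √ρ_b·f_b + √(1−ρ_b)·e_i, giving within-block
correlation ρ_b and adjacent-block correlation ρ·γ. The first
round(categorical_fraction · block size) variables of each block are
discretized into n_levels equiprobable bins by ordinal rank (ties broken
by position), which keeps level frequencies balanced at any n. Cells are
then blanked missing-completely-at-random. The RNG stream is consumed in
a fixed order (latent factors → variable noise → missing mask), so output
is bit-identical for a given spec and seed.

Defaults: 1,000 subjects, 8 blocks × 10 variables, ρ = 0.6, γ = 0.3,
30% categorical, 3 levels, 5% missing. Three levels is the smallest
categorical cardinality that retains enough of the latent association
after binning to behave like typical questionnaire items; two-level
binning would make the categorical arm of the pipeline unrealistically
lossy.

What the generator does **not** model: realistic clinical marginals
(skewed lab values, rare diagnoses), informative missingness (only MCAR
is provided, since typical cohort documentation does not specify a
mechanism), unequal block sizes by default, or variables loading on
several factors. Passing recovery tests on this model therefore shows the
pipeline recovers planted latent-block structure through mixed-type
discretization and MCAR missingness — not that it resolves the messier
overlap structure of a real phenome.

## Problem sizes used in validation

The test suite and the reproduction script run the pipeline at 80
variables × 1,000 subjects (3,160 pairs), a size chosen so a full
end-to-end run takes seconds while still containing all structural
regimes (mixed pair kinds, missingness, giant component, nontrivial
cluster counts). Oracle-agreement checks use exhaustive brute-force
references on small inputs: vectors of length ≤ 12 for the three effect
sizes (1,000 random cases, agreement to 1e-10), graphs of ≤ 7 nodes for
MST optimality against enumeration of all spanning trees, trees of ≤ 12
nodes for betweenness against the component-product closed form, and a
6-element universe for the Jaccard-distance triangle inequality.
Type-I-error calibration uses 500 null replicates per pair kind at
n = 800.

## Known limitations

- The χ² and Kruskal–Wallis p-values are asymptotic; at very small
  complete-n (near the degeneracy filters) they are approximate, which is
  one reason a large minimum-n default is sensible.
- Z²max/n is clipped at 1; values near the bound are not comparable in
  fine gradation to Spearman r² near 1.
- Louvain is a greedy heuristic: different seeds can yield different
  partitions on weakly structured networks. The seed is part of the
  configuration and recorded in every manifest.
- With huge n, many tiny effects become significant; the network then
  densifies and the MST/clustering contrast with the full network grows.
  Interpretation should lean on effect sizes, not p-values alone.
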