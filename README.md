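# phenonet

Cluster-network phenotyping for mixed-type cohort tables.

Epidemiological cohorts measure hundreds to thousands of variables per
subject — lab values, physical measurements, questionnaire items — some
numerical, some categorical, with plenty of missing cells. `phenonet`
turns such a subject-by-variable table into an **effect-size network**:
every variable pair gets an association strength R² ∈ [0, 1] chosen by the
pair's type composition, significant pairs become weighted edges, and
graph analysis of the result reveals how phenotypes cluster and which
clusters sit at the centre of the phenome.

## Method

**Pairwise effect sizes.** For each unordered pair, subjects missing
either value are dropped (pairwise-complete deletion), then:

| pair composition        | significance test                  | effect size R² |
|-------------------------|------------------------------------|----------------|
| numerical–numerical     | Student's *t* on Spearman's *r*    | Spearman *r*²  |
| categorical–categorical | Pearson χ² on the contingency table| bias-corrected Cramér φ̃² (Bergsma) |
| numerical–categorical   | Kruskal–Wallis ANOVA + Dunn post hoc | *Z*²max / *n* |

Pairs with fewer complete subjects than a power-derived minimum (default
790, from detecting a correlation of 0.1 at 80% power), or with a variable
constant after deletion, are flagged rather than tested. Significance uses
a Bonferroni threshold α_eff = α / [N(N−1)/2] over **all** unordered pairs.

**Network → MST → clusters.** Significant pairs form an undirected graph
whose edges carry R² and the effect-size distance *d* = (1 − R²)/R². The
giant component is extracted and its minimum spanning tree computed with
Kruskal's algorithm under *d*, so the strongest associations are kept
first. Louvain community detection (weight = R², resolution 1, seeded) is
applied to both the full giant component and the MST; contracting each MST
cluster to a node gives the induced cluster network, whose nodes are
classified by normalized betweenness centrality: **central** (BC ≥ 0.5),
**noncentral**, and **peripheral** (noncentral with BC = 0).

**Correspondence.** Each MST cluster is matched to the full-network
cluster at minimum Jaccard distance D_J = 1 − J, with
J(X,Y) = |X∩Y|/|X∪Y| and the subset similarity index
j = J / (min(|X|,|Y|)/max(|X|,|Y|)) measuring closeness to a
subset–superset relation. Adjusted mutual information (arithmetic-mean
normalization) summarizes global agreement between the two partitions.

**Synthetic cohorts.** Because real phenome tables are rarely shareable,
`phenonet.synthetic` generates mixed-type cohorts with planted structure:
a chain of latent factors f_b = γ·f_{b−1} + √(1−γ²)·ε_b couples B blocks,
variable i in block b is x_i = √ρ·f_b + √(1−ρ)·e_i, a fraction of each
block is discretized into equiprobable quantile bins, and cells go missing
completely at random. The block labels are the ground truth the pipeline
should recover.

## Worked example

```
phenonet run-all --synthetic --seed 1 --out demo/
```

generates the default planted cohort (1,000 subjects; 8 blocks × 10
variables; within-block correlation ρ = 0.6; backbone coupling γ = 0.3;
30% categorical with 3 levels; 5% missing) and runs every stage. The
manifest it prints ends with:

```
  "alpha_eff": 1.5822784810126583e-05,
  "ami_mst_vs_truth": 1.0,
  "giant_component_size": 80,
  "modularity_full": 0.7667292434035665,
  "modularity_mst": 0.861347052950535,
  "n_clusters_full": 8,
  "n_clusters_mst": 8,
  "n_significant_edges": 763,
```

Reading: of the 3,160 variable pairs, 763 survive the Bonferroni
threshold (α_eff ≈ 1.6×10⁻⁵); all 80 variables join the giant component;
Louvain finds exactly the 8 planted blocks on both the full network and
the MST (AMI = 1.0 against ground truth), and the MST partition is more
modular (0.86) than the full-network one (0.77) — the tree sharpens the
cluster structure, which is the point of the MST step. The output
directory holds the pair table (`pairs.tsv`), networks in GraphML/GEXF
(Gephi-ready) and TSV, cluster memberships, the induced cluster network
with betweenness classes, and the correspondence table.

The same stages are available individually (`simulate`, `pairs`,
`network`, `mst`, `cluster`, `correspond`), each re-runnable from
persisted intermediates, and as a Python API (`phenonet.run_pipeline`).

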