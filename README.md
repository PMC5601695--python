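# brcapath

Pathway-level analysis and classification of breast cancer expression
subtypes.

Clinically, breast cancer is stratified by receptor status into four
subtypes ordered by reported malignancy — luminal A (LA), luminal B (LB),
HER2-positive (HER2+) and triple-negative (TN).  `brcapath` implements, as
a tested and reusable pipeline, a systems-level analysis of such cohorts
for computational biologists working with bulk expression matrices:

1. **Subtype gene screen** — one-way ANOVA across the four subtypes
   (P < 0.05) followed, per gene and subtype, by pooled-variance Student's
   t-tests against each other subtype (all three P < 0.01).  Genes passing
   for one subtype are *associated* with it; genes unique to one subtype
   are *specific*; genes associated with all four are *core* genes.
2. **Co-expression networks** — per-subtype Pearson correlation matrices
   over chosen gene sets; edges where |r| > 0.5; degree, average shortest
   path length, closeness centrality and topological coefficient per node;
   threshold-stratified pair counts and core-vs-all log10-degree summaries.
3. **Hierarchical clustering** — average linkage on correlation distance,
   with per-subtype cluster purity as the quantitative readout.
4. **Gene-set enrichment** — one-sided Fisher exact test (hypergeometric
   upper tail) of any query set against a GMT collection.
5. **Pathway alteration score** — for pathway *P* and one sample, with
   genes split into upregulated (i = 1…m, G > μ) and downregulated
   (j = 1…n, G < μ) relative to the gene's mean μ over the LA reference:

   ```
   score(P) = ln [ Σᵢ (Gᵢ/μᵢ)²  /  Σⱼ (Gⱼ/μⱼ)² ]
   ```

   Higher scores mean more positive pathway variation relative to the LA
   state; LA samples themselves fluctuate around zero.
6. **Functional trends** — samples ordered LA→LB→HER2+→TN, scores
   integrated over sliding windows (20 samples, step 10), window medians
   smoothed by LOESS.
7. **SVM classification** — RBF kernel, C = 1, γ = 1/n_features,
   stratified 5-fold cross-validation; a four-class model plus three
   pairwise models (LA/LB, LA/TN, LB/TN) whose features are the pathways
   enriched for either subtype's specific genes; confusion matrix,
   precision/recall/F1 and cross-validated ROC/AUC.

Because cohorts of this design cannot be shipped, the package includes a
first-class synthetic cohort generator (`brcapath.synthetic`) that plants
subtype-specific genes, a core-gene malignancy gradient, subtype-degrading
co-expression and pathway enrichment structure — so every stage can be
validated against known ground truth.

## Worked example

Generate the default synthetic cohort (160 samples: 60 LA / 40 LB /
20 HER2+ / 40 TN, 2000 genes, 30 core genes, 4×50 specific genes) and run
the whole chain:

```sh
brcapath synth --seed 1 --out-dir cohort
# wrote cohort (2000 genes x 160 samples) to cohort

brcapath pipeline --expr cohort/expression.tsv --labels cohort/labels.tsv \
    --gmt cohort/pathways.gmt --out-dir out --seed 1
# 16 artifacts written to out
```

`out/summary.json` then contains, among other quantities:

* `screen` — 80/80/81/80 associated genes per subtype; Venn regions
  `1000/0100/0010/0001` = 50/50/51/50 (the planted specific genes) and
  `1111` = 30 core genes (the planted core set).
* `coexpression` — core-gene pairs at |r| ≥ 0.5 of 435 (LA), 432 (LB),
  163 (HER2+) and 21 (TN): co-expression degrades along the malignancy
  order.  In every network the core genes' mean log10 degree exceeds the
  network average (e.g. 1.02 vs 0.56 in HER2+), marking them as hubs.
* `cluster_purity` — at k = 4 the 30 core genes cluster TN with purity
  1.00, matching the full 211-gene union (LB 0.95 vs 1.00).
* `enrichment` — exactly the six planted core pathways at P < 0.05.
* `classify` — four-class weighted recall 0.92; pairwise AUC 1.0 for
  LA/LB, LA/TN and LB/TN on this planted-signal cohort.

All library functionality is importable directly (`brcapath.screen.screen`,
`brcapath.coexpression.topology_summary`, `brcapath.pathway_score.score_matrix`,
…); the CLI is a thin wrapper.

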