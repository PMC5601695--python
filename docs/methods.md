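# Methods

This note records the models, conventions and design choices behind
`brcapath`, in the order the pipeline runs them, together with what the
synthetic cohorts do and do not establish about real data.

## Data model and normalization

The substrate is a genes × samples matrix with one subtype label per
sample, the labels totally ordered by reported malignancy
LA < LB < HER2+ < TN.  Values must be finite; NaNs are rejected at load.
Normalization is per-gene z-scoring across **all** samples with sample
standard deviation (ddof = 1).  The divisor convention is immaterial
scientifically but is fixed for reproducibility; z-scoring is idempotent
to 1e-9.  Zero-variance genes cannot be scaled and are set to all-zeros
and flagged rather than dropped, so gene universes stay stable
downstream; such genes can never pass the ANOVA screen.  Gene identifiers
are opaque, case-sensitive strings — no symbol/alias mapping is
attempted.

## Two-stage subtype gene screen

Stage 1 is a classical one-way fixed-effects ANOVA per gene over the four
subtype groups, thresholded at raw P < 0.05 (strict).  Stage 2, applied
only to ANOVA-significant genes, tests each subtype M against each of the
other three with the two-sided pooled-variance Student's t-test at raw
P < 0.01 (strict).  No multiple-testing correction is applied at either
stage by default — the screen is a deliberately permissive filter whose
joint requirement (four tests per subtype call) provides the stringency —
but Benjamini–Hochberg is available behind a flag, as is Welch's t.
Degenerate cases are made total rather than NaN: an all-constant gene
gets p = 1; a zero-pooled-variance contrast gets p = 1 when the means are
equal and p = 0 when they differ.  Genes may be associated with several
subtypes; specific genes are those associated with exactly one, and core
genes with all four.  Venn-region accounting over the four associated
sets is assertable: regions sum to the union, unique regions equal the
specific sets, the 1111 region equals the core set.

## Co-expression networks

Correlations are Pearson, computed within one subtype's samples
(correlation is invariant to the global per-gene z-scoring).  Genes with
zero within-stratum variance get r = 0 against everything and are
flagged.  Two threshold conventions coexist in the field's reporting and
both are exposed: network edges use the strict rule |r| > t (default
t = 0.5), while tabulated pair counts use the inclusive |r| ≥ t.

Per-node statistics, for node n with degree k_n:

* **degree** — incident edge count;
* **average shortest path length** — mean unweighted geodesic from n to
  the other nodes of its connected component (0, flagged, for isolated
  nodes);
* **closeness centrality** — (number of reachable nodes) / (sum of
  geodesics to them), the within-component form compatible with common
  network-analysis GUIs; 0 for isolated nodes;
* **topological coefficient** — TC(n) = mean over all nodes m that share
  at least one neighbor with n of J(n,m)/k_n, where J(n,m) is the number
  of shared neighbors plus one if n and m are adjacent; 0 when no such m
  exists.  Nodes with a single neighbor are *not* excluded: a leaf of a
  star has TC = 1.  All four statistics are verified against a
  brute-force BFS / set-intersection oracle on random graphs.

Core-vs-all centrality summaries use log10(degree) over nodes with
degree ≥ 1 only (the logarithm of zero is undefined; excluded isolated
nodes are counted and reported).  The SD is the sample SD (ddof = 1).

## Hierarchical clustering and purity

Samples are agglomerated over a chosen gene subset (and genes over
samples) with average linkage on correlation distance 1 − r by default —
the standard choice for expression heat maps; complete/ward linkage and
Euclidean distance are configurable.  A zero-variance item has no defined
correlation and is assigned the maximal distance 2, flagged.  Because a
dendrogram figure is not a quantitative object, cluster quality is
summarized as **purity**: for each subtype at a cut into k clusters, the
largest fraction of that subtype's samples captured by a single cluster.
Purity at k = 1 equals 1 by construction and is non-decreasing in k.  The
scientific claim under test is that the small core set clusters samples
about as well as the much larger union of associated genes.

## Enrichment

Over-representation of a query set in each pathway of a GMT collection is
the one-sided Fisher exact test, i.e. the hypergeometric upper tail
P(X ≥ count) with the measured-gene universe as population.  The universe
is all genes of the expression matrix, not the GMT union; gene sets are
restricted to the universe at load and emptied sets dropped with a
warning.  P-values are reported raw (BH optional).  The reported Count is
the query ∩ pathway overlap.

## Pathway alteration score

For pathway P, sample expression G and per-gene reference mean μ (the
arithmetic mean over LA samples — the least malignant subtype serves as
the control), genes are partitioned per sample into upregulated
(G > μ, i = 1…m) and downregulated (G < μ, j = 1…n), ties excluded, and

    score(P) = ln( Σ_i (G_i/μ_i)²  /  Σ_j (G_j/μ_j)² ),

computed as ln Σ_up − ln Σ_down over a deterministic (sorted) gene order,
which makes the swap-the-groups antisymmetry exact in floating point.
Guards, all logged: |μ| < ε is clamped to sign(μ)·ε (sign of exact zero
taken as +); each |G/μ| is capped at 1/ε; an empty group's sum is
replaced by ε so the score stays finite and signed toward the non-empty
side; a pathway with no scoreable gene scores 0.  Default ε = 1e-6.

**Scale choice.**  The score can be computed on the raw input values or
on the row-z-scored matrix; the package pipeline defaults to the raw
scale.  The reason is the reference mean: after global z-scoring, μ is
near zero for every gene that is not strongly differential, the clamp
engages, and the capped ratios of uninformative genes dominate the sums.
On the measurement scale (e.g. log-expression), μ is well away from zero
and the ratios are meaningful.  The raw scale has its own asymmetry worth
knowing: on a positive scale, downregulation drives ratios toward zero,
*shrinking* the down-group sum, so a pathway whose genes are uniformly
suppressed scores near zero rather than strongly negative — the score is
chiefly sensitive to upregulation there.  The z-score mode (with the
guards) recovers signed behavior for strongly differential gene sets at
the cost of reference instability.  Both modes are exposed
(`score_scale` in the pipeline config, `--no-zscore` on the CLI); the
package asserts its monotone-trend and classification properties on
upregulated planted pathways, where both readings agree.

## Sliding windows and LOESS

Samples are ordered by subtype rank, stably (input order within a
subtype; the data carry no within-subtype ordering covariate, and an
optional ordering by mean pathway score is available for smoother
curves).  Windows of 20 samples advance by 10 (adjacent windows overlap
by 10); when samples remain beyond the last full window a final short
window is appended and flagged, so no sample is silently dropped — for a
698-sample cohort this yields [0,20), [10,30), …, [670,690) plus the
remainder [680,698).  The per-window median (mean of the central pair for
even counts) is smoothed by LOESS — locally weighted linear regression
with tricube weights (statsmodels' lowess, one iteration, no robustness
reweighting), span 0.75 by default, evaluated at each window index.
Degree is fixed at 1; local linear fits reproduce exactly linear data to
numerical precision, which is asserted.

## Classification

Support vector machines with the fixed, non-tuned configuration: RBF
kernel, C = 1, and γ resolved to 1/n_features (the legacy "γ = 0"
sentinel; an RBF γ must be positive).  A once-configured polynomial
degree would be inert under an RBF kernel and is not exposed.  Folds are
stratified 5-fold with a seeded shuffle — stratification is the
defensible default when one class (HER2+) is very small — and every
sample is predicted exactly once by a model never trained on it.  The
four-class model uses scikit-learn's one-vs-one decomposition.  Pairwise
models (LA/LB, LA/TN, LB/TN; HER2+ is excluded for support) take as
features the pathways significantly enriched (P < 0.05) for either
subtype's specific gene set, scored against the full-cohort LA reference,
restricted to the pair's samples and column-standardized.  ROC curves
pool the cross-validated decision scores; AUC is the trapezoid over the
tie-aware threshold sweep and equals the normalized Mann–Whitney U
statistic to machine precision (asserted).  Weighted-average recall
equals overall accuracy identically (asserted).  Division-by-zero metric
cells (a class never predicted) are reported as 0 and flagged.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: four
subtype groups with unbalanced sizes (default 60/40/20/40 — a scaled-down
analogue of a 363/184/37/114 cohort), 2000 genes, and planted truth:

* background genes i.i.d. N(baseline, 1), identical across subtypes;
  the default baseline of 10 puts values on a log-expression-like
  positive scale so that reference ratios G/μ are well-conditioned;
* 50 specific genes per subtype, mean shifted by `effect_size` (default
  2.5) SD in that subtype only;
* 30 core genes with a linear mean gradient along subtype rank
  (0, e, 2e, 3e per rank step, sign alternating per gene) — differential
  between every pair of subtypes;
* equicorrelated residuals on the core genes (block 1) and on one
  30-gene background block (block 0), with target correlation per
  subtype defaulting to 0.8 / 0.65 / 0.5 / 0.3 along LA→LB→HER2+→TN,
  emulating the loss of co-expression toward the most malignant subtype.
  Cross-gene correlation leaves all per-gene statistics (ANOVA, t, power)
  untouched; the equicorrelation Cholesky construction guarantees
  positive semi-definiteness and rejects infeasible targets;
* gene sets of 20 members: six pathways drawing 80 % of members from
  single-direction core genes (direction alternating per pathway, so each
  planted pathway has a coherent gradient), two per subtype drawing 80 %
  from that subtype's specific genes (these give the pairwise classifiers
  their enriched features), and null pathways drawn uniformly.

Everything derives from one integer seed; identical seeds give bitwise
identical cohorts.

What the generator does **not** emulate: count-level noise
(library size, overdispersion), batch effects, gene-length or GC bias,
correlated null structure beyond the planted blocks, label noise, or
outcome/survival data.  Passing tests therefore demonstrate correctness
of the algorithms and calibration under a Gaussian generative model, not
performance on real cohorts; the near-perfect pairwise AUCs on planted
signal are a property of the strong, clean effects, and quantities from
any specific real study (gene counts, enrichment p-values, AUCs) are
cohort-dependent and not reproduced here.

A note on reference stability: because the core residuals are correlated,
the estimated LA reference means of a pathway's genes share their
sampling error, which leaves a cohort-level offset of up to roughly ±0.7
in LA alteration-score medians (against a planted TN response of about
+4).  "LA fluctuates near zero" therefore holds in the relative sense.

## Problem sizes and runtime

Defaults keep the full pipeline (2000 genes × 160 samples, all eight
stages) under a few seconds on one CPU, and the whole test suite —
including 20-seed null calibrations and 200-graph oracle sweeps — under
about half a minute.  Determinism is part of the contract: the pipeline
is a pure function of (inputs, config, seed), summary artifacts are
written with sorted keys and rounded floats, and rerunning at a fixed
seed is byte-identical.
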