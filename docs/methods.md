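# Methods

## Scope and model

`gdmclust` implements an unsupervised phenotyping pipeline for gestational
diabetes: partitioning a cohort on five routine clinical variables (maternal
age, pre-pregnancy BMI, OGTT glucose at 0/60/120 min), screening candidate
partitions with internal-validity gates, validating the surviving model by
twofold cross-validation and centroid transfer to held-out data, comparing
clinical outcomes across the resulting clusters, and assigning new patients
from a portable model artifact. The intended three-cluster phenotype
structure is: cluster 1 — obese with hyperglycaemia throughout the OGTT;
cluster 2 — elevated fasting glucose with intermediate BMI; cluster 3 —
normal BMI with post-load hyperglycaemia. Cluster numbering is enforced
canonically by sorting centroids on descending fasting glucose, then the
60-minute value (descending 60-minute glucose alone would misorder clusters
2 and 3, whose published profiles have OGTT60 of ~8.2 vs ~10.3 mmol/l while
fasting glucose separates them cleanly).

## Synthetic cohort generator

No public data accompany the underlying study, so the generator is the
package's test bed. It draws, per participant:

- a latent cluster from the calibrated mixing proportions
  (246/407/501 out of 1154 → 0.213/0.353/0.434);
- each input variable independently from a quantile-pinned marginal: a
  three-parameter (shifted) log-normal when the target (Q1, median, Q3) triple
  is right-skewed — shift `c = (q1·q3 − m²)/(q1 + q3 − 2m)`, which makes
  `(q1−c)(q3−c) = (m−c)²` exactly, so log-location and log-scale follow in
  closed form and all three quartiles are reproduced to machine precision — a
  plain normal with `sd = IQR/(2·z₀.₇₅)` for symmetric triples, and a flagged
  normal fallback for left-skewed triples (the required shift would sit above
  Q1, outside the log-normal's support);
- binary outcomes Bernoulli-conditional on the latent cluster, at the
  event/denominator rates of the published training-set profile, with
  independent per-outcome missingness matching the published available-case
  totals;
- rejection of any row violating the IADPSG rule (fasting ≥ 5.1 **or** 60 min
  ≥ 10 **or** 120 min ≥ 8.5 mmol/l) or the plausibility windows
  (age 12–60 y, BMI 12–70 kg/m², OGTT 2–25 mmol/l).

An optional Gaussian-copula hook accepts a within-cluster correlation matrix;
the default is independence (no within-cluster correlations are published).

**What the generator does not emulate.** The published per-cluster quartiles
describe clusters that were *produced by* k-means — i.e. cells of a Voronoi
partition of the real data, which are disjoint by construction. Independent
parametric marginals pinned to the same quartiles necessarily produce
overlapping components: the tails of adjacent clusters cross the implied
boundaries. Three measurable consequences, all computed by the test suite and
the acceptance script rather than assumed:

1. k-means on the synthetic cohort recovers the *generating* labels only at
   ARI ≈ 0.6 (n = 1154): boundary rows are re-partitioned. Agreement between
   two k-means partitions of the *same* mixture (the external-validation
   setting) remains high — transfer accuracy ≈ 0.90, ARI ≈ 0.70–0.80 —
   because both sides see the same geometry.
2. The cluster-validity indices see much weaker three-cluster structure than
   the real data did: the gap statistic selects k = 1, the ensemble majority
   is usually k = 2, and the full gated selection lands on k-means/k = 3 in
   only roughly half of seeded runs (when k = 3 is the ensemble's winner or
   runner-up). The individual gate behaviours do match the published
   selection narrative — k = 2 candidates typically fail the all-variables
   gate on age, and k-medoids/hierarchical candidates typically fail the
   bootstrap-Jaccard gate.
3. Rejection sampling shifts the post-load glucose of the cluster straddling
   the diagnostic thresholds (cluster 3) upward by up to ~3% at the median;
   the generator logs per-cluster acceptance rates.

Passing tests on this cohort therefore demonstrate the *pipeline machinery*
(calibration, gates, matching, transfer, statistics), not that real GDM data
would yield the same k or the same stability values.

## Parameters that matter

| Parameter | Default | Why |
|---|---|---|
| Jaccard stability gate | > 0.75 per cluster | published acceptance rule |
| Silhouette compactness gate | mean ≥ 0 per cluster | published acceptance rule |
| Variable-significance gate | omnibus p < 0.05, every input variable | published acceptance rule |
| k range | 1–8 (gap), 2–8 (others) | published profile has k = 3; 8 bounds the search |
| Gap reference sets B | 50 (≥ 10 enforced) | SE of the gap curve scales as 1/√B |
| Bootstrap replicates B | 100 (≥ 20 enforced) | Jaccard means stable to ~0.02 |
| k-means restarts | 50 (library default), 10 in pipeline runs | small instances reach the global optimum; see oracle tests |
| Train fraction | 0.70 | published split (1649 → 1154/495) |
| Assignment plausibility windows | age 12–60, BMI 12–70, OGTT 2–25 | refuse implausible records rather than extrapolate |

## Numerical and procedural choices

- **Standardisation**: z-scores with training mean/SD (ddof = 1). The source
  study does not state its scaling — this is the single most consequential
  undocumented step, because unscaled Euclidean distance would be dominated
  by the 60-minute glucose. Test-set and new-patient records always use the
  training scaler.
- **k-means**: k-means++ seeding, Lloyd iterations to label stability or
  centroid movement < 1e-6 (max 300), empty clusters reseeded to the farthest
  point, objective asserted non-increasing every iteration, best of the
  restarts by WCSS. All distance ties break to the lowest index.
- **PAM**: greedy BUILD then steepest-descent SWAP on the full dissimilarity
  matrix; total dissimilarity asserted non-increasing; exemplars stored
  separately from the member-mean assignment centroids (hierarchical models
  likewise transfer via member means).
- **Ward-D2** maps to scipy's `ward` on Euclidean pairwise distances and is
  refused for Manhattan.
- **Hartigan index**: smallest k with H(k) ≤ 10; when no k qualifies (common
  on both very strong and very weak structure at these n), the vote goes to
  the k immediately after the largest drop in H — the elbow reading.
- **Cluster matching**: Hungarian assignment on per-pair Jaccard overlaps
  derived from the contingency table, so the returned bijection dominates
  every other bijection in mean Jaccard. Bootstrap stability instead matches
  each original cluster to its best-overlap refit cluster independently
  (clusterwise stability semantics). Partitions with different k are an
  error, never silently reconciled.
- **Statistical routing**: Shapiro–Wilk (subsampled at 5000) on pooled
  residuals about the group medians routes continuous comparisons to
  ANOVA + Fisher's protected LSD (pooled-MSE pairwise t-tests) or
  Kruskal–Wallis + Dunn (tie-corrected). Binary omnibus uses Pearson χ²
  without continuity correction, switching to an exact conditional
  (hypergeometric-enumeration) test when any expected count is below 5.
  Post hoc stages are protected: no pairwise output unless the omnibus
  p < 0.05. p values are unadjusted by default (explorative stance);
  Bonferroni/Benjamini–Hochberg are available behind a flag.
- **Logistic outcome models**: the cluster-factor model is saturated in
  cluster, so the omnibus LRT uses the closed-form maximised likelihoods (and
  therefore survives separation); odds ratios and Wald CIs come from a
  grouped-data binomial GLM, with unbounded ORs flagged when a cluster has
  zero events or non-events.
- **Cross-validation "input similarity"** is operationalised as the scaler
  deltas plus matched-centroid L2 distances expressed in the original model's
  standardised space; the source describes this aspect only qualitatively.
- **Twofold outcome-significance consistency** = the partial-model and
  original-model omnibus p values fall on the same side of 0.05 on the fold's
  rows.

## Problem sizes used by the tests and the acceptance script

Selection and recovery run on ten cohorts of n = 1154 with gap B = 10,
bootstrap B = 30 and 5 restarts; external validation on five cohorts of
n = 1649 (70/30 split); stability-gate soundness on 20 replicates each of
three 10-SD-separated blobs (n = 150) and uniform noise (n = 150) with
B = 20; type-I error calibration on 3000–4000 null replicates per test
(three groups of 50, or of 200 for the χ²). These sizes give Monte-Carlo
standard errors comfortably below the asserted margins. External-validation
quantities are reported as means over the five replicate cohorts because a
single run's minimum per-cluster Jaccard fluctuates around the 0.75 gate.

## Known limitations

- The generator reproduces marginal quartiles and rates, not joint structure;
  see above for the consequences for k-selection and label recovery. A
  correlation matrix can be supplied via the copula hook, but none is
  published to calibrate against.
- The index ensemble implements seven named indices rather than the ~30 of
  the R NbClust battery; majority/runner-up semantics are preserved but the
  vote composition on any given dataset will differ.
- Density-based algorithms (DBSCAN/HDBSCAN) are out of scope, as are
  imputation of input variables (complete-case only), time-course modelling
  of gestation, and covariate-adjusted outcome models.
- The exact preprocessing exclusions, the original standardisation recipe and
  the original odds-ratio workflow are not publicly documented; the package's
  choices are stated above as its own defaults, not as reconstructions.
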