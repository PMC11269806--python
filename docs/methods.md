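# Methods

This note documents the models and procedures implemented in `serostrat`,
the assumptions behind them, the defaults that matter, and what the
synthetic data generator does and does not emulate.

## Matrix model and quality control

The central object is a protein × sample matrix of log2 intensities with
missing values allowed before QC. Rows are features (proteins), columns
are samples; all thresholds phrased "fraction of samples" therefore act
row-wise. `adjust_matrix` applies five steps in a fixed order:

1. **Missingness filter** — rows with a missing fraction strictly above
   0.25 are removed; a row at exactly 25% is kept.
2. **kNN imputation** (k = 10) — each missing entry becomes the mean of
   that sample's values among the k nearest rows, with row distance
   Euclidean over mutually observed samples (sklearn's `KNNImputer`,
   uniform weights). k must be below the row count.
3. **Winsorization** — per row, values outside the [5th, 95th] percentile
   interval are set to the percentile value. Percentiles interpolate
   linearly between order statistics; the definition is recorded in the
   QC report. Note a subtlety: with interpolated percentiles,
   winsorization is only an exact fixed point when the cut lands on an
   order statistic (e.g. n = 21 samples); in general re-application moves
   boundary values by at most the gap between the order statistics
   adjacent to the cut. The pipeline applies the step once.
4. **Zero-variance removal.**
5. **Low-variance removal** — the 5th percentile of row variances is
   computed *after* step 4 and rows strictly below it are dropped.

Winsorization deliberately precedes the variance screen, so the variance
cut acts on outlier-trimmed rows. No value is ever modified except by
imputation or winsorization, and row/column order is preserved.

## Consensus partitioning

Feature ranking uses ATC: a row's score is its mean absolute Pearson
correlation to all other rows. The top 50% of rows (configurable;
`top_frac`) feed the partitioner. The intuition is that proteins which
co-vary with many others carry subgroup structure, while uncorrelated
rows carry noise.

Sample partitioning is spherical k-means: rows are z-scored, sample
column vectors are normalized to unit length, and k-means runs with
cosine similarity (centroids re-normalized each iteration; 10 restarts;
the restart maximizing total cosine similarity wins; empty clusters are
revived with the worst-fit samples). Cosine geometry makes the
partition invariant to positive per-sample scaling, which suits
intensity data where per-sample scale is partly technical. Euclidean
distance is reserved for the protein-side clustering (below) — the two
geometries serve the two different axes of the matrix.

For each k in 2..6, 50 repeats each subsample 80% of the feature rows
without replacement (samples are never subsampled, so the co-clustering
denominator is constant) and partition all samples. The consensus matrix
holds co-assignment fractions. Stability is summarised by:

- **1−PAC** with ambiguous interval (0.1, 0.9), computed on the strict
  upper triangle;
- **mean silhouette** on distance 1 − consensus against the voted
  classes;
- **concordance**: each repeat's partition is relabeled onto the first
  repeat by Hungarian maximum-agreement matching, classes are assigned by
  per-sample majority vote (ties to the lowest class index), and
  concordance is the mean fraction of samples on which a relabeled repeat
  agrees with the vote;
- **Jaccard index** between consecutive-k classifications over
  co-clustered sample pairs (1 when both pair sets are empty).

Best-k selection: rule 1 removes k whose Jaccard against k−1 exceeds
0.95 (the finer partition adds nothing); rule 2 takes the largest
surviving k with 1−PAC > 0.9, marking other qualifiers optional; rule 3
(fallback) is a majority vote among the argmaxes of 1−PAC, silhouette and
concordance, resolved in favour of 1−PAC when all three disagree.
Ties in any argmax resolve to the smaller k. A result where no k reaches
the 1−PAC cut is flagged `weak_structure`. Samples are "confidently
assigned" when their silhouette is ≥ 0.5 — a documented operating choice,
not an estimate.

The model/results split follows the statsmodels convention:
`ConsensusPartition(matrix, config).fit()` returns a `ConsensusResult`
with the per-k metric table, classes, silhouettes, confidence flags and a
`summary()`.

## Protein-side characterization

Protein clusters are average-linkage agglomerative clusters of z-scored
rows under Euclidean distance, cut at a user-chosen number (default in
the CLI: best_k + 1; the display-oriented choice is inherently free). The
cluster–class association table holds the mean row z-score per (cluster,
class).

The differential shortlist keeps proteins with ≥ 2 supporting peptides,
max pairwise fold change of class means ≥ 2, and one-way ANOVA p ≤ 0.05
(all inclusive). Intensities are modelled on the log2 scale throughout;
the fold change is computed on the natural scale as
2^(max class mean − min class mean), i.e. the largest pairwise ratio of
geometric-mean intensities — a definition that reduces to the usual
two-group fold change when k = 2.

Enrichment is a hypergeometric over-representation test of a selected
protein set against a user-supplied GMT collection, sets intersected with
the analysis universe first, with Benjamini–Hochberg control across sets.
Ranked permutation GSEA is out of scope by design; outputs are labelled
as ORA.

## Repertoire metrics

A clonotype is a unique (V gene, J gene, CDR3 amino-acid sequence)
triple; records sharing the key within a (chain, isotype) stratum merge
with summed read counts, and relative frequencies are computed within the
stratum. Metrics: clonotype counts per stratum; occupancy of the
half-open frequency bins (0,10⁻⁴], (10⁻⁴,10⁻³], (10⁻³,0.01], (0.01,0.1],
(0.1,1] (occupancies sum to 1; the top two bins — frequency > 0.01 —
constitute the hyperexpanded fraction); clonotype-weighted (not
read-weighted) V, J and V–J usage tables whose marginals are exact; and
CDR3 clustering, where similarity is 1 − Levenshtein/max-length (edit
distances via edlib), an edge joins sequences at similarity ≥ 0.8, and
clusters are single-linkage connected components. Pairwise clustering is
O(n²) and intended for per-sample repertoires, not pooled read-level
data.

## Clinical statistics

- **Median 95% CI** by the rank formula n/2 ± 1.96·√(n/4), ranks rounded
  to the nearest integer (0.5 up) and clamped to [1, n]; requires n ≥ 6.
- **Group comparison decision tree**: per-group Shapiro–Wilk at α = 0.05
  (a programmatic surrogate for visual Q–Q assessment), variance
  homogeneity by a two-sided F test (two groups) or Bartlett's test
  (more); both pass → t test / one-way ANOVA, otherwise Mann–Whitney U /
  Kruskal–Wallis. The path taken is reported. Identical constant groups
  return p = 1 with a warning.
- **Fisher's exact test**, two-sided by summing hypergeometric
  probabilities ≤ that of the observed table (scipy), cross-checked in
  the test suite against exhaustive enumeration.
- **ROC**: AUC by the rank statistic (ties half-weighted), AUC CI by
  DeLong, operating threshold by Youden's J, sensitivity/specificity CIs
  by Wilson. These CI method choices are standard but will not
  necessarily reproduce intervals computed by other software to the
  digit.
- **Responder** = MG-ADL improvement ≥ 3 points from baseline; a missing
  follow-up yields an explicit missing label, never "non-responder".
- **Time-weighted average steroid dose** over a 183-day pre-baseline
  window, computed only when doses are known on ≥ 80% of window days, as
  the sum of observed doses over the number of observed days. The
  inclusion decision depends only on coverage.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, not any real
cohort:

- **Proteome**: per-protein baseline ~ N(20, 2) log2 units; 4 planted
  protein blocks (15% of proteins each) elevated by `block_effect` ×
  `noise_sd` (default 3 SD) in their associated sample group; a shared
  per-(block, sample) latent factor (SD 0.25 × noise SD) adds
  within-block correlation beyond what the group shift induces while
  staying too weak to plant stable within-group substructure — planted
  groups are internally unstructured by design, which is what "four
  well-separated groups" means operationally. Missingness is a 50/50
  mixture of completely-at-random and intensity-dependent (logistic
  weight decreasing in intensity); outliers add ±(5–10) × noise SD.
  Defaults mirror the study scale: 140 samples × 432 proteins
  (60,480 entries), 4 groups.
- **Clinical**: QMG/MG-ADL baselines group-shifted (+5 for the designated
  severe group), onset age < 50 labels EOMG and ≥ 50 LOMG, a 183-day
  steroid-dose history with random gaps, and follow-up scores in which the
  severe group improves more.
- **Repertoires** (3 samples per group by default): clone frequencies
  follow a Zipf tail (exponent 1.2) capped at frequency 0.008 so that
  multinomial sampling noise keeps tail clones below the hyperexpansion
  edge; severe-group heavy-chain IgG repertoires carry a target 10–20%
  hyperexpanded occupancy in a few motif-sharing clones assigned the
  IGHV3-7/IGHJ4 pair, other groups 0–5%. Observed counts are a
  multinomial draw at the configured read depth with unobserved clones
  dropped, so concentrated repertoires show fewer distinct clonotypes at
  equal depth.
- **MAC readouts**: complement-activation percentages N(25, 12) clipped
  to [0, 100], severe group shifted +30 points; responder labels for a
  follow-up subset follow a logistic link expit((MAC − 50)/10).

Every generator is a pure function of (config, seed). What passing tests
on this data do **not** show: robustness to batch effects, non-Gaussian
intensity distributions, unbalanced group sizes, correlated missingness
across samples, isotype-switching structure, or sequencing error — none
of which the generator emulates.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script are desk-scale
choices made by the package: planted-recovery runs use 120 samples × 400
proteins with 50 subsample repeats over k = 2..6 and 10 seeds; the
Fisher-vs-enumeration cross-check enumerates all 2×2 tables with N ≤ 16
exhaustively plus a seeded random sample up to N = 40; null
type-I-error calibration uses 600 independent null protein rows as
replicates. Seeds are threaded explicitly everywhere; all ties break
deterministically (lowest index). Degenerate inputs (all-constant rows,
single-class labels, zero-norm vectors, empty gene lists) raise typed
errors rather than producing silent output.

Known limitations: the consensus machinery assumes the feature matrix
fits in memory and the sample count is in the hundreds (consensus and
silhouette computations are O(n²) in samples); the best-k rules inherit
the coarseness of any threshold-based selector near their cut values
(1−PAC within noise of 0.9, Jaccard near 0.95); and ORA treats gene sets
as unordered — no direction or ranking information is used.
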