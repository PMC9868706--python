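# Methods

This note documents the models, defaults and numerical choices behind
`chemotyper`, and what the synthetic-data tests do and do not establish.

## Data model

A `FeatureTable` is a sample × feature matrix of non-negative intensities
(NaN = undetected) with per-sample metadata: role (`biological` or
pooled-`qc`), injection order (unique within a platform), collection and
replicate identity, and platform tag. Zeros are treated as measured
values, not missing. Trait tables carry the fixed 13-trait leaf-morphology
vocabulary (LL, LTWR, LDH, LDW, LDN, LW, LA, CRV, LP, LT, SL, SLFW,
SLDW) with no missing entries. When per-platform tables are merged,
duplicate metabolite annotations keep the copy with the lower QC RSD
(the more reproducible measurement), ties preferring the LC-MS/MS copy.

## Synthetic data generator

The generator emulates a germplasm leaf-metabolomics screen. Per
biological replicate of collection *i*, feature *j*:

log x = b_j + s·ln2·Δ·[j marks chemotype(i)] + d_ij + ε,
multiplied by a drift factor at the sample's injection order.

* **Baselines** b_j ~ U[9, 14] on the ln scale (≈ 10⁴–10⁶ instrument
  units, the dynamic range of annotated features).
* **Chemotypes.** Default four groups of 60/50/30/20 collections with 25
  disjoint up-regulated markers each at Δ = log₂FC = 1.
* **Biological/replicate variation.** Collection-level deviation d_ij with
  ln-sd 0.3 (~35% CV between collections) plus replicate noise ε with
  ln-sd 0.2 (~22% CV), typical of leaf material and GC/LC workflows.
* **Modules.** Optional feature blocks share a standard-Gaussian latent
  factor with loading √(intra_module_cor); traits are linear in the
  latent factors plus Gaussian noise (a link (m, trait, c, σ) plants a
  true correlation c/√(c²+σ²)). By default markers are drawn *outside*
  the modules so that the planted chemotype signal is not confounded with
  module-factor variance; `markers_in_modules=True` plants each
  chemotype's markers inside one module, creating the
  marker → module → trait chain the trait-linkage stage detects. The
  module/trait studies use that switch explicitly.
* **QC samples.** Pooled mean of all biological profiles (pre-drift),
  injected first and after every 10 biological runs, with technical-only
  noise (ln-sd 0.05): a pooled QC re-injected repeatedly varies far less
  than biological replicates.
* **Drift.** Per-feature multiplicative curves mixing a shared monotone
  trend + low-frequency random walk (weight 0.7) with a feature-specific
  walk, scaled so the ln-amplitude is `drift_amplitude` and normalized to
  mean factor 1. The decorrelation scale is 50 injections: instrument
  drift evolves over many QC intervals, which is the premise of QC-based
  calibration (a curve wiggling at the QC cadence would be unidentifiable
  from QC points by construction).
* **Missingness.** Half MCAR, half preferentially in the lowest-intensity
  decile, since MS detection dropouts are abundance-linked.

The generator is a pure function of its seed. What passing tests show:
the pipeline recovers structure *of the planted kind* (multiplicative
smooth drift, Gaussian log-intensity groups, linear trait couplings).
What they do not show: robustness to retention-time misalignment,
batch boundaries, adduct/isotope redundancy, or non-linear trait
relationships — none of which the generator emulates.

## Preprocessing

* **Filter:** a feature missing in ≥ 80% (inclusive) of biological
  samples is dropped; QC samples are not counted.
* **Imputation:** k-nearest-neighbour (default k = 10) with
  nan-Euclidean distance (squared distance over shared observed features,
  scaled by the shared count); observed cells are never altered.
* **Drift correction:** per feature, the chosen regressor is fitted to QC
  intensity (normalized by its QC median) versus injection order; the
  drift factor is fitted/median(fitted at QC orders), clipped to
  [0.1, 10]. Regressors: random forest (500 bagged CART trees, single
  predictor, min leaf 5 — implemented as a vectorized single-predictor
  forest in which each tree partitions the sorted injection-order axis,
  so all features' forests are built simultaneously), LOESS
  (statsmodels `lowess`, span 0.75, locally linear — no installed
  package provides the locally quadratic variant — with linear
  extrapolation beyond the QC range), and RBF-kernel SVR (ε = 0.1,
  scale-heuristic γ) on min-max-scaled order.
* **Reliability weighting.** Each feature's correction factor is raised
  to w = clip(CV R²/0.9, 0, 1), where CV R² is the regressor's 5-fold
  (interleaved) cross-validated predictive power on its QC series. A
  trend that cannot predict held-out QC values is indistinguishable from
  technical noise, and correcting it would *inject* noise: without the
  weight, a drift-free table is distorted by up to ~8% where the
  regressors chase QC noise. Full correction applies from CV R² ≥ 0.9;
  the ramp below that trades a small under-correction for robustness.
* **Method selection:** all three regressors are run; a method qualifies
  when its reserved fraction (features with corrected QC RSD below the
  platform threshold, 0.50 GC-MS / 0.30 LC-MS) reaches 0.70; the best
  reserved fraction wins, ties preferring rf, then loess, then svr; if
  none qualify the best is used with a warning.
* **Replicate outliers:** within each collection, the `n_remove`
  replicates farthest (Euclidean) from the collection centroid in the
  global top-2 PC plane (computed on log-autoscaled biologicals) are
  dropped; collections with ≤ n_remove replicates are kept intact. Off
  by default for designs with exactly 3 replicates.
* **Standardization:** log₁₀, per-feature autoscaling to mean 0 / sd 1
  over biological samples (population sd), replicate means per
  collection. Base-10 and unit variance are conventional choices for
  metabolomics "log standardization"; both are config-exposed.

## Chemotype discovery

* **Gap statistic** (uniform bounding-box reference): Wₖ is the total
  within-cluster sum of squares of the best of 10 seeded K-means
  restarts; gap(k) = mean_b log Wₖ*(b) − log Wₖ, s_k = sd_b·√(1+1/B).
  k̂ is chosen by the first-SE-max rule (the default of R's
  cluster::clusGap): the smallest k whose gap lies within one s_k of the
  gap curve's first local maximum. The original sequential one-SE rule
  stalls at k = 1 on symmetric multi-cluster data, where
  gap(1) ≈ gap(2) ≈ 0 despite a dominant peak at the true k.
* **SOM:** rectangular 7 × 7 grid, codebook initialized on the top-2
  principal-component plane (deterministic), sequential best-matching-
  unit updates with Gaussian neighbourhood. The neighbourhood width
  decays linearly from max(rows, cols)/2 to 0.1 — the final phase is
  effectively neighbourhood-free fine-tuning (Kohonen's classic second
  phase), without which the codebook remains a smoothed average and
  cannot converge onto the data — and the learning rate decays 0.5→0.01.
  Quantization error (mean sample→BMU distance) and topographic error
  (fraction of samples whose two best units are not 4-adjacent) are
  recorded every epoch; the returned codebook is the epoch snapshot
  minimizing qe + te (equal weights, config-exposed).
* **Node → chemotype:** average-linkage hierarchical clustering of
  codebook vectors cut at k groups; collections take their BMU's group.
  Chemotypes are numbered 1..k by descending size (ties by first
  occurrence) — a convention, since no canonical ordering exists.

## Evaluation

* **RF adjudication:** stratified 75/25 split; 1,000 trees, √p features
  per split; training accuracy is out-of-bag, test accuracy and macro
  one-vs-rest AUC on the held-out set; scores are means over 20 seeded
  splits. Candidates with unscorable labellings (singleton classes)
  receive NaN rows with a warning.
* **OPLS-DA:** orthogonal components (X-variation uncorrelated with the
  ±1 response) are deflated first, then a single predictive component is
  extracted. R²Y(cum) is the response variance the predictive component
  explains; Q²(cum) = 1 − PRESS/TSS over stratified 7-fold CV (the
  orthogonal filter is re-estimated inside each fold; no leakage). VIP
  weights the squared normalized loadings by each component's variance
  share — the predictive component by explained Y variance, orthogonal
  components by their X-variance shares — normalized so Σ VIP² = p
  exactly. Permutation validation refits on shuffled responses;
  empirical p = (1 + #{permuted ≥ observed})/(n_perm + 1).
* n_orth defaults to 1; class imbalance is handled by stratification
  only.

## Marker screening

All four statistics are computed one-vs-rest per chemotype: VIP from the
OPLS-DA model on the standardized collection matrix; two-sided Student's
t (pooled variance; Welch behind a flag; zero-variance comparisons report
p = 1); fold change as the ratio of *linear-scale* collection-mean
intensities (group/rest); MDA as the per-tree out-of-bag accuracy drop
under feature permutation, divided by its standard error over trees (one
shared row permutation per tree, applied column-wise — equivalent to
independent per-feature permutations for this statistic, and
vectorizable). The joint rule is VIP ≥ 2 AND p < 0.05 AND |log₂FC| > 0.5
AND MDA ≥ 2. The fold-change criterion is interpreted two-sidedly on the
log scale because a raw ratio > 0.5 excludes almost nothing and
down-regulated markers exist; the literal raw-ratio rule is available via
`fc_mode="raw"`. No multiple-testing correction is applied inside the
joint screen (the four criteria are jointly far stricter than p alone).

A caveat established during development: the SE-scaled MDA is
overdispersed on null features relative to N(0, 1) — spurious
finite-sample feature–label association is shared across all trees, and
R's `randomForest` scaled importance shows the same heavy tail — so the
MDA ≥ 2 criterion is meaningful as one of four joint filters, not as a
calibrated 2.5% test on its own.

## Trait linkage

* **Soft threshold:** smallest power β with scale-free fit R² ≥ 0.8
  (log-log degree-distribution regression over 10 equal-width
  connectivity bins; fit is 0 when the slope is non-negative). When no
  power qualifies — typical when co-expression forms a few
  comparable-size modules, whose degree distribution is bimodal rather
  than scale-free — the conventional unsigned default β = 6 is used;
  chasing the best fit instead drives β so high that all adjacency
  vanishes.
* **Modules:** unsigned TOM, average-linkage tree on 1 − TOM, static cut
  at height 0.99 (a deterministic simplification of dynamic tree cut),
  clusters < 10 features to module 0 ("grey"); modules renamed by the
  conventional size-ordered colour list. Eigenmetabolites are
  sign-oriented (positive mean loading), unit-variance first principal
  components of the standardized module submatrix.
* **Module–trait correlation:** Pearson r with two-sided p over shared
  collections (Spearman is a noted alternative for monotone non-linear
  couplings).
* **Morphological markers:** per chemotype, the module holding the
  largest count of its up-regulated chemomarkers; its trait is the
  max-|r| trait with p < 0.05, else none (with a warning).
* **RF regression importance:** %IncMSE = mean per-tree percent increase
  of out-of-bag MSE under feature permutation (1,000 trees, mtry = p/3).
* **LASSO predictability:** outer 10-fold CV produces held-out
  predictions; the penalty within each outer training set is chosen by
  5-fold inner CV with the 1-SE rule (sparsest λ within one standard
  error of the minimum CV error). Predictability = 1 − SSE/SST on the
  pooled held-out predictions; it may be negative and is not clamped.
  Out-of-fold R² is used because resubstitution R² of a tuned LASSO is
  optimistically biased and not comparable across traits.
* **Trait ANOVA:** one-way per trait across chemotypes with Tukey HSD
  pairwise comparisons.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from the global seed by a stable CRC32 hash, and a run's
manifest (config, stage seeds, output SHA-256 hashes, timings) makes
reruns byte-comparable. The verification studies use these problem
sizes, chosen to estimate each rate with adequate precision at desk
scale: the default design (160 × 3 × 600) for end-to-end recovery,
drift and marker studies; 100 seeds (tests; 50 in the acceptance script)
of 160-point 2-D data for gap-statistic calibration rates with B = 25
reference draws over k = 1..8; 10 masking seeds for imputation; a
200-feature, 5-module design for module/trait recovery; 20 seeds
(tests; 10 in the script) of a 160 × 200 design for LASSO calibration.

## Known limitations

* LOESS is locally linear (degree 1); strongly curved drift within a
  span is better served by the rf regressor, which the selection step
  generally prefers.
* The static TOM tree cut at 0.99 does not merge highly correlated
  modules the way dynamic tree cut's eigengene-merging step would;
  planted equal-size modules are recovered cleanly, but real data with
  nested correlation structure may fragment.
* The gap statistic's uniform bounding-box reference loses power in very
  high-dimensional, strongly correlated matrices; the RF adjudication
  over candidate k values is the pipeline's robustness mechanism, as the
  classification stage evaluates k ∈ {4, 5, 6} for both clusterers.
* OPLS-DA is one-vs-rest only; no multi-class OPLS.
* Chemotype numbering is by size, so labels are not comparable across
  datasets with different group-size orderings.
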