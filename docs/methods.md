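# Methods

This note documents the models, estimators and numerical choices behind
`ectpredict`, and what the synthetic studies do and do not establish.

## The classification design

The pipeline predicts a binary treatment-response label from a subjects ×
features matrix of pre-treatment fMRI metrics under a nested, repeated
cross-validation design:

- **Outer validation.** 5-repeated 5-fold stratified cross-validation.
  For n = 46 balanced subjects this gives 25 train/test partitions with
  training sets of 36–37 (modal 37) and test sets of 9–10, each within
  one subject of class balance. Stratification is an explicit choice (a
  plain random split at n ≈ 9 too often yields unevaluable test folds).
- **Feature selection.** Within each outer training set, a further
  5-repeated 5-fold split yields 25 feature-selection partitions. Each
  runs recursive feature elimination (RFE) with an RBF-kernel SVM.
  Radial kernels expose no coefficients, so features are ranked by
  permutation importance: the AUROC drop on the partition's held-out
  fold when that feature's column is shuffled (one shuffle; all shuffled
  copies scored in a single batched kernel evaluation). Candidate subset
  sizes follow a halving grid {p, 256, 128, …, 4, 2}; the size with the
  best held-out AUROC is that partition's selected set, ties going to
  the smaller (more parsimonious) size.
- **Consistency ranking.** Features are re-ranked by the number of the
  25 feature-selection partitions that selected them (25 = 100%
  consistency); ties break lexicographically. The top 25 features feed
  the model sweep.
- **Model sweep.** For each size s ∈ {2, …, 25} (24 models), an RBF-SVM
  on the top-s features is tuned on the outer training set by stratified
  resampled AUROC over a grid of kernel widths (median heuristic of the
  squared pairwise distances, × {0.1, 1, 10}) and costs {0.25, 1, 4},
  refit, and evaluated once on the outer test fold. Features are
  z-scored with training-set statistics only. Sensitivity is responder
  recall, specificity non-responder recall, balanced accuracy their
  mean; PPV/NPV are derived from the same 2×2 table.
- **Null comparison.** The identical pipeline is rerun on the same
  features with labels randomly permuted (balanced by construction;
  identity permutations are re-drawn). Veridical and null records are
  compared per metric × size with one-tailed Welch t tests (unequal
  variances, Welch–Satterthwaite df; direction veridical > null) and
  Benjamini–Hochberg FDR, adjusted by default within each metric
  (3 families of 24); a pooled single family is available by flag.
- **Post hoc regressions.** Each top-ranked feature is regressed (OLS)
  against mean percent improvement with age as a nuisance covariate, on
  the full cohort. These are descriptive — they reuse all subjects and
  are not cross-validated — and p-values are reported uncorrected.

All randomness flows from one root seed through `numpy.random.SeedSequence`;
runs are bit-for-bit reproducible at fixed thread count.

### Leakage boundaries

The near-zero-variance and collinearity filters run once on the full
cohort before any train/test split. They are label-free, so they leak no
outcome information, but they do use all subjects' feature distributions;
this mirrors common practice and is flagged as a trade-off. Everything
label-dependent (RFE, consistency ranking, tuning, standardization) sees
only training subjects; a construction test corrupts outer test rows and
verifies the selection outputs are unchanged.

## Metric definitions

- **CBF (ASL simple subtraction).** Per voxel, the mean of pairwise
  control − label differences; tag order is declared (default
  label-first). The default output is the unscaled perfusion-weighted
  map; absolute quantification needs calibration constants the caller
  must supply.
- **ReHo.** Kendall's coefficient of concordance
  W = 12·S / (k²(n³ − n)) for the k timecourses of a voxel and its
  neighbors (7/19/27-voxel neighborhoods, clipped at volume edges), S the
  sum of squared deviations of per-timepoint rank sums. Ties take
  midranks with no tie correction; a fully constant neighborhood is
  masked rather than given a value.
- **fALFF.** After linear detrending, the sum of discrete-Fourier
  amplitudes at band-inclusive frequencies (0.01–0.1 Hz by default)
  over the sum across all positive frequencies. Note that detrending and
  spectral leakage keep even a pure in-band sinusoid slightly below 1.
- **Connectivity strength.** Pearson correlation between two node
  timecourses; constant nodes propagate masked values.
- **Graph metrics.** The network is built from the node correlation
  matrix by discarding negative weights and retaining the strongest 25%
  of edges (proportion configurable; the policy is recorded in all
  outputs — no single convention exists for "the thresholded whole-brain
  network", so provenance matters more than the particular default).
  Strength is the weighted degree; clustering is Onnela's geometric mean
  of triangle weights (normalised by the maximum weight); local
  efficiency is the standard weighted neighborhood formulation with
  shortest paths on 1/w edge lengths inside each node's neighborhood
  subgraph. Nodes of degree < 2 get clustering and efficiency 0. A
  plausible alternative reading of "local efficiency" as a node-to-network
  average shortest path length exists in the applied literature; the
  toolbox-standard neighborhood definition was chosen and is
  oracle-tested.
- **Filters.** The frequency ratio compares the counts of the two most
  prevalent values after rounding to 8 significant digits (raw floats
  almost never repeat, which would make the test vacuous). Defaults:
  remove when ratio > 19 *and* distinct-value fraction < 0.10; constants
  always removed. Collinearity uses absolute correlation (redundancy is
  sign-agnostic): while any pair exceeds |r| = 0.70, the member of the
  worst pair with the larger mean |r| to all remaining features is
  removed; mean-correlation ties drop the lexicographically later name.

## The synthetic cohort generator

The generator emulates the *structure* of a pre-treatment multimodal fMRI
study of ECT response at configurable scale: default 46 subjects, 202
ROIs, 31 RSNs, 178 timepoints at TR 2.0 s, 30 ASL label/control pairs.

- **Timecourses** are AR(1) + random low-frequency sinusoid mixtures with
  a weak global component (baseline positive connectivity). For a planted
  node pair, both nodes load on a shared component with per-subject
  loading λ = clip(0.5 + 0.18·z, 0.05, 0.95), so the pair's Pearson
  correlation is the planted quantity.
- **Outcome model.** The five planted latents z share a common factor u
  (mutual correlation 0.6, deliberately below the 0.70 collinearity
  cutoff): consistently selected features in this kind of study belong to
  one interacting network system, not to five unrelated circuits.
  Improvement is 45 + 12·(es·u + σ·ε)/√(es² + σ²) percent, with
  effect size es (default 1.0) and residual scale σ (default 0.5). At
  the defaults each planted feature correlates ≈ 0.5–0.7 with
  improvement — the regime in which a nested RFE design at n = 46 can
  recover features at high consistency, and comparable to the strong
  positive feature–improvement correlations such designs report.
  Independent weak latents would be unrecoverable by *any* method at
  this n (the maximum spurious |r| over a few hundred features matches
  the planted signal), which would make every downstream test vacuous.
- **Clinical scores.** Three scales with pre-treatment means anchored at
  HAMD-17 24.0, MADRS 37.5, QIDS 19.7; each scale's percent change is
  the subject's latent improvement plus scale-specific jitter (sd 5),
  so the cross-scale mean is meaningful. Ages are N(41.7, 6.8) and enter
  only as the post hoc covariate.
- **Nuisance structure.** A block of connectivity features driven by one
  shared subject latent (pairwise r > 0.70 → pruned by the collinearity
  filter) and node pairs with identical series (correlation exactly 1 →
  zero variance, caught by the near-zero-variance filter).
- **Voxel phantoms.** Small grids (default 12×12×8) whose label volume
  tiles ~90% of voxels into equal ROIs; one designated ROI shares a
  sinusoidal component (high ReHo/fALFF by construction) and ASL volumes
  alternate label/control with an exact, known per-ROI difference.

What the generator does **not** emulate: spatial structure (registration
error, smoothing, partial voluming), scanner artifacts and motion,
heavy-tailed or autocorrelation-matched BOLD spectra, site effects, and
realistic missingness. Passing tests therefore establish that the
*pipeline* behaves correctly under its own assumptions — not that those
effect sizes are attainable in patients.

## Simulation studies and their scales

Problem sizes were chosen so each study runs in minutes on one CPU while
keeping the full nesting where it matters; they are fixed in
`ectpredict.studies` so tests, analysis scripts and the reproduction
script run identical conditions.

- **Chance calibration.** Standard cohort (16 ROIs / 4 RSNs, ~180
  post-filter features), the full 5×5/5×5 nested pipeline with fixed
  hyperparameters (median-heuristic width, C = 1), labels permuted.
  A single permutation is *not* enough to estimate the chance level: the
  permuted labels chance-correlate with the learnable planted factor at
  r ~ n^(-1/2), which moves a single run's mean balanced accuracy by
  several points in either direction. The chance level is therefore the
  mean over 6 independent balanced permutations, with the Monte-Carlo
  standard error taken across permutation means. This estimates the same
  quantity as a one-permutation control, with quantified error.
- **Parameter recovery.** 20 cohorts (12 ROIs / 3 RSNs, planted features
  only, ~115 features), outer 3-repeated 5-fold, inner 5×5 (selection
  stability is the object under test, so the 25 feature-selection splits
  are kept), fixed hyperparameters. Checks: planted features occupy ≥3
  of the top-5 aggregate consistency ranks in ≥80% of cohorts, and the
  veridical-vs-null Welch/FDR comparison flags balanced accuracy at ≥1
  feature-set size in ≥80% of cohorts.
- **Type-I control.** 50 no-signal cohorts (effect size 0; 10 ROIs),
  2-repeated 3-fold everywhere: the average fraction of FDR-significant
  metric × size tests stays ≤ 5%.

## Known limitations

- The feature census at full scale (202 ROIs, 31 RSNs) is derived from
  first principles: C(202,2) = 20,301 ROI pairs, 202×31 = 6,262 ROI–RSN
  pairs, C(31,2) = 465 RSN pairs. Published applications of this design
  report slightly different totals that do not reconcile combinatorially;
  the package trusts the arithmetic.
- At desk scale (a few hundred features, top-25 tables), the cross-split
  consistency of *null* runs is inflated by chance overlap, so the
  within-RFE vs cross-split dissociation that distinguishes veridical
  from null selection is muted relative to a 1,800-feature cohort. The
  diagnostics report both quantities; only their ordering is asserted.
- RFE importance uses one shuffle per feature on small validation folds;
  it is deliberately cheap and noisy, matching the instability such
  designs actually exhibit. Increase `n_importance_shuffles` for
  smoother rankings.
- The sweep's tuning AUROC is reported but not an unbiased performance
  estimate (it is maximised over the grid); only outer-fold metrics are.
- Group-ICA estimation of RSN maps, spatial preprocessing, and GM-volume
  derivation are out of scope; RSN timecourses are inputs, and GM volume
  can only be appended as a precomputed feature block.
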