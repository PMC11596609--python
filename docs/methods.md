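# Methods

## The problem

Honey is among the most frequently adulterated foods: cheap sugar
syrups — rice, beet, or high-fructose corn syrup (HFCS) — are blended
into authentic honey at volume fractions from a few percent upward.
Untargeted LC-MS is sensitive enough to see low-level additions, but
routine laboratories historically could not use it, because standard
processing (retention-time alignment plus peak correspondence across
samples) couples every sample to its processing batch: classifying one
new sample would mean reprocessing the entire accumulated reference
set. `honeyscreen` implements the alternative: summarize each run
*independently* onto a fixed grid, and let a supervised model absorb
the residual instrumental variance.

## Processing model

**Peak detection.** A simplified centWave-style procedure per run and
per MS level / vDIA window. Centroids are pooled across scans, sorted
by m/z and split at relative gaps above the ppm tolerance (default
5 ppm); each m/z cluster is split at retention-time gaps larger than
1.5 scan intervals and must span at least `min_scans` (5) consecutive
scans. Within an ROI, elution peaks are local maxima of a 3-point
moving average; bounds expand to the first local minimum or to the
point where intensity falls below `bound_frac` (10 %) of the apex.
Gates: base width inside `peakwidth` (5–15 s) and apex at least
`snr_min` (3) times the median trace intensity outside candidate peaks
(floor 1). Peak intensity is the summed trace intensity between the
bounds — an area proxy that is conserved by bucketing and linear in
the input intensities. The continuous-wavelet stage of full centWave
is omitted deliberately: downstream features are 20 s × 2 Da bucket
sums, so sub-second apex refinement cannot change them.

**Bucketing.** The grid is defined purely by configuration (m/z range,
RT span, widths 2 Da × 20 s; one layer per MS level / vDIA window,
fragment layers spanning the window's detection range rounded outward
to 2 Da multiples). Buckets are half-open `[lo, hi)`; a peak
contributes its whole intensity to the bucket of its weighted-mean m/z
and apex RT; out-of-grid peaks are dropped with a count. Vectors are
TIC-normalized (each bucket divided by the vector total), so every
normalized block sums to 1; a signal-free run cannot be normalized and
is removed from the cohort, with a report. The central property,
guaranteed by construction and asserted by tests, is sample
independence: no processing step sees more than one run, so a vector
is bit-identical whether computed alone or in any batch.

**Alignment.** None by default — tolerating modest RT drift is what
the coarse buckets are for. An optional rigid-shift correction
(`align_global_shift`) searches integer-second offsets against a
stored reference vector and keeps the cosine-similarity maximizer
(ties toward zero). It replaces warping-based alignment, which would
reintroduce cross-sample coupling.

**Fusion and splitting.** Low-level fusion concatenates each sample's
normalized blocks in a fixed order (HILIC MS1, RP MS1, then any
fragment layers); a fused row sums to the number of blocks, and block
slices are retained so fusion is lossless. The train/test split is by
honey: all six samples of a held-out honey (pure + five mixtures)
leave the training set together, so test metrics measure
generalization to unseen honeys.

## Models

* **Classification** (pure vs adulterated): bagged CART trees with
  case-weighted bootstrap — each tree is grown on a multinomial
  bootstrap with inclusion probability proportional to the sample's
  case weight, `n_total / (2 n_class)`, so both classes contribute
  equal expected mass to every tree. This mirrors the `case.weights`
  semantics of the R `ranger` forest (sampling weights), which behaves
  better under imbalance than impurity re-weighting; tree induction
  itself is scikit-learn's `DecisionTreeClassifier`. Out-of-bag error
  is the unweighted misclassification rate of OOB votes. Prediction
  ties resolve to the lowest class code (pure). Defaults: 5000 trees,
  `mtry = round(sqrt(p))` (round-half-up, reproducing 205/259/330 for
  p = 42,000/67,200/109,200), minimal node size 1.
* **Regression** (syrup % v/v): scikit-learn `RandomForestRegressor`,
  5000 trees, same `mtry` rule, minimal node size 5 (mapped to
  `min_samples_split=5`; `ranger`'s `min.node.size` is a stopping
  size, the two differ by at most one sample per node). Trained on all
  training samples including the pure (0 %) ones, so the estimator is
  defined for unadulterated honey.
* **Metrics.** Headline R² is the squared Pearson correlation of
  predicted vs true proportions (robust to affine miscalibration, as
  read off a predicted-vs-known scatter); the `1 − SS_res/SS_tot` form
  is reported alongside. RMSE and per-level mean absolute errors are
  in percentage points v/v. Classification is reported as OOB error,
  held-out accuracy and a per-level correct/total tally.
* **PCA QC.** Column-centered, unscaled PCA of the full matrix; the
  first two components are summarized by silhouette scores for device
  and proportion labels. On multi-device cohorts the device silhouette
  dominates — the motivation for supervised modeling.

## Synthetic cohort

The generator reproduces the study design (34 honeys; rice, beet and
HFCS scenarios; mixtures at 5/10/20/50/80 % v/v; 3 devices; HILIC
negative and RP positive modes; randomized, seeded acquisition order)
at compound level:

* **Blocks.** 60 shared-sugar compounds (glucose/fructose-like), 120
  honey-block, 60 per-syrup, 60 ubiquitous background compounds,
  shared across modes with independent per-mode retention times.
* **Templates.** Honey: 35 % of abundance mass on shared sugars, 45 %
  honey-block, 20 % ubiquitous. Rice/beet: 5 % shared, 75 % on their
  own marker block, 20 % ubiquitous. HFCS: 35 % shared (honey-like),
  **no** unique block — like the real syrup, whose sugars all occur in
  honey — with the remainder on the ubiquitous block. This makes the
  similarity gradient structural: rice/beet are detectable from marker
  buckets, HFCS only from a compositional shift.
* **Honey diversity.** Per-honey log-normal variation per compound
  (sd 0.4 on the honey block, 0.2 elsewhere) plus a per-honey whole-
  block scale factor (sd 0.15), so natural between-honey composition
  differences confound small admixture shifts — the mechanism that
  makes low-level HFCS genuinely hard.
* **Mixing.** Samples are equal-concentration solutions blended by
  volume, so mixture abundances are exactly `(1−p)·honey + p·syrup`;
  with noise off this linearity survives the full render → detect →
  bucketize chain to within peak-integration error (≤ 5 % per occupied
  bucket), which the tests assert.
* **Acquisition.** Gaussian elution profiles (sd 1.5–3 s), 1 s MS1
  scans, centroids recorded above a 200-count floor; per-run
  log-normal intensity noise (sd 0.15), RT jitter (sd 1 s), m/z jitter
  (sd 1.5 ppm), and 50 spurious noise peaks around the 1000-count
  noise floor. Devices differ systematically: RT shift −15/0/+15 s,
  intensity gain 0.7/1.0/1.4 (cancelled by TIC normalization), m/z
  offset ±3 ppm — strong enough to dominate PCA without destroying
  the supervised signal. Optional vDIA MS2 rendering emits two
  deterministic pseudo-fragments per precursor into the matching
  window layer.
* **Scale.** The default acquisition is desk-scale: RT spans 200 s
  (HILIC) and 240 s (RP) instead of the instrument-scale 1200/1920 s,
  giving 7,000 + 8,400 = 15,400 fused variables instead of
  42,000 + 67,200 = 109,200. The span only multiplies empty grid area
  and scan count; the structure (compound density per bucket, device
  effects, noise) is preserved. Full-scale grids are exercised as grid
  arithmetic in the tests; instrument-scale rendering is a
  configuration change (`rt_span`), not a code path.

**What the generator does not emulate:** isotope patterns, adducts,
in-source fragmentation, ion suppression, column aging or drift within
a batch, chimeric MS2 spectra, and adversarially formulated syrups.
Passing tests therefore demonstrate that the pipeline recovers the
designed structure under realistic noise — not that real-world
performance at these exact numbers is guaranteed.

## Numerical choices and degenerate inputs

Half-open bucket intervals, lower edge inclusive; the grid's upper
limits are out of range. Ties in shift alignment break toward the
smallest absolute offset, then the negative one. Zero-variance
regression predictions yield R² = 0 with a warning rather than NaN.
An all-zero feature vector raises an empty-run error at normalization
and the sample is dropped with a report. Every stochastic step — the
library, per-honey variation, device assignment, run rendering, the
honey split and both forests — is seeded explicitly, and per-run seeds
are derived from (cohort seed, scenario, honey, level, mode) so any
single run regenerates identically in isolation.

## Known limitations

The fragment-layer grid reproduces each vDIA window's detection range,
but the exact fragment-grid layout used to produce historical
fragment-inclusive variable counts is not recoverable from the
acquisition parameters, so fragment-layer counts are
configuration-defined rather than fidelity targets. Random-forest
regression compresses predictions at the extreme training levels (the
80 % level shows the largest per-level error, and a test honey's
samples at that level can only be pulled downward), which is intrinsic
to forest averaging rather than a property of the features. The
ranger-style case weights act on bootstrap sampling; with fully grown
trees their effect on already-separable problems is small, as
expected.
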