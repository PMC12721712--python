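# Methods

`sizersa` implements a cross-modal representational similarity analysis
(RSA) pipeline for disentangling three correlated object properties —
perceived real-world size, retinal size, and inferred real-world depth —
in time-resolved multichannel neural data and in model feature spaces,
together with all of the resampling-based inference it requires and a
synthetic-data generator that makes every stage testable end to end.

## Representational dissimilarity matrices

All comparisons run through RDMs: symmetric `n × n` matrices of pairwise
dissimilarity between stimulus conditions, compared via their vectorized
strict upper triangles (`n(n−1)/2` cells; 19,900 for the 200-condition
design the package emulates). Three constructions are provided:

* **decoding RDMs** — per timepoint, the cross-validated accuracy of a
  linear SVM discriminating each condition pair from the channel pattern
  (chance 0.5). Accuracy is a noise-robust dissimilarity for short-window
  multichannel data, where per-timepoint pattern correlations are unstable.
* **hypothesis RDMs** — absolute differences `|x_i − x_j|` of a
  per-condition scalar: behavioral real-world size ratings (on their
  published 0–519 scale, used without a log transform — the scale already
  spans a logarithmic size range, and everything downstream is rank-based);
  retinal size as the object's pixel diagonal; and a depth index
  `size / retinal size`, proportional to egocentric distance under
  perspective projection at fixed viewing distance. The depth index is a
  proxy, not a calibrated distance; `|Δ(s/r)|` is not scale-free, which is
  acceptable here because only ranks enter the statistics.
* **model RDMs** — `1 − Pearson(row_i, row_j)` over per-condition feature
  vectors (network layer activations, word embeddings), supplied as plain
  matrices; the package never runs networks itself.

Vectorization uses row-major `(i, j), i < j` order, fixed so bootstrap
resample indices are shared across neural, target, and control vectors.
Decoding matrices may be symmetrized (`(M + Mᵀ)/2`) on construction; all
other RDMs must be symmetric to 1e-10. Diagonals are stored as 0 and never
enter any statistic.

## Pairwise decoding

Features at timepoint `t` are the raw channel amplitudes (17 by default).
Each condition pair is decoded with repeated stratified k-fold
cross-validation (default five-times fivefold). Choices the underlying
convention leaves open are fixed and exposed in `DecodingConfig`:

* regularization `C = 1.0`;
* features z-scored using training-fold statistics only (no test leakage);
* pseudo-trial averaging off by default (`pseudo_average_k = 1`);
* fold assignment is computed on trials sorted canonically by their sample
  values, so results are invariant to trial order; repeats reshuffle with
  seeds `seed + r`. Stratified balanced folds guarantee both classes in
  every training fold.

The solver is a dual coordinate-descent implementation of the
L2-regularized squared-hinge linear SVM with a regularized intercept — the
same convex problem `sklearn.svm.LinearSVC` solves, verified to agree with
it to 1e-5 in the test suite — compiled with numba so that the ~10⁵ tiny
fits of a full pairwise decoding run execute in seconds. The default epoch
cap (`max_epochs = 200, tol = 1e-3`) is effectively converged; the
recovery studies use a reduced budget (`max_epochs = 30, tol = 1e-2`),
which biases accuracies toward chance by ≲ 0.03 uniformly across pairs —
immaterial for rank-based RSA, which only consumes the ordering of cells.

## RSA statistics

**Partial Spearman.** All vectors are rank-transformed (average ranks);
`x` and `y` are residualized on the ranked controls plus intercept by
least squares and the residuals Pearson-correlated. This equals the
precision-matrix partial-correlation formula (asserted to 1e-10). A vector
numerically fully explained by its controls gets partial correlation 0 by
definition. With no controls the function reduces exactly to Spearman.

**Cluster-based permutation test.** Per timepoint, a one-sample one-tailed
t-test against zero across subjects; contiguous supra-threshold runs
(cluster-forming p < 0.05, df = S−1 — the threshold is a config knob, since
the convention leaves it open) form clusters scored by the sum of their
t-values. The null sign-flips each subject's whole timecourse with
probability ½ and records the maximum cluster statistic; cluster p-values
use `(1 + count) / (1 + N)` so p never reaches 0. Timepoints with zero
across-subject variance are excluded with a warning. Only the one-tailed
"greater" variant is implemented. Empirical family-wise false-positive
rate on exchangeable noise: 5% (see acceptance outputs).

**Bootstrap peak latency.** Per subject and bootstrap iteration, the RDM
cells are resampled with replacement — identical indices applied to the
neural, target, and control vectors, all re-ranked after resampling — the
partial-correlation timecourse is recomputed, and the argmax latency
within the search window recorded (ties → earliest sample). The subject's
estimate is its bootstrap-mean latency; group summaries are mean ± SEM.
Paired two-tailed t-tests compare features' per-subject bootstrap means
(zero-variance differences are reported as p → 0 with a warning). The
search window is meant to be the union of significant cluster spans; with
only 3 pseudo-subjects a sign-flip null has 2³ = 8 patterns and cannot
reach p < 0.05, so the demo pipeline and the recovery studies use the full
post-onset epoch instead.

**Model × hypothesis shuffle test.** Observed statistic: partial Spearman
of the model RDM vector with one hypothesis vector, controlling the other
two. Null: shuffle the order of the model vector's cells (1000×) and
recompute all three partials; a hypothesis is flagged iff the observed
value exceeds the null's one-sided 95th percentile. Because RDM cells are
not exchangeable (they inherit metric structure), this null is mildly
anti-conservative: measured per-hypothesis false-positive rates are 5–7%
at 190 cells. This is a property of the procedure itself and is reported,
not corrected. No correction is applied across the three hypothesis
timecourses beyond cluster-level control, matching per-feature reporting
conventions.

**Variance partitioning.** Commonality analysis on ranks: R² of every
nonempty regressor subset (≤ 4 regressors) by least squares, components by
inclusion–exclusion (`C(S) = (−1)^{|S|+1} Σ_{T⊆S} (−1)^{|T|} R²(all∖T)`).
Components sum to the full-model R² to 1e-10; negative shared components
(suppression) are legitimate and reported as-is.

**Noise ceiling.** Per timepoint, the upper bound is the mean over
subjects of Spearman(subject vector, grand-mean vector); the lower bound
leaves the subject out of the mean. With independent-noise subjects the
lower bound is ≈ 0 while the upper bound retains the √(1/S)
self-correlation of the mean — the bracket is informative only jointly.

## Synthetic data generator

The generator emulates the statistical shape of the recording the package
is designed around — 200 natural-object images at 80 trials each, 17
posterior channels, −100..300 ms epochs at 100 Hz (40 samples; onset on
sample 10) — at configurable size. It does **not** attempt biophysical
realism: noise is i.i.d. Gaussian per channel and sample (no 1/f spectrum,
no channel covariance), and no condition-identity patterns are injected by
default, so passing tests demonstrate correctness of the machinery under
the stated geometry, not performance on real recordings.

* **Latent features.** Size ratings log-uniform on [100, 423] (the span of
  actual mean ratings on the 0–519 scale); retinal sizes log-uniform on
  [50, 600] px, independent of size; depth exactly size/retinal. This
  reproduces the qualitative intercorrelation structure (all three
  positively related on average) that motivates partial-correlation RSA.
* **Trials.** Noiseless signal
  `s_c(ch, t) = Σ_f a_f g_f(t) u_f[ch] z_f(c)` with unit-peak Gaussian
  bumps `g_f` (center, SD in ms), fixed random unit channel vectors `u_f`,
  and z-scored latent values `z_f`. A single direction per feature scaled
  by the feature value makes the noiseless pattern distance proportional
  to `|Δz_f|` inside each window — exactly the geometry of an
  absolute-difference RDM, so injected structure is recoverable by
  construction. Default windows: depth 87 ms, retinal 138 ms, size 206 ms
  (SD 20 ms, amplitude 1.5 against noise SD 1.0 — pairwise decoding peaks
  well above chance without saturating). The injected latencies are config
  values chosen to make the recovery demonstration legible, not constants.
  Multi-subject datasets use independent seeds per subject over a shared
  condition set.
* **Model features.** `1 − Pearson` between zero-mean unit-norm rows
  equals `1 − ⟨x̂_i, x̂_j⟩`, so the generator realizes a chosen RDM
  exactly by designing the rows' Gram matrix: the noiseless cells are a
  *linear* combination of the weighted features' rank-transformed
  absolute-difference vectors, scaled to keep the Gram matrix positive
  definite, embedded in `100 × n_features` dimensions (comparable to
  pooled network layers / word embeddings) with i.i.d. Gaussian entry
  noise. Linearity in the controls' ranks matters: a curved monotone
  encoding of exact latent values would leak into *correlated* features
  under rank-linear partial correlation — in particular, exact retinal +
  depth encodings algebraically determine size (their product), a
  precision no realistic feature space has. Recipes: "early layer"
  (retinal + depth), "late layer" (size only), "semantic"
  (size amid heavy unrelated variance), and pure noise.

## Validation studies and problem sizes

`sizersa.validation` runs the package on its own generator at desk scale
(chosen as the smallest sizes at which every effect of interest is
unambiguous):

* **Latency recovery** — 20 seeds × (20 conditions, 80 trials/condition,
  17 channels, 40 samples, 3 pseudo-subjects); decoding with 2 repeats ×
  5 folds at the reduced epoch budget; 200 bootstrap resamples. Recovered
  group latencies order depth < retinal < size in 20/20 seeds with ~2 ms
  mean absolute error against the injected centers.
* **Error calibration** — cluster test: 500 pure-noise replicates
  (10 subjects × 40 timepoints, 200 permutations); shuffle test: 400
  replicates with fresh condition tables and pure-noise features.
* **Decoding sanity** — chance on exchangeable pairs (240 estimates),
  ≥ 0.95 on clusters separated by 6 SD, monotone accuracy across an
  injected-amplitude ladder (0–6).
* **Recipe pattern** — 100 seeds; encoded features flagged (early:
  retinal + depth; late: size). The *strict* pattern (additionally no
  false flag on non-encoded features) has an expected ceiling of
  (1−α)² ≈ 0.90 even for an exactly calibrated test, so it is reported
  (`early_strict_rate`, `late_strict_rate`, empirically ≈ 0.9) but not
  asserted.

## Known limitations

* Decoding accuracies at the reduced epoch budget are uniformly biased
  toward chance by up to ~0.03; use the default budget for absolute
  accuracy values.
* The shuffle-null model test is mildly anti-conservative (above); treat
  flags near the critical value with caution.
* The cluster permutation test requires enough subjects for the sign-flip
  null to resolve p < 0.05 (≥ 5 for a meaningful test).
* The generator's noise model is deliberately minimal; conclusions about
  real recordings require the real data.
* NPZ container bytes embed zip timestamps; the determinism contract is
  over array/table *contents* (manifest hashes), not container bytes.
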