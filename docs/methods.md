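# Methods

## Problem setting

A field spectrometer produces one mean reflectance spectrum per plant
sample — here 125 bands spanning 400–1000 nm — and an expert must assign a
species label. Labels are the expensive resource: imaging is cheap,
botanical annotation is not. The package addresses that asymmetry with a
three-stage pipeline: remove the physical nuisance variation (scatter and
band noise), compress the spectra to the low-dimensional manifold they
actually occupy, and spend a small labeling budget where the classifier is
least certain.

## Scatter model and correction

Field canopy spectra are distorted by surface geometry, plant height and
illumination into an approximately affine family: an observed spectrum is
`x = a + b·x_true + ε` with a per-sample offset `a`, a positive gain `b`,
and band-wise noise `ε`. Multiplicative scatter correction (MSC) estimates
`(a, b)` for each sample by ordinary least squares against a reference
spectrum and inverts the distortion as `(x − a)/b`.

Decisions:

* The reference is the per-band **mean of the fitting set**; held-out
  spectra are always corrected against the *training* reference, never
  their own mean, so preprocessing cannot leak test information.
* Correction of an affine-distorted noiseless spectrum is exact (the test
  suite requires agreement to 1e−10); applying the transform to its own
  fitting set and refitting returns slopes within 1e−6 of 1.
* A zero-variance reference or a fitted slope below 1e−12 raises rather
  than silently dividing; both indicate degenerate input.

Smoothing is a weighted running mean over a window of `2n + 1` bands.
Defaults: `n = 2` (five bands ≈ 24 nm at this resolution) with uniform
weights; triangular weights are selectable. At the spectrum edges the
window shrinks to the bands that exist and its weights are renormalized —
no reflectance is invented beyond the measured 400/1000 nm endpoints, and
constants are preserved everywhere. Uniform smoothing of unit-variance
i.i.d. noise leaves variance `1/(2n+1)`, which the tests verify by Monte
Carlo. No polynomial (Savitzky–Golay) fit is applied; the moving mean is
the entire smoothing model.

## Isomap reconstruction

The preprocessed spectra are embedded by the classical Isomap chain:

1. k-nearest-neighbor graph (default `k = 10`), symmetrized by union,
   Euclidean edge weights; equal distances break toward the smaller
   index, and duplicate points receive a 1e−12 edge-weight floor instead
   of forbidden zero weights.
2. All-pairs shortest-path distances `D_G` via Dijkstra per source
   (a Floyd–Warshall implementation exists in the tests as the oracle).
   A disconnected graph raises by default; the pipeline uses the optional
   `bridge` mode, which repeatedly joins the nearest pair of components
   by their shortest Euclidean edge — with 15 well-separated classes the
   neighborhood graph is otherwise frequently disconnected, and silent
   infinite distances would corrupt the MDS step.
3. Classical MDS: `B = −½ H D_G² H`, eigendecomposition, coordinates
   `Y = V_Z F_Z^{1/2}` with eigenvalues sorted descending and each
   eigenvector's largest-magnitude entry made positive (a deterministic
   sign convention). Negative eigenvalues — `D_G` need not be Euclidean —
   are clipped to zero for the coordinates and their count is reported.

**Component selection.** The retained dimension `Z` minimizes the
reconstruction RMSE, defined here as the root mean square over unordered
pairs of `D_G[i,j] − ‖Y_i − Y_j‖` using the first `Z` columns, scanned
over `Z = 1..20`. When the curve plateaus (exactly low-dimensional data),
the smallest `Z` within numerical tolerance of the minimum is taken. This
RMSE definition is a package decision — discrepancy between geodesic and
embedded distances is the quantity the embedding optimizes — and other
definitions would select differently.

**Out-of-sample extension.** New spectra never refit the manifold. A new
point's geodesic distance to every training point is the minimum over its
k nearest training neighbors `i` of `‖x − x_i‖ + D_G[i, ·]`; the squared
distances are projected on the stored eigenbasis (Nyström). Transforming
a training point reproduces its training coordinates exactly, which the
tests assert at 1e−6.

Sensitivity: `k` trades graph shortcuts (large `k`) against
disconnection (small `k`). On the synthetic benchmark the selected `Z`
typically lands between 10 and 20 and accuracy is flat over `k ∈ [8, 15]`;
`k` is exposed in the configuration.

## Second-order gradient boosting

The classifier is written from scratch so that every quantity is
inspectable and testable. The objective is a loss plus per-tree penalty
`Ω(f) = γT + ½λ‖w‖²`. Expanding the loss to second order around the
current prediction gives per-sample gradients `g` and Hessians `h`
(softmax cross-entropy: `g = p − 1[y=c]`, `h = p(1−p)`), the optimal leaf
weight `w* = −G/(H+λ)` for leaf sums `(G, H)`, the structure score
`−½ Σ G²/(H+λ) + γT`, and the split gain as its decrease. Splits are
found by exact greedy scan over sorted feature values (midpoint
thresholds, ties toward lower feature index then lower threshold) and are
kept only with positive gain and both children above the `min_child_weight`
Hessian floor. Multiclass training grows one tree per class per round on a
shared softmax; the raw-score prior is zero (uniform probabilities).

Defaults (160 rounds, depth 5, learning rate 0.1, `λ = 1`, `γ = 0`,
`min_child_weight = 1`, row and feature subsampling 0.6) describe the
study-scale protocol. Two practical notes:

* With softmax Hessians of order `p(1−p)` ≈ 0.06–0.25 per sample, a
  `min_child_weight` of 1 requires several samples per child; on
  few-sample toy problems it suppresses all splits, which is correct
  behavior but means toy tests relax the floor.
* The recorded training objective is the loss plus the penalty of the
  *shrunken* leaf contributions `η·w` actually added to the model; in
  full-sample mode it is non-increasing over rounds (asserted for 50
  rounds in the tests).

Row/feature subsampling draws from the ensemble seed only, so equal seeds
give bit-identical ensembles. A squared-error mode (unit Hessians) exists
for regression-style checks, and an adapter allows an external
gradient-boosting library as the active-learning base learner for
cross-checks; the from-scratch learner is the default and the test target.

## Active-learning protocol

From `n = 750` samples: a stratified 30% test split (largest-remainder
allocation, 225 samples), an initial labeled pool of 52 (~9.9% of the
remaining 525; one guaranteed sample per class, the rest uniform), and an
unlabeled pool of 473. Each of 5 iterations scores the pool with the
current model, moves the 12 most-uncertain samples (least confidence
`1 − max_c p_c`; ties toward the lowest index) with their hidden
ground-truth labels into the labeled set, refits, and evaluates on the
test split — never on pool samples. The final labeled set holds
52 + 60 = 112 samples. A budget of zero degenerates to passive learning
with a single evaluation. The batch size 12 is the budget divided evenly
over the iterations. The manifold is embedded once before the loop, not
refitted per iteration: refitting would change the representation under
the learner mid-protocol and would be far more expensive, at no observed
accuracy benefit on the benchmark.

Replicate runs use explicit per-run seeds derived from the global seed by
`SeedSequence`, so "mean over 5 runs" is exactly reproducible. An
optional label-flip rate simulates annotator error (default 0). The
comparison harness gives every method identical pools and total label
counts; passive baselines (random forest, decision tree) are trained on
the random-query run's final labeled set.

## Synthetic benchmark: what it does and does not emulate

The generator reproduces the *structure* of a grassland campaign: 15
classes × 50 samples, 125 bands on 400–1000 nm; smooth per-class profiles
sharing landmark positions (green bump 550 nm, chlorophyll trough 680 nm,
red edge 690–750 nm, NIR plateau, water dip 970 nm) with class-specific
amplitudes; per-sample affine scatter `a ~ N(0, 0.02)`,
`b ~ U(0.8, 1.2)`; band noise `ε ~ N(0, 0.01)`. Landmark amplitude ranges
were set once so that passive training with all 525 labels reaches ≥ 0.95
test accuracy — end-to-end accuracy assertions therefore test the
machinery, not a conveniently easy generator. Profile smoothness is
enforced by binomial smoothing in band space until the per-band first
difference is below 0.05, which keeps the invariant at any band count.

Not emulated: radiative-transfer leaf optics, wavelength-correlated noise,
mixed pixels, illumination drift across a campaign, or label noise.
Passing tests show the pipeline's algebra and protocol are correct and
that it succeeds on data matching its distortion model; they do not
certify field performance.

The affine scatter model is chosen deliberately: it is exactly the family
MSC inverts, which makes the correction testable analytically. On this
generator the scatter-corrected pipelines dominate raw spectra by a wide
margin (raw-spectrum active learning lands near 40% accuracy, corrected
pipelines above 90%), because the per-sample gain variation swamps the
class signal a tree learner can use.

## Known limitations

* **Batch uncertainty sampling can lose to random querying.** Least
  confidence with a 12-sample batch carries no diversity term. On most
  benchmark seeds it beats random querying by 1–3 accuracy points; on
  seeds where the generator happens to produce a nearly inseparable class
  pair, the entire budget concentrates there, other classes starve, and
  random querying wins by up to ~10 points. The averaged comparison in
  the acceptance script makes both numbers visible rather than hiding the
  variance.
* ENVI support is a minimal documented subset: BIL interleave, data types
  4 (float32) and 12 (uint16), header offset, optional wavelength block.
  No radiometric calibration, white-reference correction or
  georeferencing.
* Exact greedy split finding is quadratic-ish in samples × features and
  intended for datasets up to a few thousand rows; there is no histogram
  approximation.
* The Isomap `bridge` mode guarantees finite geodesics but the bridged
  distances between genuinely separate clusters are arbitrary up to the
  single connecting edge; with strongly clustered data the embedding
  between clusters should not be over-interpreted.

## Problem sizes used in the shipped runs

The acceptance script and the end-to-end tests run the full 750 × 125
benchmark but fit the boosted learner with 40 rounds rather than the
study-scale 160: on the 10–20-dimensional embedded representation the
accuracy curve is flat beyond roughly 30 rounds, and the shorter fit keeps
a full five-replicate, three-arm comparison around a minute on one CPU.
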