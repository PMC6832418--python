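# Methods

## Model

Each point of a cloud is described by the shape of its local
neighborhood at several scales.  A scale is the diameter *d* of a sphere
centred on the point; the neighborhood is every point within *d*/2
(the query point always belongs to its own neighborhood).  The
neighborhood covariance

Σ = (1/M) Σᵢ (pᵢ − p̄)(pᵢ − p̄)ᵀ

is normalized by the neighbor count M (a population covariance, not the
M−1 sample form), eigendecomposed, eigenvalues sorted descending and
clipped at zero against floating-point undershoot.  Five features per
scale: linearity L = (λ₁−λ₂)/λ₁, planarity PL = (λ₂−λ₃)/λ₁, sphericity
SPH = λ₃/λ₁, horizontality HOR = arccos(|v₃·ẑ|) in degrees, and PERCZ,
the 5th–95th percentile span of Z over a vertical column.  L, PL and SPH
are scale-free ratios on [0, 1] satisfying L + PL + SPH = 1 whenever
λ₁ > 0; HOR uses the *absolute* dot product so the arbitrary sign of the
eigenvector cannot flip 0° into 180°; both conventions are load-bearing
for the invariance tests (full feature vector invariant under
translation and rotation about ẑ; the three ratios under any rotation).

### PERCZ column

The "vertical column" is a cylinder of the same diameter as the PCA
sphere, unbounded in Z.  A cylinder (rather than a square prism) keeps
the one-parameter sphere-diameter convention; the same ladder is used
for the column as for the sphere.  Percentiles interpolate linearly
between order statistics (numpy's default); the 5–95 span rather than
the raw min–max range makes the feature robust to isolated outlier
returns — a single stray point 100 m above a 1 m column moves the value
by under 0.1 m.

### Degenerate neighborhoods

Neighborhoods with fewer than `min_neighbors` points (default 3 — the
minimum for a full-rank 3D covariance) or with λ₁ = 0 yield
L = PL = SPH = HOR = 0; PERCZ is always computed.  Zero vectors keep
isolated noise points finite and recognizable to the classifiers
instead of poisoning them with NaNs.

### Scale ladder

Default {0.05, 0.10, 0.20, 0.30, 0.40, 0.50} m: six rungs spanning
5 cm – 50 cm.  The endpoints bracket the object sizes the two scenarios
contain (branch thickness to trunk diameter; pole shafts to façade
patches); the intermediate rungs are an even spread and fully
configurable.  Units are metres throughout, Z up.

## Classifiers

The four families are deliberately classical, with configuration fixed
rather than searched: LDA (closed form); multinomial logistic regression
fit by plain maximum likelihood (regularization disabled — C = ∞);
RBF-SVM with γ = 0.01, C = 10 and the one-against-one decomposition
(C(C−1)/2 binary machines — the de-facto standard for kernel SVMs);
random forest of 50 trees, Gini criterion, bootstrap aggregation, nodes
grown without depth or leaf limits, scikit-learn's default
mtry = √(number of features).  Training data is balanced by drawing up
to `per_class` rows per class uniformly without replacement; prediction
never reweights.

No feature standardization is applied by default: the fixed SVM γ is
only meaningful relative to raw feature magnitudes (degrees for HOR,
metres for PERCZ, unit ratios for the rest), so scaling is an explicit
`standardize` switch applied identically at fit and predict rather than
a hidden preprocessing step.

## Evaluation

Per-class metrics are one-vs-all precision, recall and F1 read off the
confusion matrix (rows = reference), with 0/0 ratios defined as 0 so the
per-class table is always total.  Overall accuracy is the diagonal
fraction.  Kappa is Cohen's, with expected agreement from the product of
row and column marginals; the degenerate case p_e = 1 is defined as
kappa 0.  Train and test sets are spatially disjoint halves of the scene
along X, separated by a 0.5 m buffer strip (equal to the largest default
scale) so no test neighborhood touches training points.

Variable importance is the mean decrease in Gini impurity: every split
on feature j credits j with the drop in sample-fraction-weighted
impurity between the node and its children, impurity recomputed from the
node class counts as G = 1 − Σpᵢ²; credits are summed over all nodes of
all trees and divided by the number of trees.  Values are reported
unnormalized (they do not sum to 1).  Only the forest exposes this;
requesting it from another family is an error.

## Synthetic scenes

The generator emulates the *geometry* of the two target settings, not a
scanner.  Forest (default 20 m × 10 m, ≈49k points): a gently undulating
ground surface (superposed sinusoids, ≈10 cm relief), ten vertical
trunk cylinders (radius 0.10–0.20 m, height 5–7 m, points on the lateral
surface, as a scanner sees a stem), eight oblique thin branch segments
per tree on the upper stem (length 1.0–1.8 m, drooping 5–40° below
horizontal, 1.5 cm radial jitter).  Urban (default 40 m × 20 m): ground,
two 10 m façade planes, eight thin poles (4–8 m), six volumetric
vegetation blobs (uniform balls, radius 1–2 m), six car-like box slabs
(4 × 1.8 × 1.5 m, roof and sides).  Densities are per m² for surfaces,
per m³ for blobs, per metre for thin linear objects; all points receive
isotropic Gaussian noise of `noise_sd` = 1 cm by default, the order of
low-cost mobile/wearable scanner noise.  Objects are placed half in each
X-half so both split regions contain every class.  Generation is fully
deterministic given the recipe seed; a `density_scale` knob shrinks
scenes proportionally for fast tests.

What the scenes do **not** model: occlusion, beam divergence,
range-dependent density, registration drift, understory clutter, class
boundary ambiguity of real vegetation.  Passing tests on these scenes
demonstrates that the pipeline is implemented correctly and that the
features separate the intended geometric archetypes; they say nothing
quantitative about accuracy on real scanner data, which is typically
lower (real urban clouds are substantially harder than this synthetic
street).

## Numerical choices

- Eigendecomposition via symmetric `eigh` on batched 3×3 covariances;
  eigenvalues clipped at 0, sorted descending.
- The production extractor accumulates neighborhood moments with
  `np.add.reduceat` over flattened KD-tree neighbor lists, chunked
  (20k points per block) to bound memory; the test suite checks it
  cell-for-cell at 1e-9 against a naive O(N²) reference and checks that
  chunking is invisible.
- Percentiles: linear interpolation (documented because the exact
  choice moves the PERCZ reference example at the third decimal).
- Ties in the importance ranking are broken by a stable sort, so equal
  importances keep ladder order.
- Determinism: one seed drives scene generation, balanced sampling and
  the forest bootstrap; rerunning the pipeline with the same config
  reproduces the evaluation report byte for byte.

## Problem sizes used in the acceptance suite

The end-to-end checks run the default ≈49k-point forest scene with a
1000-per-class training sample; the multiscale-vs-single-scale
comparison repeats it across three seeds, reusing the full ladder's
feature columns for the single-scale fits (a single scale's features
are exactly a column subset).  The reproducibility check uses a
`density_scale` 0.1 scene, where bit-identity is equally meaningful.

## Known limitations

- O(N·k) neighbor gathering keeps ~50k-point scenes interactive, but
  multi-million-point clouds need tiling or subsampling upstream; no
  out-of-core path is provided.
- The SVM exposes no probabilities (no Platt calibration by design).
- LAS/LAZ input is not implemented; convert to XYZ or PLY first.
- Kappa follows Cohen's marginal-product chance model; other chance
  models would shift absolute kappa values slightly.
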