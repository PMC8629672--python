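# Methods

## The model

`fwnnet` implements a fuzzy wavelet neural network (FWNNet): a first-order
Takagi–Sugeno–Kang (TSK) fuzzy system whose rule consequents are wavelet
networks.  For an input vector x ∈ ℝⁿ and M rules, rule k carries

* Gaussian antecedent memberships μ_kj = exp(−((x_j − c_kj)/σ_kj)²) — note
  the exponent has **no** ½ factor; this convention is used consistently by
  the membership functions, the histogram model, and the phantom generator;
* a firing strength O_k = Π_j μ_kj (product t-norm);
* a consequent Y_k = Σ_{i=1..N_k} w_ik Ψ_ik + ȳ_k, where
  Ψ_ik = Π_j ψ((x_j − b_ijk)/a_ijk) is a product of dilated/translated
  copies of a mother wavelet ψ.

The crisp output is the firing-strength-weighted mean
y = Σ_k O_k Y_k / Σ_k O_k; in classification mode an eighth layer rounds y
half-away-from-zero and clamps it to the label range 0..C−1.  The trainable
set is Θ = {c_kj, σ_kj, b_ijk, a_ijk, w_ik, ȳ_k}.

Two mother wavelets ship: the Mexican hat ψ(x) = (1 − x²)e^(−x²/2)
(default) and the real Morlet ψ(x) = cos(5x)e^(−x²/2).  Both satisfy the
admissibility condition C_ψ = ∫|ψ̂(ω)|/ω dω < ∞, which
`check_admissibility` verifies numerically (quadrature of the Fourier
transform on a wide log-frequency grid; a non-vanishing ψ̂(0) flags
divergence).  The |a|^(−1/2) normalization prefactor is optional
(`normalize_wavelet`); the default is the bare form.

## Numerical floors and degenerate inputs

* Membership widths are projected to σ ≥ 1e−3 during training.
* Dilations are projected to |a| ≥ 1e−3 with their sign preserved (an
  update crossing zero keeps its post-update sign, or the pre-update sign
  if it lands exactly on zero).
* The defuzzification denominator Σ_k O_k has a floor of 1e−12; below it no
  rule fires, the output is undefined, and `DegenerateInputError` is
  raised.  During swarm search, particles producing degenerate outputs are
  scored +∞ rather than erroring.
* Rounding ties go half-away-from-zero before clamping.  These defaults are
  the package's own choices where the underlying conventions are ambiguous.

## Hybrid training

Training minimizes E = ½(y_true − y)² per sample (dataset RMSE is
reported).  It proceeds in two stages:

1. **PSO initialization.**  A global-best particle swarm (psize = 20,
   maxgen = 50, c1 = c2 = 2, inertia decreasing linearly 0.9 → 0.4,
   velocities clamped to half the box width) searches a data-driven box:
   centers and translations span the observed feature range, widths and
   dilations span (floor, range], and consequent weights/biases a symmetric
   interval wide enough to reach the target range.  Two modes exist:
   `plain_pso` moves the full concatenated Θ at once; `inline_pso`
   (default) moves one parameter block at a time — (c, σ), then (b, a),
   then (w, ȳ) — within every generation.  The blockwise variant is this
   package's concrete reading of a two-stage, coordinate-grouped swarm
   initialization; both are selectable and the global-best fitness is
   non-increasing by construction in either.
2. **Gradient descent.**  Exact chain-rule gradients of E through all
   layers, one learning rate per parameter group (default 0.01, full-batch;
   an online mode is available).  Gradients are validated against central
   finite differences in the test suite (rel. tol 1e−5).

**Feature standardization.**  `hybrid_train` z-scores the features
internally and maps the fitted parameters back to raw units on return.
The mapping is exact because every parameter enters through (x − ·)/(·)
forms: c, b → mean + scale·(c, b) and σ, a → scale·σ, scale·a (with the
|a|^(−1/2) prefactor enabled, the constant Π_j scale_j^(−1/2) is absorbed
into the weights).  Without this, gradient steps on intensity-scale
features (tens to hundreds) are numerically frozen at any sensible
learning rate.

**Classifier wrapper.**  `train_classifier` trains against the numeric
labels 0..C−1 directly (learning rate 0.05, up to 4000 epochs), stops as
soon as every training sample rounds to its own label, and — if it does
not get there — restarts the whole hybrid run from a deterministically
shifted swarm seed (up to 3 attempts), keeping the best attempt.  The
default architecture for the 4-feature classification task is M = 2 rules
with N_k = 4 wavelet neurons.

## Histogram features

Each image's normalized 256-bin histogram is modeled as
h(v) ≈ Σ_{g=1..4} A_g exp(−((v − m_g)/s_g)²), fitted by bounded
least squares (`scipy.optimize.least_squares`, trf) from 5 starts — the
first places the means at the weighted 12.5/37.5/62.5/87.5% quantiles of
the histogram, the rest jitter means and widths from the seeded generator.
Bounds: A ∈ [0, 2·max density], m ∈ [0, 255], s ∈ [1, 128].  Modes are
sorted by mean, making the feature vector invariant to mode relabeling.
The default per-image feature vector is the 4 sorted means (modes
`amplitudes` and `all12` are alternatives); which four numbers constitute
the features is a package choice, since histogram shape is most
discriminative through the mode locations.

An eigenface-style reduction (`eigen_reduce`) is provided as an
independent, composable step: images are vectorized, centered on their
mean, and the covariance eigenproblem is solved in the image-count-sized
Gram space before mapping eigenvectors back to pixel space.  It is not on
the default classification path.

## Synthetic phantoms

The generator emulates 8-bit grayscale MRI-like images whose histograms
are four-Gaussian mixtures:

* base mode means (40, 100, 160, 220), widths s = 12 (sampling sd
  s/√2 ≈ 8.5), mixture weights (0.35, 0.30, 0.20, 0.15);
* class c ∈ {0..3} shifts all mode means by +10·c intensity units, the
  separation that makes histogram features class-discriminative;
* an optional elliptical "tumor" of smooth intensity (default ≈ 200, noise
  sd 6) is stamped in, with a {0, 255} ground-truth mask; random tumors
  have semi-axes 8–20% of the image side;
* `generate_class_dataset(mode="features")` emits the four mode means plus
  N(0, 2.0) jitter directly — the jitter magnitude matches the ≤2%
  mean-recovery error of the histogram fitter, so feature-mode data behave
  like extracted features without rendering 2000 images.

What the phantoms do **not** model: anatomy, bias fields, Rician noise,
partial-volume effects, spatially correlated tissue texture.  Passing
tests therefore demonstrate that the algorithmic pipeline is correct and
can solve a separable task at the full study size — not that the method
reaches any particular accuracy on clinical MRI.

## Supervised segmentation

1. The image is transformed by an oriented Gabor bank (default 0°, 45°,
   90°, 135°, wavelength 8 px at the nominal 256-px image scale, octave
   bandwidth 1, magnitude responses aggregated by max and rescaled to
   [0, 1]).  On the phantoms this is the discriminative step: background
   tissue is a per-pixel mixture draw (high local contrast, strong Gabor
   energy) while tumor tissue is smooth (weak energy).
2. Every m×m mask patch (default m = 4, stride m, row-major) is paired
   with the co-centered 2m×2m window of the transformed image; windows
   beyond the border use reflect padding (zero padding available).  With
   stride = m the mask-side pairing is exactly invertible, which the tests
   check bit-exactly.
3. A single FWNNet in regression mode (shared across patch pixels, with
   the normalized (row, col) pixel offset appended to the input; a
   per-pixel-network mode is available) is hybrid-trained on (window,
   mask-pixel) pairs.  Training rows are capped at 6000 (seeded
   subsample), and the swarm objective uses a further 2000-row subsample;
   gradient descent (300 epochs, rate 0.05) runs on the full capped set.
   Because the product t-norm multiplies n ≈ (2m)² membership values, the
   swarm's width/dilation box is scaled to (0.5√n, 1.5√n) in standardized
   units — narrower widths underflow every rule's firing strength.
4. At inference the per-patch predictions are averaged into a
   full-resolution score map in [0, 1] and thresholded at 0.5 into a
   {0, 255} mask.  Evaluation is pixel-level ROC/AUC, per image and pooled,
   plus Dice overlap.

## Problem sizes and scale choices

The package's reference experiments (test suite and
`scripts/acceptance.py`) use: 2000 feature vectors (500 per class) for
classification; 20 phantoms of 128×128 px (train 15 / test 5) with
Gabor wavelength 4 px for segmentation; one 256×256 phantom for the
histogram round trip.  The segmentation phantoms are scaled down from the
nominal 256-px image side with all method length scales (wavelength,
patch size) scaled along, keeping tumors at the same relative size; at
64 px the smallest tumors approach the Gabor envelope width and pixel-level
AUC degrades for scale reasons rather than method reasons, so 128 px is
the smallest faithful size.

## Known limitations

* The compact architecture (few rules, few wavelet neurons) has low
  capacity; on tasks that are not low-dimensional and near-separable it
  underfits, and the blockwise swarm with a 6000-row cap is a search
  heuristic, not a convergence guarantee.
* Gradient descent on the defuzzified output can stall when rules split
  responsibility for a shared bias (the per-rule effective rate is scaled
  by the squared responsibility); the swarm initialization mitigates but
  does not remove this.
* The Gabor front end assumes texture contrast between tumor and
  background; tumors textured like their surroundings are invisible to it.
* Baseline classifiers (DT, KNN, LDA, NB, MLP, SVM) are scikit-learn
  estimators with library defaults behind a `StandardScaler`; they are a
  comparison harness, not tuned competitors.
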