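# Methods

This note documents the models, numerical choices and open design
decisions behind nodulewalk, and what the synthetic phantom study does
and does not demonstrate.

## Anisotropic diffusion

The denoiser integrates the Perona-Malik PDE with the explicit
4-neighbour scheme: per step, `I ← I + λ Σ_d c(|g_d|) g_d` over the four
one-sided differences `g_d`, replicate boundaries (zero boundary flux).
Because every inter-pixel flux appears with opposite signs in the two
pixels it joins, the total intensity is conserved exactly (up to
roundoff), and for `λ ≤ 1/4` the update is a convex combination of
neighbours, so no new extrema appear. The output is clipped to [0, 1]
once at the end rather than rescaled, preserving intensity semantics for
the downstream co-occurrence quantisation.

Defaults: exponential conduction, `κ = 0.1` (intensity units on [0, 1] —
gradients well below κ diffuse, well above are kept), `λ = 0.2`, 15
iterations. On phantom noise (σ = 0.05–0.1) this reduces background
variance by well over half while the nodule step (contrast ≈ 0.45)
retains ≥ 80 % of its gradient.

## LBP codes

Each pixel's 8-bit code sets bit k iff neighbour k (clockwise from the
top-left of the 3×3 window) is ≥ the centre. Ties count as 1, so flat
regions code 255 deterministically. Only differences between codes are
consumed downstream, making the bit order a pure convention; it is fixed
and documented for reproducibility. The map uses replicate padding so it
aligns pixelwise with the segmentation lattice. Uniform/rotation-
invariant and multi-radius variants are deliberately out of scope.

## Random-walker segmentation

The Dirichlet problem is assembled on the 4-connected lattice with the
weights given in the README. Design choices:

- **Weight floor** `ε = 1e−6` keeps the graph connected and the reduced
  Laplacian symmetric positive definite; the solver is sparse LU up to
  256×256 pixels (exact at test scale) and Jacobi-preconditioned
  conjugate gradients at relative tolerance 1e−8 above.
- **Defaults** `β = 90` (on [0, 1] intensities), `γ = 2`, threshold 0.5,
  closing disc radius 2. All exposed in `RWParams`.
- **Two labels only** (nodule / background), matching the semi-automatic
  two-seed workflow; multi-label generalisation is out of scope.
- **Post-processing** closes with a disc, fills holes and keeps the
  largest 4-connected component. An empty thresholded field is returned
  as an empty mask with a warning so batch studies can skip the sample.

`auto_seeds` derives seeds from a ground-truth mask for unattended
phantom runs: the foreground seed is a radius-3 disc about the mask
centroid (clipped to the mask, with a nearest-pixel fallback for
non-convex masks), background seeds are border pixels at distance ≥ 12
from the mask. A *disc* rather than the centroid pixel alone: a single
Dirichlet anchor competing against hundreds of border seeds cannot hold
the interior potential once the boundary leaks slightly, and the
segmentation can collapse to the seed pixel; a small disc removes that
fragility for both weight schemes symmetrically. For file inputs, seeds
come from a user CSV (row, col, label).

### What the texture term does on these phantoms — honestly

The phantom's two regions differ in intensity only, so LBP codes inside
nodule and background are both noise-driven: the normalised Hamming
distance between adjacent codes is ≈ 0.2 inside homogeneous regions and
not reliably larger across the margin (two pixels straddling a clean
step see the same edge structure and code alike). The texture term
therefore carries no discriminative signal here, and RWI reproduces RW's
mask up to a few boundary pixels: across repeated 50-phantom runs the
paired median Dice difference is exactly 0 and the mean difference is
below 1e−4 in magnitude with unstable sign. Passing segmentation tests
on these phantoms shows the solver and the weight plumbing are correct;
it does **not** demonstrate a texture-driven improvement, which requires
images whose regions differ in texture (as real parenchyma and nodules
do), not merely in level.

## Features

- **Shape (13)** from the mask only, via moment-based region properties:
  area and convex area as pixel counts (solidity their exact ratio),
  ellipse-moment orientation/eccentricity/axis lengths, 8-connectivity
  Euler number, contour-weighted perimeter estimator. Centroid and the
  8 extremal boundary points are vector-valued; they are reduced to
  scalars (mean of coordinates) so the vector has one number per name.
- **GLCM (7)**: intensities inside the region are quantised to 8 equal
  bins over the region's min-max range; pairs are counted at distance 1
  in four directions, symmetrically, only when both pixels are in the
  mask (the reason for a hand-rolled co-occurrence count rather than a
  whole-image library call), and normalised to sum 1. Entropy uses the
  natural log. All settings configurable.
- **Intensity (8)** on the LL subband of a single-level orthonormal Haar
  transform of the region's bounding box (symmetric padding; a constant
  region of value v maps to 2v); the mask is downsampled by a 2×2 "any"
  rule. Statistics are population moments; kurtosis is non-excess
  (Gaussian → 3). IDM is the homogeneity statistic of a GLCM built on
  the subband region itself; note the normalised form is bounded by 1.
  A config flag computes the intensity block on the raw region instead,
  since the subband-vs-raw choice is genuinely open.

## Classifiers and evaluation

Random forest: 100 trees, √d feature subsampling, raw features (trees
are scale-invariant). ANN: one hidden layer of 16 logistic units,
trained on z-scored features whose mean/std come from the training split
only — the cross-validation harness fits one model per fold, so no
statistic ever sees held-out data. Stratified 5-fold CV is the default;
pooled confusion counts (which partition the dataset exactly) feed the
metric suite. Fixed seeds make every fit reproducible.

## Metrics

All ratios are computed from the 2×2 counts; `error`, `fpr` and `fnr`
are defined as exact complements (100 − accuracy, 100 − specificity,
100 − sensitivity) so the complementarity identities hold in floating
point. Two false-rate conventions exist in the literature this package
tracks: the standard `FP/(FP+TN)` (reported as `fpr`) and a variant
normalising by the total number of correct decisions, `FP/(TP+TN)`
(reported as `fpr_alt`); both are always emitted so neither can be
silently conflated. Overlap is the pixel Jaccard `TP/(TP+FP+FN)`; MCC
and Cohen's kappa use their standard 2×2 forms and are reported as
ratios. Zero-denominator cases yield NaN plus an entry in the report's
`degenerate` list rather than an exception.

## Phantom generator: what it emulates, what it does not

Each sample emulates a CT slice cropped around a nodule: homogeneous
parenchyma (level ~0.15–0.25), brighter nodule (~0.60–0.70), additive
Gaussian noise (σ = 0.05 by default, 0.1 in the noisy-segmentation
study), margin `r(θ) = R(1 + a sin(kθ + φ))` with radius 12–22 px,
6–11 lobes, and class boundary at amplitude 0.15 (benign draws from
[0, 0.10], malignant from [0.25, 0.45] — disjoint by construction).
Masks are guaranteed single 4-connected components without holes.

Not emulated: vessels, ribs and other clutter; Hounsfield calibration;
texture differences between nodule and parenchyma; partial-volume and
reconstruction effects; 3-D context. Consequently the classification
task is driven almost entirely by margin shape (solidity alone separates
the classes with AUC > 0.9), and near-perfect cross-validated accuracy
on phantoms demonstrates that the pipeline's plumbing — segmentation
fidelity, feature computation, leakage-free evaluation — is sound, not
that comparable accuracy would be reached on clinical CT.

## Problem sizes

The default study uses 200 phantoms at 128×128 with 5-fold CV; the
paired RW-vs-RWI comparison uses 50 phantoms at noise σ = 0.1; the
Monte-Carlo solver check uses 200 000 walks on an 8×8 lattice. These
sizes give stable statistics (binomial standard error on a 200-sample
accuracy ≈ 1–3 points; Monte-Carlo error per pixel < 0.01) while a full
run of suite plus study completes in a couple of minutes on one CPU.

## Known limitations

- Per-slice 2-D only; no volumetric features or 3-D connectivity.
- The LBP-Hamming texture term is the simplest reading of
  intensity+texture weight fusion; patch-histogram distances would be
  more noise-robust and are a natural extension (see the discussion of
  the texture term above).
- GLCM quantisation over the region's own min-max range makes texture
  features contrast-normalised but sensitive to outlier pixels.
- The spiculation phantom is star-shaped by construction; real
  spiculation is branching and partly tangential.
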