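# nodulewalk

Seeded random-walker segmentation and benign/malignant classification of
pulmonary nodules in 2-D CT slices, with an *improved* weight scheme that
fuses image intensity with local-binary-pattern (LBP) texture, a
28-feature shape/texture/intensity bank, and random-forest / neural-
network classifiers. A built-in synthetic nodule-phantom generator makes
every stage testable end to end without any clinical data.

## Who this is for

Researchers in medical image analysis who want a reproducible, inspectable
reference implementation of the classic semi-automatic nodule pipeline —
denoise, segment from seeds, extract hand-crafted features, classify —
rather than a clinical tool. All inputs are ordinary 2-D grayscale images
(PNG/JPEG/TIFF, optional single-slice DICOM); nothing here is 3-D.

## The model

**Denoising.** Perona-Malik anisotropic diffusion
`∂I/∂t = div(c(|∇I|) ∇I)` with an edge-stopping conduction
`c(s) = exp(−(s/κ)²)` (or `1/(1+(s/κ)²)`), discretised as the explicit
4-neighbour flux-form scheme with replicate boundaries. Homogeneous noise
is averaged away while nodule margins keep their gradient.

**Segmentation.** Each pixel is a node of the 4-connected lattice; edge
(i, j) carries a weight

    RW:   w_ij = exp(−β (g_i − g_j)²) + ε
    RWI:  w_ij = exp(−β (g_i − g_j)² − γ h_ij) + ε

where `g` are intensities in [0, 1] and `h_ij ∈ [0, 1]` is the Hamming
distance between the two pixels' 8-bit LBP codes divided by 8. The
probability that a random walk from pixel i reaches a nodule seed before
a background seed solves the combinatorial Dirichlet problem
`L_U p_U = −Bᵀ m` on the graph Laplacian (foreground seeds held at 1,
background at 0). Thresholding at 0.5, disc closing, hole filling and
largest-component selection yield the mask. `γ = 0` reduces RWI to RW
exactly.

**Features.** Per segmented nodule, 28 numbers: 13 shape descriptors of
the mask (area, solidity, eccentricity, Euler number, …), 7 Haralick-type
statistics of the grey-level co-occurrence matrix restricted to the
region (contrast, entropy, energy, cluster shade/prominence, …), and 8
moment statistics of the region on the LL subband of a single-level Haar
wavelet transform (mean, variance, skewness, kurtosis, IDM, …).

**Classification.** A 100-tree random forest (raw features) or a
16-hidden-unit perceptron (z-scored features, training-split statistics
only), evaluated by stratified 5-fold cross-validation; pooled confusion
counts feed a metric suite (accuracy, sensitivity, specificity,
precision, F1, both false-rate conventions, Jaccard overlap, Matthews
correlation, Cohen's kappa).

**Phantoms.** A synthetic slice is a dark parenchyma field with a brighter
nodule whose margin is `r(θ) = R (1 + a sin(kθ + φ))` plus Gaussian noise:
`a ≈ 0` gives a smooth benign-style nodule, large `a` a spiculated
malignant-style one — the shape cue the feature bank targets.

## Worked example

```python
import nodulewalk as nw

# a noisy spiculated phantom with ground truth
sample = nw.generate_phantom(nw.PhantomSpec(
    noise_sigma=0.1, spiculation_amplitude=0.4, rng_seed=3))

den   = nw.anisotropic_diffusion(sample.image)       # denoise
codes = nw.lbp_map(den)                              # texture codes
seeds = nw.auto_seeds(sample.mask)                   # seeds from truth
prob, seg = nw.segment(den, seeds, method="rwi", lbp_codes=codes)

print(f"Dice vs truth: {nw.dice(seg.mask, sample.mask):.4f}")
vec = nw.extract_features(den, seg.mask)
print(f"{len(vec)} features; solidity = {vec['solidity']:.4f}")
```

prints

```
Dice vs truth: 0.9735
28 features; solidity = 0.6334
```

— the segmentation recovers 97 % of the spiculated margin, and the low
solidity (area / convex area ≈ 0.63) is exactly the irregular-margin
signal the classifier keys on (a smooth nodule scores ≈ 0.95+).

The same thing from the shell:

```bash
nodulewalk demo --n 200 --seed 7          # full study, prints metrics JSON
nodulewalk phantom generate --n 20 --out-dir phantoms/
nodulewalk segment slice.png --seeds seeds.csv --method rwi --out mask.png
```

`nodulewalk demo` runs 200 phantoms through diffusion → RWI → features →
random-forest 5-fold CV and reports pooled accuracy (≈ 100 % on the
default phantom family, whose classes are separable by margin shape) and
the mean Dice of the segmentations against ground truth (≈ 0.99).

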