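# Methods

## Scope and data model

The package operates on 2D images and 3D stacks (PNG, single/multi-page
TIFF) holding non-negative real intensities.  Coordinates are 0-based
(x, y, z) voxel indices; arrays are stored (z, y, x).  Multi-channel
images are reduced at load time to one channel ("all" averages RGB, or a
named/indexed channel is selected — e.g. the green/GFP channel of
fluorescent stains).  Integer intensities are kept bit-exact; extractors
define their own normalisation.

Training labels attach to images in three ways: a whitespace-separated
target file (`image-name label [label ...]`, multi-label allowed), a
directory tree with one subdirectory per class, or ROI mode where ImageJ
ROI zip / Vaa3D marker files over one image carry labelled points and the
file base name is the class (`pos.zip` -> class `pos`).  Vaa3D marker
coordinates are 1-based and shifted by -1 on read (+1 on write); ImageJ
ROI coordinates are already 0-based; area ROIs (rectangle, oval) are
reduced to their integer centres.

## Algorithm chains and evaluation

A chain = ordered extractor list + optional selector cascade + one
classifier.  Extractor outputs are concatenated per sample (combined
dimensionality = sum of parts); output length of every extractor is a
function of its configuration only, never of image content, and the
plugin registry enforces this contract on first use.  Samples are
featurized sequentially, one image resident at a time.

Evaluation is stratified k-fold cross-validation repeated with
reshuffling: defaults 5 folds, 5 repeats, 25 runs.  Each repeat derives
its shuffle seed from the protocol seed via `SeedSequence([seed, repeat])`,
so a fixed protocol yields identical fold assignments for every chain —
comparisons are paired, and the per-run test-fold membership hashes are
recorded to prove it.  Reported variance is the population variance over
the runs (N, not N-1).  Selectors are fitted inside each training fold
only; a dedicated test injects label-valued columns into held-out rows to
verify nothing fitted ever sees them.  Ranking is by mean accuracy
descending, ties broken toward fewer post-selection features (compact
models preferred), then chain order.  Only user-listed chains are
compared; there is no exhaustive search, so the winner is best among the
candidates, not globally optimal.

If the smallest class has fewer members than the requested folds, the
fold count is clamped to that size (minimum 2) with a warning.

## The anisotropic wavelet feature

For a voxel of interest, the (2rx+1) x (2ry+1) x (2rz+1) patch is
collapsed along z with Gaussian weights w(zi) ∝ exp(-zi²/(2σ²)),
σ = max(rz, 1)/2 by default and exposed as a parameter, renormalised to
sum 1; the collapsed plane is then decomposed by a multi-level 2D Haar
DWT and all coefficients are returned, flattened coarsest-LL first, then
per level (coarsest to finest) the LH, HL, HH blocks.  Numerical fixed
points:

* orthonormal filters (1/√2): total coefficient energy equals pixel
  energy for power-of-two inputs, which gives a clean oracle;
* detail = (first − second)/√2 per sample pair;
* odd side lengths are edge-replicated on the high side to the next even
  size at every level.  Replication (rather than zero padding) keeps a
  constant patch constant, so flat image regions have exactly zero detail
  coefficients;
* out-of-bounds *patch* voxels at volume borders are zero-filled —
  fluorescence backgrounds are dark, and it keeps "every voxel is
  annotated" literally true at interval 1;
* feature count = padded patch area, independent of rz (quadratic, not
  cubic, in the patch side — the reason the z axis is collapsed rather
  than transformed).

Because Σw = 1, a z-constant volume yields identical features for every
rz; and by linearity, collapsing-then-transforming equals per-slice
transforms summed with the same weights (both are asserted in tests).

Whole-image (variable-size) wavelet features use per-subband mean and
standard deviation of absolute coefficients, length 2·(3·levels + 1);
fixed-size ROIs may use the raw coefficient vector.  Both poolings are
config fields.

## Moment and object features

Hu 2D: the seven classical invariants from intensity-weighted,
scale-normalised central moments η_pq = μ_pq/μ00^(1+(p+q)/2), plus the
known eighth skew invariant
I8 = η11[(η30+η12)² − (η03+η21)²] − (η20−η02)(η30+η12)(η03+η21).
Moments are computed on raw intensities, not binarised masks.

Hu 3D (8 values, documented in the code): the three second-order rotation
invariants J1 (trace), J2 (sum of principal 2x2 minors), J3 (determinant)
of the normalised second-moment tensor, plus five squared-sum groups of
the scale-normalised third-order central moments (pure terms, mixed
terms, η111², and the two contracted-vector norms).  All are translation
invariant by construction and scale-normalised via
η_pqr = μ_pqr/μ000^(1+(p+q+r)/3); only J1–J3 are rotation invariant.  The
exact historical 8-value set is not published anywhere we could verify,
so this fixed, tested set honours the stated count and invariances.

Zernike: magnitudes |A_nm| for (n, m) enumerated n ascending, m ≥ 0,
n−|m| even, m ascending within n — the first 20 pairs end at n = 7.  The
image is mapped onto the unit disk centred on its intensity centroid with
radius the largest centroid-to-corner distance, and moments are
mass-normalised, so magnitudes are rotation invariant and unitless.

Object features threshold the image (Otsu by default, parameter-free;
fixed threshold available) and label components under full connectivity
(8 in 2D, 26 in 3D).  The 7 object statistics are, in order: count, mean
and (population) variance of component sizes, mean and variance of
component-centroid distances to the image's intensity centre of mass, the
largest/smallest size ratio, and the furthest/closest distance ratio.
Component centroids are binary, the image reference point is
intensity-weighted, distances are Euclidean in voxel units (anisotropy
ignored).  Territory is the total foreground voxel count.  An image with
no foreground yields an all-zero statistics vector with a warning.

Differential features per Gaussian scale: first derivatives, Laplacian
and Hessian eigenvalues (sorted descending), pooled either as map
mean/std (whole images) or sampled at a coordinate (ROIs).  Gaussian
kernels are truncated at 6σ so that second-derivative kernels sum to ~0
and constant images give numerically zero features.

## Selection and classification

Fisher score per column: Σ_c p_c(μ_cj − μ_j)² / (Σ_c p_c s²_cj + ε) with
ε = 1e-12, so zero-within-variance columns rank top without division by
zero.  Top-N selection keeps original column order, ties to the lower
index; cascaded selectors re-score on each stage's output and compose
their index maps back to original provenance.

Classifiers: kNN (default k = 3) is implemented in-package because its
tie-break is part of the contract — on a vote tie, the label of the
single nearest neighbour among the tied classes wins; distance is
Euclidean on unscaled features.  Linear SVM (C = 1), Gaussian naive
Bayes, decision tree and random forest (100 trees) are scikit-learn
estimators behind the module's contract (closed kind set, defaults,
determinism under the spec seed, column-provenance checks at predict
time).

## Annotation and counting

Sliding-window annotation classifies the model's patch at every lattice
site ({0, s, 2s, ...} per axis for interval s); interval 1 annotates
every voxel.  Border sites use zero-padded patches rather than being
skipped.  For mostly-dark stacks, decisions can be restricted to local
intensity maxima: voxels whose value equals the grayscale dilation of the
image under a cubic structuring element (radius 1 by default) and exceeds
an intensity floor (Otsu by default).  A connected equal-valued plateau
of maxima is reported once, at its lexicographically smallest (x, y, z).

Counting mean-shifts each positively classified site to the
intensity-weighted centroid of its spherical neighbourhood (window radius
defaults to the merge radius) until displacement < 0.5 voxel or 50
iterations, then merges converged points by single linkage at the merge
radius; each cluster reports one intensity-weighted centre, and the count
is the cluster count.  The convergence constants are fixed and exposed as
parameters.

Multi-label annotation runs one binary present/absent model per label
over whole-image features; an image's label set is the union of positive
predictions, and the consolidated report lists every image, including
those with an empty set.

Models persist as single versioned archive files; loading a truncated or
alien file raises a format error, and a reloaded model reproduces the
original's predictions bit-for-bit.  ROI-trained models record their
patch geometry and refuse annotation with a different one.

## Synthetic data

The generators are first-class, deterministic (seeded) code whose outputs
are written in the real external formats so the IO paths are exercised.

* Blob volumes (64 x 64 x 24 by default): 20 anisotropic Gaussian blobs,
  x-y spread 2.5 voxels vs z spread 1.5 (emulating the axial/lateral
  resolution disparity of confocal stacks of labelled nuclei), peak 200
  over folded-normal noise of σ 5, centres ≥ 12 voxels apart (≥ 4σ keeps
  neighbours resolvable) and ≥ 3σ from the x-y borders.  Ground-truth
  centres are returned and written as Vaa3D markers.
* Texture sets: two classes of sinusoid gratings, 2 vs 16 cycles per
  32-pixel image for the "easy" preset at noise σ 0.02 with one fixed
  grating per class (phase drawn once from the seed), so intra-class
  variation is pixel noise only.  That construction is what guarantees —
  and generation-time assertion enforces — an inter-class Haar-statistic
  distance above 10x the intra-class spread, which in turn forces perfect
  cross-validated accuracy for any reasonable chain.  The "hard" preset
  (6 vs 9 cycles, random orientation and phase, noise σ 0.25) removes
  those guarantees.
* Tube images: a Gaussian-profile bright ridge at a chosen orientation,
  the minimal axon-like fixture for Hessian-feature checks.

What the generators do *not* emulate: realistic point-spread functions
beyond axial anisotropy, intensity falloff with depth, blob shape and
brightness heterogeneity, touching/overlapping objects, and uneven
background.  Perfect scores on the easy fixtures therefore demonstrate
pipeline correctness (wiring, no leakage, determinism), not expected
performance on real microscope data, where crowded and blurry objects
make both classification and counting substantially harder.

## Problem sizes

Default test and acceptance runs use 20-image texture sets (32 x 32), one
64 x 64 x 24 training volume with 100 labelled ROIs (7 x 7 x 5 patches,
rz = 2) and one held-out volume with 20 blobs.  These sizes were chosen
so the complete pipeline — generation, featurization, 25-run
cross-validation per chain, annotation and counting — is exercised end to
end in seconds while every guarantee stated above remains assertable.

## Known limitations

* ROI mode reduces ImageJ area ROIs to centre points; masks are not used.
* No image preprocessing (denoising, registration, enhancement) — that is
  delegated to upstream tools, which can also supply the ROI files.
* No Haralick/Gabor/Chebyshev texture families; the extractor inventory
  is the one listed above plus user plugins.
* Feature scaling before kNN/SVM is off by default; the classifier spec's
  `zscale` flag enables per-column standardisation (fitted on training
  rows only) for parity experiments.
* The CLI's classify command assumes a directory of readable images; OME
  metadata and proprietary microscope formats are out of scope.
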