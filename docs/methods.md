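# Methods

This note documents the model implemented by `beaverid`, the parameter
defaults, the synthetic benchmark, and the numerical choices and limitations
a user should know about.

## Model and assumptions

The tail scale mosaic is treated as a rigid, persistent texture: views of the
same animal differ by an approximately affine viewpoint change (rotation,
moderate scale), illumination changes, blur and sensor noise, but not by
deformation of the pattern itself. Under these assumptions, local
scale/rotation-invariant features are a natural representation, and identity
can be decided by counting distinctive descriptor correspondences —
no training data or learning stage is required, and new individuals are
enrolled by simply adding their feature sets to the database.

## Feature extraction

A from-scratch SIFT implementation, with the following fixed design:

- **Scale space**: 4 octaves × 5 Gaussian levels, base σ = 1.6, multiplicative
  step k = √2. The input is not upsampled before the first octave. Each
  octave's base is the previous octave's level with doubled blur, downsampled
  by taking every second pixel. Absolute scale of level *j* in octave *o* is
  σ·k^j·2^o. The octave count is reduced (with a warning) when the image is
  too small for the deepest octave to retain an 8-pixel side.
- **Detection**: a difference-of-Gaussians pixel is a candidate only if it is
  *strictly* greater or strictly smaller than all 26 space/scale neighbours;
  plateaus yield nothing and a constant image has no keypoints by
  construction.
- **Refinement**: up to 5 iterations of the 3-D quadratic (Taylor) fit;
  candidates are discarded when the fit is singular, drifts out of the valid
  domain, fails the contrast threshold (0.03 on the interpolated response) or
  the edge test tr²/det < (r+1)²/r with r = 10 (threshold 12.1).
- **Orientation**: gradient magnitude/direction from plain pixel differences,
  accumulated into a 36-bin histogram under a Gaussian window of
  σ = 1.5 × scale (radius 3 × that); every strict local maximum within 80 %
  of the global peak spawns a keypoint, with parabolic peak interpolation.
- **Descriptor**: a 16 × 16 sample grid rotated to the keypoint orientation,
  pooled into 4 × 4 spatial sub-blocks × 8 orientation bins (128 values) with
  trilinear interpolation and Gaussian weighting; the vector is normalised,
  clamped at 0.2 and renormalised, making it robust to affine illumination
  changes and limiting the influence of single strong gradients.

Descriptor computation is vectorised per pyramid level (batched bilinear
sampling and scatter-add into padded histograms), which keeps extraction at
roughly half a second per 640 × 480 image on one CPU.

## Matching and identification

Descriptors are compared by Euclidean distance with an exact 2-nearest-
neighbour search (a k-d tree backend is available but the 128-dimensional
exact scan is the default and the reference). A correspondence is accepted
only under Lowe's ratio test, d₁ < 0.75·d₂, which discards ambiguous matches;
a second neighbour at distance zero is rejected as degenerate. Matching is
one-directional by default (an optional cross-check is provided). When an
image is matched against itself (same non-empty image id), the zero-distance
self-neighbour is excluded.

A query is identified as the individual owning the database image with the
most accepted matches. Ties are broken by the smaller summed match distance,
then lexicographically by image id, and are flagged on the result. If the
best image has fewer than `min_match_count` matches the query is reported as
unidentified rather than guessed.

## Evaluation protocol

Images are split into an enrollment database and a test set by an
individual-stratified draw: each individual contributes its
largest-remainder share of the database quota (70 % by default), so a
100-individual, 800-image dataset splits into exactly 560 database and 240
test images while every individual stays enrolled. Individuals with a single
image go to the database with a warning. Test images are evaluated in
samples (blocks of 25 individuals per capture group by default); each sample
yields a confusion matrix with columns = actual and rows = predicted
identity, plus a separate per-individual count of unidentified queries.
Reported numbers are pooled counts (correct/total), per-group and
per-individual percentages, and the mean per-individual accuracy over
individuals that have at least one test image; displayed percentages are
rounded half-up to one decimal.

## Synthetic benchmark

Real tail photographs of monitored animals are usually not redistributable,
so the package generates a stand-in dataset with the same design. One
individual = one seeded Voronoi mosaic: jittered-grid points partition a
1330 × 889 canvas into ~400 cells, each cell receives a Gaussian-distributed
base shade (sd 0.14), boundaries are darkened over a 4-pixel ridge, and an
elliptical silhouette masks the canvas. Views are rendered by a single
bilinear affine resampling (rotation ±15°, scale 0.9–1.1) followed by gain,
gamma, Gaussian blur and seeded noise; the "close" tier uses blur σ 0.5 and
noise 0.01, the "far" tier is blurrier (σ 1.2), noisier (0.02) and darker
(gain × 0.85), emulating whole-tail photographs taken from further away.
All randomness flows from one global seed (derived seeds stay below 2³¹);
regeneration is bit-identical. Cell spacing and shading were calibrated so
that the default extractor finds 50–500 keypoints per working-resolution
image.

What the generator does **not** emulate: perspective and non-rigid
distortion, wet/dry appearance changes, specular highlights, occlusion and
background clutter, and — importantly — truly independent cell *layouts*:
all individuals share the same underlying jittered grid, so cell junctions
sit at roughly corresponding positions across individuals and differ mainly
in shading and local geometry. Identification on the default benchmark is
nevertheless reliable (rank-1 accuracy ≥ 90 % is asserted at seed 42, and is
typically 100 %), but same-versus-different *match-count margins* are
narrower than on real tails: different individuals attract roughly 20–25 %
as many ratio-test matches as the same individual under pure rotation
(ratios ≈ 3.5–5.5×), because junction descriptors match generically. The
rotation-margin acceptance test asserts a 5× separation and therefore fails
for some seed/angle combinations; this is a known property of the shared-grid
generator, documented here rather than papered over by retuning the
generator, and it does not affect identification accuracy.

## Numerical choices and caveats

- Images are float64 in [0, 1] throughout; enhancement stages at their
  identity settings are skipped, so identity configurations are bit-exact
  no-ops.
- The enhancement chain applies, in order: adaptive-histogram backlight
  correction (CLAHE, clip limit derived from the backlight/intensify/brighten
  sliders), exposure gain, lightness offset, contrast (slope about 0.5),
  gamma (out = in^(1/γ)) and unsharp masking (σ = 1.0). All point and
  convolution stages commute with a horizontal image flip to ≤ 1e-10; the
  CLAHE stage does **not** commute exactly because its tile grid is not
  flip-symmetric — a known, documented asymmetry of the adaptive step.
- The stratified split, tie-breaks and sample blocks are fully deterministic
  given the seed; the end-to-end pipeline writes its config (TOML, with a
  content digest) next to its outputs, and the HDF5 feature database refuses
  to load under a mismatched extraction-config digest.
- Display rounding is decimal half-up (so 97.95 → 98.0), not banker's
  rounding.

## Problem sizes

Defaults target the scale of a realistic monitoring study: hundreds of
images of ~100 individuals for evaluation arithmetic, and a 25-individual ×
8-image benchmark (≈ 3–4 CPU-minutes end-to-end) for the shipped synthetic
run. Extraction cost grows linearly in image count; the exact matcher is
quadratic in descriptors per image pair (~300 × 300 here, negligible), and
identification is linear in database size.

## Limitations

Beyond the generator gaps above: the pipeline assumes the tail region is
roughly planar and the crop excludes most background; it performs no
geometric verification of matches (match counts alone decide identity, as a
deliberate simplicity choice); and accuracy on real photographs depends on
image quality — lower-detail, whole-tail captures are expected to identify
somewhat worse than close-ups, which the two benchmark tiers mirror.
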