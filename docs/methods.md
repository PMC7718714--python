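# Methods

This note documents the models, parameter choices and numerical decisions
behind `roireg`, and what the synthetic phantom does and does not show about
real data.

## Problem setting and assumptions

A stack of serial histology sections is registered so that a user-defined
ROI (here: a blood vessel and its neighborhood) lines up through depth.
The core assumptions are:

- **Local rigidity.** Within an ROI of a few hundred pixels, tissue
  deformation between consecutive 4 µm sections is well approximated by a
  rotation plus translation.  Non-rigid deformation fields are explicitly
  out of scope; so is recovery of torn or folded regions.
- **Artifacts lie outside the ROI.**  The attention mechanism tolerates
  arbitrary corruption away from the ROI, but the ROI content itself must
  be intact in every slice.
- **Brightfield polarity.**  Tissue is darker than the illuminated
  background (configurable via `PreprocessParams.tissue_below_mean`).

## Stage 1 — surrounding-artifact removal

Grayscale conversion, Gaussian smoothing (σ = 10 px at the working level),
thresholding at the image mean, morphological opening then closing with a
20 px disc, connected-component selection, convex hull, background fill.

Decisions taken where the procedure is underdetermined:

- **Contour selection.**  Components are scored
  `area / (1 + distance(centroid, image center))`; the top scorer plus any
  component within 25 % of that score are kept.  This makes "large and
  central" deterministic and keeps genuinely bipartite sections.
- **Fill value.**  Pixels outside the hull are replaced by the per-channel
  median of the below-threshold (background) pixels rather than zero, so
  the hull boundary introduces no strong gradient and therefore no spurious
  SIFT keypoints.
- Pixels inside the hull are never modified; a blank slide returns
  unchanged with a `no_tissue_found` flag instead of raising.

## Stage 2 — rough alignment

**Segmentation.**  The piecewise-constant Mumford–Shah (Potts) energy

    E(labels, c) = Σ_x (I(x) − c_label(x))² + λ · |label boundaries|

is minimized by multi-resolution stochastic relaxation: quantile-initialized
labels are annealed with checkerboard Metropolis sweeps (geometric cooling,
factor 0.7) on a 4× downsampled image, upsampled, and refined at 2× and full
resolution with a final greedy sweep; phase means are re-estimated between
sweeps and the best labeling seen at the finest stage is returned.  Any good
Potts minimizer would serve here — the segmentation only denoises and
stain-normalizes the images before SSD matching — so a compact annealer was
preferred over more elaborate exact schemes.  Defaults: 3 phases
(background / weak stain / strong stain), 5 sweeps per stage, λ chosen
automatically so the boundary term roughly balances the data term of the
initialization.  The seed is explicit; identical seeds give bitwise-equal
labels.

**Search.**  The SSD objective is evaluated on phase-mean images (each pixel
replaced by its phase mean), cancelling inter-slice stain-density
differences.  The search is a true exhaustive grid enumeration — the
returned triple is the exact grid argmin, with ties broken toward the
identity (smallest |θ|, then |dx|+|dy|, then lexicographic).  For integer
translation grids the moving image is rotated once per θ onto a canvas
padded by the maximum shift, so every shifted window sees exactly what a
single combined rigid warp would see; this fast path is numerically
identical to warping per triple.  Defaults: search at pyramid level 2,
θ ∈ ±30° step 1°, shifts ±20 % of width step max(1, W/64) — wide enough for
mounting errors, small enough for desk-scale runtime.  The winning
transform is rescaled to level 0 (dx, dy, center double per level; θ is
scale-invariant).

## Stage 3 — multi-scale attention ROI registration

Per level r = k … 0 (default k = 3):

1. The ROI is materialized at level r: center ÷ 2^r, width/height fixed but
   clamped to the level's bounds.  At coarse levels the window therefore
   covers most of the tissue; the ROI-to-image area ratio is non-decreasing
   with level.
2. SIFT keypoints (10 scales per octave; detector thresholds at library
   defaults) are detected inside both ROIs.  Each 128-d descriptor is
   augmented with the keypoint position normalized to [0, 1] by the ROI
   extent and multiplied by a spatial weight — by default 0.25 × the median
   raw-descriptor norm, keeping geometry influential but not dominant.
   Matches are mutual nearest neighbors in augmented space, sorted by
   distance.  A Lowe ratio test is available but off by default: in
   repetitive tissue it can starve the 8-match pool.
3. The 8 strongest matches (all, if fewer) yield one rigid candidate per
   3-combination — C(8,3) = 56.  Each triplet is fit by orthogonal
   Procrustes restricted to det +1 (SVD of the 2×2 cross-covariance); the
   estimator refuses fewer than 3 pairs.  Collinear triplets (triangle area
   below 1e−6 × scale²) become *flagged identity candidates* rather than
   being dropped, preserving the candidate count and the safety floor.
4. Candidates are scored by the sum of squared grayscale differences over
   the ROI; the identity always competes, so the chosen SSD never exceeds
   the unregistered SSD.  Ties prefer the candidate nearest the identity.
   Scoring samples the moving image at the inverse-transformed ROI grid
   (bilinear, background fill), which equals warping the full image and
   cropping, at a fraction of the cost.
5. The winning `F_r` (rotation center: the ROI center at level r, keeping
   translations small) is rescaled to level 0 via `S F S⁻¹`,
   `S = diag(2^r, 2^r, 1)`, and composed as `F* = F_0 F_1 … F_k`.  At every
   level the *original* moving image is warped by the accumulated
   transform, so no resampling error compounds across levels.

Stack chaining: slice i+1 registers against the already-registered slice i;
each slice's stored transform (`composed_roi ∘ rough`) maps the raw slice
directly into the registered frame.  Conventions throughout: 0-based (x =
column, y = row) coordinates with pixel centers on integers, half-open ROI
boxes, degrees in configs/JSON and radians internally, bilinear
interpolation for images and nearest-neighbor for masks.

## Evaluation

Dice similarity `2|A∩B|/(|A|+|B|)` between consecutive warped lumen masks,
reported as mean ± std over pairs (flat mean over all pairs when several
vessels are evaluated).  A pair of empty masks is undefined: recorded as
NaN, excluded from the mean, warned about.  Masks are warped
nearest-neighbor so they stay binary.

## Synthetic phantom

`generate_phantom` renders, per slice: a tissue disc with an irregular
boundary and band-limited noise texture (two Gaussian-smoothed scales,
shared across the stack plus a small per-slice component — consecutive real
sections are locally similar, which is what SIFT exploits); a vessel with a
dark wall ring and bright lumen whose center follows a low-order polynomial
in z (≈ 0.75 px/slice) and whose radius (20 px) drifts sinusoidally by
≤ 0.5 px/slice; a per-slice stain-intensity scale in [0.85, 1.15]; and an
independent uniform rigid perturbation per slice (|θ| ≤ 10°, shifts
≤ 30 px at level 0), recorded as ground truth.  Defaults: 10 slices,
512×512 canvas, 4 pyramid levels (2×2 block-mean), 128×128 ROI centered on
the vessel.  Artifact injection adds dark stain blobs and background-valued
tear wedges, placed by rejection sampling strictly outside an exclusion
circle of 1.5 × the ROI half-diagonal around the (perturbed) ROI center;
lumen masks, ground-truth transforms and all pixels inside the exclusion
zone are untouched.

What passing on the phantom does **not** show: robustness to real stain
chemistry (CD31/SMA color variation is modeled only as an intensity scale),
to deformations *inside* the ROI, to out-of-plane structural change between
sections, or to gigapixel-scale images (the phantom is 512², standing in
for slides that are orders of magnitude larger; the algorithm's per-level
cost depends on the ROI size, not the slide size, so the attention
mechanism is exercised faithfully at this scale).

## Numerical choices and degenerate inputs

- Transforms store rotation center and level explicitly; composition and
  rescaling are exact matrix operations, validated to 1e−9.
- Fewer than 3 matches at a level → identity with a `too_few_matches` flag,
  never an exception; degraded cases propagate as QC flags.
- Rough-search tie-breaks and candidate tie-breaks both prefer the
  identity, making results reproducible under exact SSD ties.
- Test and acceptance problem sizes (10 × 512² stacks, 48² oracle grids,
  256² unit fixtures) were chosen so the full suite completes in minutes on
  one CPU while still exercising every stage at realistic perturbation
  magnitudes.

## Known limitations

- Purely rigid per-ROI output; no b-spline refinement stage is included.
- The chained registration accumulates any per-pair bias along the stack
  (visible as slow frame drift when the ROI content itself drifts); Dice
  between consecutive pairs is unaffected.
- ROI selection is manual; automatic vessel detection is out of scope.
- Scanner-vendor pyramid formats are not parsed; the canonical input is a
  plain per-level TIFF directory.
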