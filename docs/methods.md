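# Methods

This note documents the models, parameters and numerical choices behind
`motormap`, and what the synthetic phantom does and does not establish
about real data.

## Signal model of the phantom

A voxel time course is

    y(t) = baseline + drift(t) + g·G(t) + s(t) + ε(t)

with `baseline` = 1000 signal units, `drift` a polynomial of order ≤ 3
in normalized time (default coefficients (0, 8, −5, 3) units),
`G(t)` a brain-wide fluctuation shared by every brain voxel (z-scored
white noise, amplitude `global_amp` = 2 % of baseline), and
ε ~ N(0, `noise_sd`²) i.i.d. per voxel and time point
(`noise_sd` = 20 units, i.e. tSNR ≈ 50 in quiet tissue). The
signal term `s(t)` is:

* **Task runs** — the block indicator convolved with the canonical
  double-gamma HRF (response peak 6 s, undershoot peak 16 s, ratio 1/6,
  unit peak amplitude), scaled to `task_effect` = 2 % of baseline, and
  confined to the task's activation region. The default design has 12
  active blocks (6 per side, alternating with rest) and 6 rest blocks
  tiling 144 volumes at TR 3.0 s; `active_left` blocks drive the
  right-hemisphere region and vice versa. Resting runs are 200 volumes
  at TR 2.8 s.
* **Rest runs** — a single band-limited source (white noise brick-wall
  filtered below 0.1 Hz, then z-scored) shared by all sensorimotor-
  network voxels at `network_amplitude` = 2 % of baseline.

Randomness is split into one `numpy` Generator stream per operation,
seeded as `spec.seed + fixed offset`, so adding an operation never
perturbs the draws of existing ones; a fixed seed gives bit-identical
output.

### Geometry

Anatomy is parametric (boxes, ellipsoids) on a 48 × 54 × 42 grid of
2.5 mm isotropic voxels: a brain ellipsoid, pre- and post-central gyrus
slabs (22.5 mm wide, 12.5 mm thick, 47.5 mm tall) separated by a 5 mm
central sulcus, an ellipsoidal hand-knob protrusion on each precentral
slab, medial paracentral lobules, a ventral mouth strip, a 7.5 mm-radius
lesion anterior to the right precentral gyrus, and a deep white-matter
core. Cortical regions are clipped to the brain. Two sizing rules
matter:

* every activation region is at least ~12.5 mm across, so after 8 mm
  FWHM smoothing the 50 %-of-peak threshold contour falls essentially on
  the true region boundary (for a slab much wider than the kernel, the
  smoothed profile at the boundary is exactly half the plateau value) —
  this is what makes AMPLE recover planted extents;
* the network occupies roughly a tenth of the brain. Spatial sparsity
  is what makes a resting-state network a high-negentropy (super-
  Gaussian) spatial component; a network occupying a quarter of a small
  brain is spatially *sub*-Gaussian and fixed-point ICA will not isolate
  it. The same sparsity keeps the network's contribution to the global
  mean small, so global signal regression attenuates rather than
  removes it.

Ground-truth stimulation sites are placed by picking random surface
voxels of the activation mask and bisecting along the outward ray from
the mask centroid until the nearest-supra-voxel distance equals the
requested offset (60 bisection steps, ~1e-15 mm accuracy).

## Preprocessing chain

Fixed order: confound regression → polynomial detrend → low-pass →
global signal regression (GSR) → smoothing.

* **Detrending** uses an orthonormalized polynomial basis (QR of the
  Vandermonde matrix on a [−1, 1] time axis); the result is the exact
  least-squares projection and basis-invariant.
* **Low-pass** is zero-phase frequency-domain apodization: unit gain
  below the cutoff, raised-cosine roll-off of width 0.02 Hz centred on
  the cutoff (default 0.1 Hz), zero above. Zero phase shift keeps
  centre-of-mass and overlap measures comparable across filtered and
  unfiltered maps. Only pass-band/stop-band behaviour is contractual
  (≥ 0.95 retention at ≤ half the cutoff, ≤ 0.05 at twice the cutoff);
  the kernel family is an implementation choice.
* **GSR** is single-pass OLS of each voxel on the brain-mean course
  plus intercept, applied after detrending; the residual brain-mean
  course is analytically zero.
* **Smoothing** is volume-wise 3D Gaussian convolution,
  σ = FWHM / (2√(2 ln 2)) per axis in mm, zero-padded at the edges;
  masks are applied after smoothing, never before.

## Mapping

* **GLM**: per-run, per-voxel OLS with t statistic of the task
  coefficient; no autocorrelation correction (single-run fixed-effects
  analysis). Perfect fits are capped at |t| = 1e8. In the phantom
  pipeline the left- and right-side regressors enter one design
  together with cubic drift confounds, and the bilateral map is the
  voxel-wise max of the two one-sided t maps. Maps are brain-masked
  (non-parenchymal voxels removed), mirroring clinical practice — and
  necessary here because voxels outside the noise-bearing brain would
  otherwise reach arbitrarily large t from smoothing leakage alone.
* **SBA**: the seed's unweighted mean course as GLM regressor. The
  anatomical hand seed is the 10 × 2 mm axial slab around the hand knob
  intersected with the precentral gyrus; the functional seed is a 6 mm
  sphere at the task-activation peak of the healthy hemisphere.
* **Spatial ICA**: voxels × time matrix, PCA-whitened to 20 components,
  unmixed by fixed-point negentropy maximization (scikit-learn FastICA,
  logcosh contrast, max 500 iterations, tol 1e-6, seed exposed).
  Component maps are z-scored over the brain mask; the sign is fixed by
  non-negative spatial skewness. The sensorimotor component is chosen
  automatically as the component maximizing the fraction of its
  supra-threshold voxels (z ≥ 2.0 by default) inside a sensorimotor
  reference mask, with ties broken by inside-count then component
  index — an automated stand-in for the two-observer visual selection
  used clinically; the selection is recorded in the map's provenance.

## Thresholding and concordance

* **AMPLE**: threshold = 0.5 × the map maximum inside the motor mask
  ipsilateral to the lesion; the supra-threshold set is taken over the
  whole map. Supra-threshold is non-strict (≥), so the peak itself is
  always included. A non-positive in-mask maximum is an error ("no
  excitable peak").
* **Overlap**: α = V_overlap / V_tb (sensitivity of the rs map),
  β = V_overlap / V_rs (specificity), with all three counts restricted
  to an evaluation mask — by default the bilateral pre+postcentral mask
  dilated by 2 voxels (6-connected iterations; the paracentral mask for
  foot tasks takes 6). Whether the evaluation mask should be bilateral
  or ipsilateral is genuinely open; bilateral is the default and the
  choice is recorded in the result's `mask_label`.
* **Centres of mass** pool *all* supra-threshold voxels inside the
  anatomical mask (no cluster pre-selection, which removes
  fragmentation confounds), weighted by t score, in world mm. The
  lesion CoM is the unweighted centroid; distance-to-lesion is measured
  to the lesion CoM (a border-distance variant is not provided — the
  centroid definition is the one carried through the per-case tables).
* **ECS scoring**: sites are Cartesian-projected to the nearest cortex
  voxel centre (ties → lowest linear index, logged); the score is 0 if
  the projected site lies inside a supra-threshold voxel, else the
  Euclidean distance to the nearest supra-threshold voxel centre.
  Match rates count distances strictly below 7 or 10 mm cutoffs.
* **"Dilated by k voxels"** is read as k iterations of 6-connected
  binary dilation (city-block ball) — the common morphological-toolbox
  semantics, and checkable against a distance-transform oracle. The
  iteration count is kept as provenance on the mask.
* **Aggregation** uses sample SD (n−1); single-value groups report
  SD 0. Missing cells carry two distinct markers: '-' (map unavailable)
  and '- -' (comparison undefined because the reference task map is
  absent); both are excluded from means, never imputed.

## Numerical and interface choices

* All distances are computed in world mm through the affine; voxel
  indices never appear in results.
* The hand-area slab is the symmetric half-open interval
  [z₀ − 10 mm, z₀ + 10 mm) around the knob; half-open avoids
  double-counting at slab joins.
* The fROI sphere includes a voxel when its centre is within the
  radius; the centre is the arg-max voxel centre, ties to the lowest
  linear index (logged).
* Reports are written both as TSV rounded to reporting precision
  (2 decimals for α/β, 1 for mm) and as JSON at full precision.
* Gyrus masks are plain NIfTI inputs; no atlas fetching. The hand-knob
  coordinate is supplied by the user or the phantom, not detected.

## What the phantom does and does not show

The phantom establishes that the implementation is correct: planted
activations, networks and stimulation sites are recovered at known
tolerances, and every geometric kernel agrees with brute-force
enumeration. It deliberately omits head motion, slice-timing effects,
physiological (cardiac/respiratory) noise, autocorrelated noise,
field-strength differences, neurovascular uncoupling near lesions, and
inter-subject anatomical variability. Passing tests therefore say
nothing about rs-fMRI's clinical adequacy on real patients — that
question is answered by the per-case clinical tables packaged as
fixtures, which the aggregation layer reproduces but cannot recompute
from raw data (the underlying images are not public). Re-aggregating
rounded per-case cells can differ from a summary computed on unrounded
values by one unit in the printed precision; the tests allow exactly
that margin.

## Problem sizes

Default test and acceptance runs use the 48 × 54 × 42 grid (≈ 45 000
brain voxels), 144-volume task runs and 200-volume rest runs — chosen
so a full pipeline run completes in well under a minute on one CPU
while keeping every region large relative to both the voxel size and
the smoothing kernel. Unit tests use a 24 × 24 × 20 miniature of the
same anatomy.
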