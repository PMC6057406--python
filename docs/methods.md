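# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not establish.

## Problem and pipeline

Input is a single 8-connected foreground component in a 2D binary raster
(the segmented corpus callosum in the mid-sagittal plane) with a known
isotropic pixel size. Output is an open subpixel polyline from the anterior
pole of the rostrum to the posterior pole of the splenium, centred in the
shape. The pipeline is: boundary tracing and oriented frame → radial
five-subregion partition → statistical shape-context endpoint localization →
distance-map active contour with clamped endpoints → disk-reconstruction
evaluation. Every stage is deterministic; there is no randomness anywhere in
extraction, which is why repeated runs agree to the bit.

## Geometry conventions

Pixels are indexed `grid[row, col]`; points are `(x, y)` with y increasing
downward. Reported angles use the y-up sense (an axis rising to the right of
the image is positive). Masks are assumed anatomically canonical (anterior at
low x, superior at low y); the CLI offers flips. A boundary pixel is a
foreground pixel with a 4-neighbour background pixel (8-connected object,
4-connected background). The oriented frame comes from the principal
eigenvector of the second central pixel moments, sign-fixed toward +x; the
bounding rectangle is the tightest axis-pair-aligned box on pixel centres.
A rasterised disk has an isotropic moment tensor and is rejected
("degenerate orientation", relative eigenvalue gap ≤ 1e−6).

The five-subregion partition fans four rays, at equal angular interval, from
the midpoint of the rectangle's inferior long side (the long side whose
midpoint has larger y). The fan is bounded by the rays through the
anterior-most and posterior-most pixels *along the major axis*; angles are
unwrapped relative to the posterior ray so the rostrum may dip below the fan
origin's horizontal, and pixels angularly outside the fan are clamped into
the first/last sector. This span rule is our choice — the radial Witelson
variant we follow states only the equal interval — and makes the five
sectors cover the shape exactly.

## Endpoint model

The shape context of a boundary point is a 15 × 10 (angular × log-radial)
histogram of the other contour points, built on the closed contour resampled
to 200 points at uniform arc length. Radii are normalised by the CC
bounding-rectangle height; log-radial bin edges run geometrically from 1/16
to 2 of that height, with under/overflow clamped into the extreme bins so
every histogram sums to exactly 1 (this keeps L1 distances between
histograms comparable). Angles are measured counterclockwise from the
subregion reference direction: the principal axis of CC1 (anterior) or CC5
(posterior) pixels, sign-fixed anterior→posterior; degenerate subregion
moments fall back to the whole-CC major axis with a logged warning. The
histogram is centred at the candidate point itself — a descriptor centred at
the subregion mass centre would be identical for all candidates and could
not discriminate them; the subregion frame contributes only the angular
reference.

Training histograms are computed at the labelled endpoint snapped to the
nearest traced-boundary pixel (labels further than 2 px from the boundary
are rejected); the model is the elementwise mean over the K training masks.
Localization computes the histogram of every resampled contour point lying
in CC1 (or CC5) and returns the candidate with minimal sum of absolute bin
differences, ties to the earliest in contour order. Restricting candidates
to the end subregions prevents spurious far matches; `--candidates all`
lifts the restriction. L1 is used because a signed bin-difference sum would
cancel; χ² would be a reasonable alternative but is not the default.

One angular bin spans 24°, which bounds the rotation mismatch the descriptor
absorbs between model and sample; the synthetic generator's rotation range
(±20° about a 22.5° canonical tilt) stays within this.

## Distance map and active contour

The distance map assigns every foreground pixel its exact Euclidean distance
to the nearest boundary pixel (boundary pixels are their own nearest, hence
0; background is 0 by definition). Masks with no interior pixel ("no
interior") are rejected. The external force is `c(D_n)·∇D_n` on the
normalised map, gradient by central differences (one-sided at image
borders), sampled at subpixel snake points bilinearly. The modulation
coefficient `c(d) = (e − e^d)/(e − 1)` is the simplest exponential form with
the required behaviour — continuous, strictly decreasing, `c(0) = 1` at the
boundary, `c(1) = 0` on the ridge — and is pluggable. The force is naturally
zero on flat background (≥1 px outside the object); background pixels
touching the boundary keep the inward pull their central difference picks up
from the interior, which helps recapture points that stray slightly outside.

The snake is initialised by a natural cubic spline through the anterior
endpoint, the maximal-distance pixels on the four divider rays (ties to the
pixel nearest the fan origin), and the posterior endpoint, parametrised by
chord length and resampled to `n_points = 100` at equal arc length
(coefficient of variation of spacings < 1% by construction).

Evolution is the canonical semi-implicit scheme: implicit pentadiagonal
internal operator built from tension α = 0.1 and rigidity β = 0.5 (working
values established for callosal masks) with unit time step, explicit
external force. The
two endpoint rows are Dirichlet (identity rows, zero force, right-hand side
pinned), which fixes the endpoints bit-exactly at every iteration. Two
stabilisations matter in practice:

* **Normal-only external force.** The tangential force component slides
  points along the ridge toward thicker regions without changing the curve's
  geometry; periodic arc-length resampling (every 10 iterations) undoes the
  slide, so together they form a limit cycle (~0.06 px/iteration) that never
  meets the convergence tolerance. Projecting the external force onto the
  curve normal removes the slide, leaves the limit geometry unchanged, and
  lets the iteration reach a genuine fixed point (~70 iterations on
  synthetic masks).
* **Foreground confinement.** On flat background the force vanishes, so a
  curve segment that leaves the object (e.g. the initial spline chord
  cutting the concave pocket under the genu hook) would relax only through
  slow internal tension. Interior points whose containing pixel is
  background are projected to the nearest foreground pixel after each
  update, keeping every interior point where the force field is defined.

Convergence is declared when the maximal per-point displacement of an update
falls below `tol_px = 0.01`, with a cap of 500 iterations; non-finite
coordinates raise "diverged" with the iteration number.

## Evaluation

Reconstruction uses one disk per centerline point with radius equal to the
exact Euclidean distance from the (subpixel) point to the nearest boundary
pixel centre plus half a pixel — the maximal inscribed disk of the
pixel-square shape centred there. Two deliberate departures from the naive
"radius = interpolated distance-map value": the map measures to boundary
pixel *centres* (half a pixel short of the shape's edge), and bilinear
interpolation along the mid-channel of an even-width region underestimates
the true distance by up to another half pixel (adjacent rows carry equal
values), which would leave entire tube walls uncovered on a knife edge.
Pixel membership is by centre-in-disk, matching pixel-count areas. The error
rate is computed as `A(O \ R)/A(O)` — pure rasterisation leakage of R
outside O neither helps nor hurts, and the rate stays in [0, 1].

The centerline distance is the symmetric mean nearest-neighbour distance
between the two point sets, in mm; reproducibility is its mean over all
unordered pairs of repeated runs.

## Synthetic data

The generator emulates the anatomy the clinical selection filter describes:
an 8-control-point arched backbone (~80 mm span) with an anterior hook,
swept with a shape-preserving thickness interpolant through half-widths of
5 mm at the genu (s ≈ 0.15), 3 mm mid-body, 2 mm at the isthmus (s ≈ 0.75)
and 5.5 mm at the splenium (s ≈ 0.95), tapering to zero exactly at both
tips. Control points are jittered (σ = 1 mm) for inter-subject variability;
rotation is drawn uniformly in ±20° about the 22.5° canonical tilt and scale
in [0.9, 1.1]; the mask is rasterised as the union of disks along the dense
backbone; boundary irregularity is smooth radial noise (≤8 Fourier
harmonics, RMS 0.5 px by default) attenuated near the tips to keep the tip
geometry stable and the mask connected. A draw failing the single-component
check or the anatomical filter (length 7–9 cm, width 2–4 cm, orientation
5–40°, area > 2 cm²) is redrawn, mirroring the clinical pipeline's candidate
selection; the accepted sample is deterministic in the seed. Ground truth is
the pre-noise backbone, its tips projected to the nearest boundary pixel of
the rasterised mask so the true endpoints lie on the boundary.

What the synthetic results show: the pipeline's determinism, its endpoint
accuracy and centerline recovery under controlled shape variability and
smooth segmentation noise, and the internal consistency of every stage
against brute-force oracles. What they do not show: performance under the
pixel-level segmentation errors, partial-volume effects, pathology-driven
shape outliers and rater disagreement of real clinical masks — synthetic
boundaries are smoother than clinical ones, so reconstruction error rates
here are expected to undercut what the same method achieves on clinical
masks, and the acceptance checks therefore treat the clinical benchmark
figures (0.85 mm endpoint error, 0.12 mean RER) as upper bounds.

## Problem sizes and defaults

Acceptance runs use 15 training and 20 test masks per figure on a 128 × 160
grid at 1 mm/px — small enough to recompute everything from scratch in
seconds, large enough for stable means. All tunables sit in two frozen
configs: `LogPolarConfig` (15 angular / 10 radial bins, radial range
1/16–2 of the CC height, 200 contour samples) and `SnakeConfig` (α = 0.1,
β = 0.5, 100 points, step 1.0, tolerance 0.01 px, cap 500 iterations,
resampling every 10).

## Known limitations

* Endpoint localization degrades on shapes whose CC1 principal axis deviates
  strongly from the population (occasional 3–5 px anterior outliers on
  heavily jittered synthetic rostra); the descriptor's 24° angular bins
  bound how much local-frame error it can absorb.
* The partition fan-span rule and the inferior-side convention are
  documented choices; other radial Witelson variants would shift subregion
  borders and hence the candidate sets.
* Masks with internal holes keep their outer contour only; the distance map
  still treats hole borders as boundary, which is untested territory —
  upstream segmentation is expected to deliver hole-free masks.
* The snake's β penalises curvature, so extremely sharp rostral hooks are
  smoothed slightly relative to the true medial axis.
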