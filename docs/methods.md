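# Methods

This note documents the models, algorithms and parameter choices behind
`cortexmetrics`, what the synthetic scenes do and do not emulate, and the
numerical decisions a user may want to override.

## Coordinate and unit conventions

Image data live in `VoxelGrid` arrays ordered `(time, z, y, x, channel)`.
Indices are 0-based, pixel centers sit at integer coordinates, and z
index 0 is the apical-most slice. All reported lengths and areas are in
physical units (µm, µm²) via `pixel_size_xy` and `z_step`; times are
seconds at acquisition level and minutes for constriction kinetics (each
`KineticsSeries` carries a unit tag). Calibration is read from TIFF
metadata and falls back to an explicit config — never to silent defaults.

## Basal-plane detection and ingression depth

The apicobasal mean-intensity profile of a reporter stack has two peaks:
the apical cortex at the surface and the basal network at the furrow
front. The basal peak is the most prominent local maximum deeper than an
apical exclusion zone (default 2 µm); the exclusion zone exists because
prominence alone cannot distinguish a bright cortex from the basal
signal, and the default is logged so the choice is visible. Ties in
prominence break to the deeper candidate. Boundary slices count as
maxima (the apical peak usually sits at z = 0).

Projections sum `n_projection_slices` (3–5, default 3) slices centered at
the basal peak; windows truncated by the stack boundary are flagged.
Ingression depth is the distance between the apical peak (most
superficial local maximum) and the basal peak, measured between slice
centers, and is invariant to global intensity scaling.

Ingression curves from different samples start at arbitrary acquisition
times, so they are aligned by time shifts that minimize the mean squared
depth difference to the first curve over the overlap — a grid search at
frame resolution refined by a parabolic fit through the three best
offsets, with the admissible shift bounded by the reference record length
(beyond that there is no overlap to score). The aligned curves are
averaged on a common grid and the time axis zeroed where the mean crosses
`zero_depth` (default 4 µm, the staging threshold for the slow phase).

## Opening segmentation

The watershed chain runs, in order: (1) intensity inversion (openings
become bright); (2) min–max rescale and tile-based CLAHE (clip limit
0.01) — the rescale makes the whole chain invariant to affine intensity
changes; (3) Sobel gradient magnitude; (4) foreground markers: regional
maxima of the image morphologically opened with a disk, cleaned by a 3×3
closing then erosion; maxima are additionally required to lie in the Otsu
foreground of the opened image, because contrast enhancement can raise
residual texture in signal-free regions to local-maximum status without
those maxima being openings; (5) background markers: skeleton of the
Otsu-complement of the opened image; (6–7) watershed of the gradient
image seeded with the labelled fore/background markers (equivalent to
flooding after minima imposition at the markers), 4-connected, with
watershed lines kept; (8) the background basin and all ridge pixels map
to label 0. Openings touching the frame border are flagged and excluded
from shape statistics by default since their areas are truncation
artifacts.

The disk radius is the one free parameter. It is chosen by running the
marker stage over a candidate list (default 6–26 px) and taking the
midpoint of the longest run of consecutive radii that yield an identical
marker count — a stability plateau. Radii yielding zero markers are
failures, not plateaus; ties take the smaller radius; if every usable
count differs, the smallest usable radius is returned with a warning.
The rule is isolated in `optimize_marker_radius` so it can be swapped.

Watershed lines sit on the gradient crest, i.e. on the opening boundary,
so assigning them to background biases areas low by roughly half a pixel
of perimeter. At the default sampling (0.1 µm/px, ~1 µm fibers, ~8 µm
lattice pitch) this amounts to ~2–3 % of an opening's area and is the
dominant term in the area-error budget.

## Shape statistics

Angularity is `(convex perimeter / ellipse perimeter)²`. The convex hull
is taken over the sub-pixel iso-0.5 boundary contour rather than pixel
centers, which removes most rasterization bias from the perimeter. The
"major and minor axis" of an opening are those of the moment-equivalent
ellipse (the standard region-properties convention); the ellipse
perimeter is evaluated with the complete elliptic integral of the second
kind (machine precision; the test suite checks it against an independent
arc-length quadrature). A rasterized disk of radius 40 px measures
1.014; the error decays monotonically with radius and the statistic is
rotation- and scale-invariant to well under 1 % at the sizes the pipeline
segments.

## Contractility kinetics

Mean opening area per frame is computed over openings whose centroids
fall in a region of interest (frame-wise means, no identity tracking —
the openings do not move, and frame-wise statistics are what the
summary measures need). Fold change is control mean over activated mean
at each time point. The constriction rate is the negated least-squares
slope of the mean area over a window from the first sample; the default
window is 1 min with 2 min available, since both read-out windows are in
common use, and an `effective_diameter` mode fits 2·√(A/π) to report
µm/min — both are emitted, clearly labelled, because area-rate and
diameter-rate conventions coexist in this literature.

The myosin-II fold change takes, for each stack, the mean of three slices
centered at that stack's basal peak, subtracts the background (mean
intensity of opening interiors eroded by 2 px, avoiding ridge
bleed-through), and divides the post-activation maximum by the
pre-activation value.

## Ablation recoil

Tracks are displacement versus seconds since the cut, zero at t ≤ 0 by
construction. Interpolation onto analysis grids is linear and never
extrapolates. Maximum displacement is read at 125 s (saturation) by
default. The initial recoil velocity is the least-squares slope of all
in-window (1–4 s) samples *pooled* across an embryo's tracks; per-track
slope averaging is available via a flag, because the pooling convention
is ambiguous in practice and the two differ under unbalanced sampling.

## Fiber metrics

The fiber segmenter is deliberately minimal — Otsu threshold,
skeletonization, branch-point removal, minimum-length filter — so that
the width and density formulas run on reproducible geometry; it does not
attempt oriented filtering or fragment regrouping, and crossing fibers
are split at junctions rather than resolved. Width is twice the mean
Euclidean distance transform of the binary mask along the skeleton:
exact for a clean rectangle, with a worst case of about +2 px for
axis-aligned bars whose half-covered anti-aliased edges clear the Otsu
threshold; averaged over orientations the bias stays below 1 px for
3–15 px bars. Density is the fiber's background-subtracted mean
intensity (measured in a tube of the fiber's width around its skeleton)
divided by an explicitly designated single-fiber reference intensity —
the reference choice is recorded in the output rather than made
implicitly. Relative density divides by a control-population median.
Knockdown efficiency is integrated frame signal over the control mean;
values below 0.15 are flagged as efficient depletion.

## Synthetic scenes

The generator exists to make every stage testable against analytic truth:

- **Network frames** render a honeycomb of hexagonal openings
  (`hexagonal`), circles on the same lattice (`ring`), a vertex-jittered
  mesh (`meshwork`), or low-contrast filtered noise (`priming`, which
  has no openings because the early-stage signal is diffuse). Polygons
  are anti-aliased by 4× supersampled coverage so sub-pixel truth areas
  are meaningful; the surrounding field is filled at fiber intensity so
  no synthetic opening touches the border. Truth areas and angularity
  come from the exact vector geometry (Green's-theorem moments, elliptic
  integral) before rasterization.
- **Constriction movies** shrink each opening isotropically about its
  center so its area follows A(t) = A₀ − rate·t, with the rate selected
  by membership in a rectangular activated region; generation refuses
  parameter combinations that would drive an area to zero.
- **Embryo z-stacks** are spatially uniform slices whose axial profile is
  an apical plus a basal Gaussian (width 1 µm, amplitudes 1 and 3 —
  basal dominance is what makes the two-peak profile resolvable).
- **Recoil tracks** follow d(t) = d_max(1 − e^(−t/τ)) plus i.i.d.
  Gaussian noise at t > 0. A single exponential is used because it gives
  closed-form truth for both the initial velocity (d_max/τ) and the
  saturation plateau; it is a description of the curve shape, not a
  viscoelastic model.
- **Fiber images** are anti-aliased rectangles of stated width, angle
  and peak intensity over a uniform background, with pairwise overlap
  rejected beyond a tolerance.

Noise layering is fixed: Poisson shot noise (scaled so the image peak
maps to `peak_photons`; peak SNR = √peak_photons), then additive
Gaussian read noise, then Gaussian blur standing in for the PSF; with
all three disabled the image equals the analytic scene exactly. Every
generator draws from one `numpy` generator seeded per call, so identical
parameters and seed give bit-identical outputs. Detector noise
statistics are not constrained by any reference data, so the defaults
(peak 100 photons, 1 % read noise, 0.1 µm blur) are stated in
`PipelineConfig` and easy to override.

What the scenes do *not* emulate: mechanics (no force balance or vertex
model), 3-D furrow geometry beyond the axial profile, illumination
inhomogeneity, bleaching, or cell-to-cell variability in opening shape.
Passing the recovery suites therefore demonstrates that the operator
chain measures what it claims on images with known truth — not that real
microscopy meets these noise assumptions.

## Problem sizes and defaults

Default synthetic sampling is 0.1 µm/px for network scenes (≈10 px
across a 1 µm fiber, keeping the watershed-line quantisation small
relative to opening areas), 0.3 µm/px for embryo stacks, and 15 nm/px
for fiber images. The recovery suites run 8×8-opening lattices over 10
noise seeds for segmentation, 3×3 lattices at 0.12 µm/px over 20 seeds
per rate for constriction kinetics (four- to five-frame movies), 10-track
ensembles over 20 seeds for recoil, and 5 widths × 10 orientations for
fiber width — sizes chosen so the full suite completes in a few minutes
on one CPU while keeping every tolerance meaningfully tight.

## Known limitations

- The segmentation count is only exact when openings are well separated
  at the chosen marker radius; heavily fragmented or merging openings
  (late ring phase collapse) are outside the validated regime.
- Opening areas carry the ~2–3 % negative watershed-line bias described
  above; fold changes largely cancel it, absolute areas do not.
- `area_series` uses frame-wise means; openings that disappear mid-movie
  shift the mean rather than being tracked out.
- The fiber segmenter is not a replacement for oriented-filter
  extraction tools on dense, curved, or crossing networks.
- Recoil analysis assumes tracks are already extracted; no automated
  interface tracking is provided.
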