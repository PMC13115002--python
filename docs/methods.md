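# Methods

This note documents the models, parameters and numerical choices behind
`nervemap`, and what the synthetic phantoms do and do not establish about
behaviour on real scans.

## Working resolution and physical units

All analysis runs on a downscaled raster. Coordinates are 0-based,
row-major, origin top-left; point coordinates are (x, y) = (column, row).
Physical quantities are µm and mm. `effective_mpp = mpp_base × downscale`
is the single source of physical scale; window sizes given in mm² are
converted with `window_px = ⌊√area · 1000 / mpp_eff⌋`, so a 1 mm² window
at 8 µm/px is 125 px. Downscaling selects the nearest coarser pyramid
level of a tiled TIFF and then box-resamples to the exact factor; box
(area) averaging is used because it preserves the mean stain fraction the
density metric measures. Non-integer pyramid ratios are resolved by the
final exact resampling step, keeping window arithmetic deterministic.
The native mpp is metadata, never assumed: it is read from the TIFF
resolution tags or an Aperio-style `MPP=` description field, from PNG
dpi, or supplied by the caller; a file with no resolution information and
no override is an error.

## Tissue segmentation

A pixel is tissue-candidate when its blurred Rec.601 luma is below
`brightness_max` OR its Sobel gradient magnitude is at least
`gradient_min` (the OR keeps pale but textured regions; an AND mode is a
config switch). Components under `min_area_px` (8-connectivity, inclusive
threshold) are removed and the survivors dilated by a disc of
`dilate_radius` so fibres at the tissue rim are not clipped. Defaults
(blur σ=2, brightness 220, gradient 10, min area 500 px, dilation 3 px at
downscale 16) are engineering choices exposed in config — the appropriate
values depend on scanner background and staining intensity.

## Fibre classification

HSV thresholding in the 8-bit convention H∈[0,179] (half-degrees),
S,V∈[0,255], with closed intervals at both ends and no hue wraparound
(DAB brown sits near the hue origin but does not cross it under this
convention). The default range H (0,80), S (12,125), V (31,162) matches a
calibrated DAB/hematoxylin setup; because staining hue varies with
antibody dilution, counterstain strength and scanner, the range is a
required parameter with these values only as defaults. Classification is
restricted to the tissue mask, so FiberMask ⊆ TissueMask always holds.
No stain deconvolution or learned detection is attempted.

## Density mapping

Non-overlapping tiling (stride = window) is the default because the
rendered grid should coincide with the analysis windows; a stride
parameter allows overlapping maps, at the cost of the count-conservation
identity. Partial edge windows are normalised by their true pixel count
rather than padded — padding would fabricate low densities along the
slide border. With the default tiling, Σ(density × cell area) equals the
fibre pixel count exactly (integer arithmetic via a summed-area table).

Rendering uses fixed logarithmic bins — default 8 lower edges from 1e-4
to 10^-0.5 at constant ratio √10 — so colours are comparable across
slides; densities below the first edge form a designated background bin
that is left unpainted. Alpha blending is `round_half_up(α·heat +
(1−α)·base)` with α = 0.3 by default.

## Ring reassembly

Fragment placements (flip, rotation about the fragment centre, integer or
fractional translation, z-order) live in an explicit per-ring JSON layout
— the "predefined spatial map" of a dissection protocol, which has no
published encoding. Images and binary masks are transported by
nearest-neighbour inverse mapping; the composite density map is then
**recomputed** from the assembled fibre mask rather than by resampling the
coarse window grids, because window-grid transport under rotation cannot
conserve fibre counts, while mask transport followed by re-tiling is
exact for exactly invertible placements.

Seam refinement closes residual gaps between fragments: a gap pixel is a
background pixel within `seam_band/2` (default 5 px) of two distinct
fragments and inside the morphological closing of the tissue (the closing
keeps the outer rim from being inflated). Gap pixels inherit tissue,
colour, fibre value and provenance from the nearest tissue pixel. The
relative tissue-area change is reported, and if it would exceed the bound
(default 1%) the composite is returned unchanged with a warning — the
correction is deliberately conservative, never forced. Gaps wider than
the seam band are only partially detected; that is intentional, since a
wide mismatch signals a layout error rather than processing shrinkage.

## Registration

The rigid/similarity stage is the closed-form Procrustes solution (SVD of
the centred cross-covariance); reflections are disallowed by default and
available behind a flag for flipped sections. The deformable stage is a
single regularized thin-plate spline: kernel U(r) = r² log r, side
conditions enforced through the bordered linear system, regularization λ
added to the kernel diagonal. λ = 0 interpolates landmarks exactly;
λ → ∞ recovers the best affine fit, so the smooth family spans the linear
stage as its limit. A per-sector piecewise mode is intentionally left
out; a single TPS with tunable λ was sufficient for every phantom case
and keeps the inverse well behaved. Because a TPS has no closed-form
inverse, image resampling uses a reverse-direction TPS fitted on the
swapped landmark pairs; forward point mapping and inverse image mapping
are therefore consistent only up to the spline's invertibility, which
holds for the small distortions this stage is meant to absorb. Nearest
interpolation is the default for masks and density grids (value-range
preserving); out-of-domain samples receive an explicit fill value
(default 0). Landmarks are human-placed, read from CSV
(`x_src,y_src,x_dst,y_dst`, 0-based px). Per-ring λ is a config value —
deformation varies between rings and there is no universal default.

## Fusion

Registered density grids are stacked apex → base (slice 1 = apex) at the
sectioning thickness, default dz = 4 mm, one ring per reference slice.
Missing interior slices are linearly interpolated between the nearest
present neighbours (inverse-distance weights), terminal gaps copy the
nearest slice; interpolated voxels are bounded by their sources and
provenance is marked per slice. NIfTI export stores (x, y, z) data with
the spacing on the affine diagonal; the fill sentinel is −1 (valid
densities are ≥ 0).

## Spatial statistics

* **Entropy**: −Σ pᵢ ln pᵢ over the histogram of window densities across
  the fixed logarithmic bins, tissue-covered windows only. Densities
  below the lowest edge form their own category — dropping them would
  blind the statistic to how much of the section is near-empty, and
  near-empty windows dominate sparse slices. Natural log, so the maximum
  for k occupied categories is ln k.
* **Moran's I**: the standard double-sum with binary contiguity weights
  on the density-map lattice restricted to tissue-covered cells, both
  directions counted in W. Queen adjacency is the default (diagonal
  neighbours matter on coarse lattices); rook is an option. Constant
  grids, fewer than two valid cells, or no adjacent valid pair raise
  errors rather than returning a conventional value.
* **Mean NND**: fibre-mask pixels as points at their centres, k-d tree
  nearest-neighbour query, px units at the working downscale; 1 px is the
  lattice floor, so values near 1 indicate near-saturated packing.
* **Hotspot volume**: Σ of true window areas with density strictly above
  the threshold. The default threshold is the lowest edge of the top
  logarithmic bin; it is config-exposed because any fixed choice is a
  claim about what "high density" means for a given staining batch.
* **Profile**: per-region mean and 95% Student-t interval over the slices
  of the region; single-slice regions report the value with NaN bounds,
  identical slices give a zero-width interval.

All four statistics are invariant under grid rotation and (except NND's
dependence on pixel positions) under cell permutation, and each is tested
against an independent brute-force oracle.

## Phantom generator

The phantom emulates what the pipeline actually consumes: DAB-brown fibre
pixels (RGB 120,95,70 → HSV8 (15,106,120), strictly inside the default
range) on hematoxylin-like tissue (RGB 190,185,220, V=220 strictly above
the V bound) over white glass, so phantom classification is exact by
construction and every downstream number has a known truth. The default
truth model draws each tissue pixel as an independent Bernoulli variable
from a fibre-fraction field — appropriate because the density metric is a
pixel-count fraction; a curvilinear mode draws random smooth polylines
for visual realism when needed.

The heart stack assigns each slice a mean fibre fraction from a gradient.
In the default "sector" mode the slice's fibres concentrate in a hot
annular sector (p = 0.5) over a sparse background (p = 0.002), the sector
angle set so the tissue mean equals the gradient value: every slice then
contains an explicit high-density region, giving positive spatial
autocorrelation and a hotspot volume that tracks the gradient — the
spatial structure the statistics are designed to detect. A "uniform"
mode spreads the fraction evenly. The reference volume is a blurred
grayscale rendering of the stack at dz = 4 mm — a stand-in with the right
geometry and contrast, not an MRI simulation.

Default phantom study conditions: 400×400 px canvas at 8 µm/px (a
0.5 µm/px scan at downscale 16), annulus radii 60–140 px, 8 slices,
gradient 0.01 → 0.10, analysis windows of 0.01 mm² (12 px) for profile
statistics, hotspot threshold 0.05. Ring-reassembly phantoms use a
420×420 canvas with radii 50–170 px so that a 2 px seam loss stays under
the 1% area bound. Default ring placements use flips, 90°-multiple
rotations and integer translations, which are exactly invertible under
nearest-neighbour resampling; arbitrary-angle placements are supported
but cost a boundary-pixel band to double resampling.

What passing phantom tests does **not** show: robustness to staining
variability, pen marks, coverslip artefacts, fixation shrinkage (real
tissue loses substantial volume during processing), out-of-plane
sectioning, or landmark placement error — real deployments must
recalibrate the HSV range and mask thresholds per batch and validate
registration on their own landmarks.

## Determinism and degenerate inputs

All randomness flows through named, seedable generators; repeated
pipeline runs with the same config and seed produce byte-identical
CSV/JSON (and manifest checksums). Empty tissue masks are valid results;
empty density maps, constant grids and single-point patterns raise
explicit errors where the statistic is undefined. Edge rounding is
round-half-up for blending; interval membership is inclusive at both
bounds throughout.
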