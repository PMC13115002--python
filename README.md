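# nervemap

Three-dimensional mapping of myocardial innervation from immunostained
whole-slide images of serial heart sections.

## The problem

Cardiac nerve fibres (visualised with a pan-neuronal marker such as
UCHL-1/PGP9.5 as brown DAB chromogen on a blue hematoxylin counterstain)
are distributed heterogeneously through the ventricular wall. Quantifying
that distribution in 3-D requires a chain of steps that no single existing
tool covers: per-slide fibre quantification on gigapixel scans,
reassembly of each transverse myocardial ring from the fragments it was
split into for cassette embedding, registration of the reassembled rings
onto a reference anatomical volume (e.g. post-mortem MRI), fusion of the
registered density maps into a volume, and spatial statistics along the
apex → base axis. `nervemap` implements that chain as a tested Python
library with a thin CLI.

## Method

Per slide, at working resolution (native scan downscaled by an integer
factor, default 16):

1. **Tissue mask** — grayscale + Gaussian blur, keep pixels that are dark
   (below a brightness threshold) or lie on an intensity edge (Sobel
   gradient), drop small connected components, dilate.
2. **Fibre classification** — a pixel is a fibre iff it is tissue and its
   8-bit HSV value (H∈[0,179], S,V∈[0,255]) falls inside a calibrated
   range, default `H (0,80), S (12,125), V (31,162)`.
3. **Density map** — tile the binary fibre mask into windows of fixed
   physical area *A* (default 1 mm²; side `⌊√A·1000/mpp⌋` px); density is
   the fibre-pixel fraction per window. Rendered as a fixed logarithmic
   red scale blended over the histology at α = 0.3 with a window grid.
4. **Ring reassembly** — rigid placements (flip, rotation, translation)
   from a per-ring layout JSON; residual seam gaps are closed only if the
   change stays within 1% of the section area.
5. **Registration** — least-squares rigid/similarity (Procrustes) fit on
   paired landmarks, then a regularized thin-plate spline
   (λ = 0 interpolates; λ → ∞ tends to the best affine fit).
6. **Fusion & statistics** — registered density grids stacked apex → base
   at the ring thickness (4 mm), missing slices filled by inverse-distance
   interpolation; per slice: Shannon entropy of the density histogram
   (natural log over the fixed log bins), global Moran's I
   (binary rook/queen lattice weights,
   `I = (N/W)·Σ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σ(xᵢ−x̄)²`), mean nearest-neighbour
   distance of fibre pixels, and hotspot volume (total pixel area of
   windows whose density exceeds a high-density threshold), plus
   per-region means with 95% Student-t confidence intervals.

A seedable phantom generator (synthetic DAB/hematoxylin slides, fragmented
annuli, apex→base stacks with known fibre-fraction gradients) provides
exact ground truth for every stage.

## Worked example

`examples/05_innervation_profile.py` builds an 8-slice phantom heart whose
mean fibre fraction rises linearly from 1% (apex) to 10% (base) and runs
the full per-slice analysis:

```
 slice_index  entropy  morans_i  nnd_mean  hotspot_volume_px
           1   0.7078    0.3385    3.0923          1728.0000
           2   0.7831    0.7233    1.9710          3456.0000
           3   0.8711    0.8345    1.6122          4752.0000
           4   0.9174    0.8548    1.4214          6336.0000
           5   0.9603    0.8969    1.3035          7776.0000
           6   0.9865    0.9104    1.2562          9216.0000
           7   1.0920    0.9109    1.2701         10656.0000
           8   1.0651    0.9067    1.1735         11808.0000
```

Hotspot volume (px at the working downscale) increases strictly from apex
to base, recovering the imposed gradient; Moran's I is strongly positive
(fibres cluster in a high-density sector); mean NND falls towards the
1 px lattice floor as packing densifies; entropy rises as the density
histogram becomes more mixed. The other examples cover single-slide
density mapping, ring reassembly with seam refinement, landmark
registration, and NIfTI volume fusion — each prints the quantities it
computes.

The same pipeline is scriptable from a shell:

```bash
nervemap run --config pipeline.yaml            # slide→ring→register→fuse→stats
nervemap slide scan.svs --mpp 0.5 --out out/   # one slide only
nervemap phantom heart --n-slices 8 --out out/
```

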