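"""Apex -> base innervation profile of a phantom heart.

Eight annular slices with mean fibre fraction rising linearly from 1% at
the apex to 10% at the base, each slice carrying an explicit high-density
sector; the profile tabulates entropy, Moran's I, mean nearest-neighbour
distance and hotspot volume per slice, with per-region summaries.
"""

import numpy as np

from nervemap import (
    PhantomSpec,
    classify_fibers,
    compute_density_map,
    compute_tissue_mask,
    innervation_profile,
    make_phantom_heart,
)

spec = PhantomSpec(canvas=(400, 400), radii=(60, 140))
slides, reference, truth = make_phantom_heart(
    8, np.linspace(0.01, 0.10, 8), spec_template=spec, seed=1
)
print(f"reference volume {reference.voxels.shape}, dz = {reference.spacing[0]} mm")

entries = []
for i, (slide, _truth_mask) in enumerate(slides):
    tissue = compute_tissue_mask(slide)
    fibers = classify_fibers(slide, tissue)
    dm = compute_density_map(fibers, window_mm2=0.01, tissue=tissue.mask)
    entries.append((i + 1, dm, fibers))

table = innervation_profile(
    entries,
    region_spec={"apex": (1, 3), "mid": (4, 6), "base": (7, 8)},
    threshold=0.05,
)
print(table.slices.to_string(index=False,
                             float_format=lambda v: f"{v:.4f}"))
# entropy rises as the hot sector grows (more mixed histogram), Moran's I
# stays high (clustered hot region), NND falls (denser packing), and
# hotspot volume increases monotonically apex -> base
cols = ["region", "hotspot_volume_px_mean", "hotspot_volume_px_ci_lo",
        "hotspot_volume_px_ci_hi"]
print(table.regions[cols].to_string(index=False,
                                    float_format=lambda v: f"{v:.1f}"))
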