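"""Synthetic slides, fragmented rings and stacked reference volumes.

Every pipeline stage is testable without real scans: the phantom emulates
DAB-brown fibre structures on hematoxylin-blue tissue over white glass,
annular rings cut into angular fragments with known rigid displacements,
and an apex -> base stack with an imposed fibre-fraction gradient whose
blurred grayscale rendering stands in for the reference anatomical volume.

The default truth model draws each tissue pixel as a fibre independently
with probability given by a fibre-fraction field (Bernoulli), because the
density metric is a pixel-count fraction; a curvilinear mode draws random
smooth polylines instead for visual realism. Default stain colours sit
strictly inside (fibre) / outside (tissue, glass) the default HSV range,
so phantom pixel classification is exact by construction. All outputs are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .density import compute_density_map
from .fiber_detect import FiberMask
from .fusion import Volume3D, build_volume
from .ring import Fragment, FragmentLayout, FragmentPlacement, RingComposite, assemble_ring
from .slide_io import SlideImage
from .tissue_mask import luminance

__all__ = [
    "PhantomSpec",
    "make_phantom_slide",
    "make_phantom_ring",
    "make_phantom_heart",
    "inverse_placement",
    "FIBER_RGB",
    "TISSUE_RGB",
    "BACKGROUND_RGB",
]

# DAB-brown, strictly inside the default HSV range: HSV8 (15, 106, 120)
FIBER_RGB = (120, 95, 70)
# hematoxylin-like pale blue-violet, V = 220 > 162 so never fibre-classified
TISSUE_RGB = (190, 185, 220)
BACKGROUND_RGB = (255, 255, 255)


@dataclass
class PhantomSpec:
    """Recipe for one synthetic slide.

    canvas : (H, W) px of the working image
    mpp_eff : µm/px of the working image (default 8.0, i.e. a 0.5 µm/px
        scan downscaled 16x)
    geometry : "disc" | "annulus" | "half-annulus"
    radii : (inner, outer) px for annuli; (0, outer) for discs
    fiber_fraction : scalar in [0, 1] or an (H, W) field of per-pixel
        fibre probabilities
    curvilinear : draw random smooth polylines instead of Bernoulli pixels
    """

    seed: int = 0
    canvas: tuple[int, int] = (400, 400)
    mpp_eff: float = 8.0
    geometry: str = "annulus"
    radii: tuple[float, float] = (60.0, 140.0)
    fiber_fraction: float | np.ndarray = 0.05
    curvilinear: bool = False
    fiber_rgb: tuple[int, int, int] = FIBER_RGB
    tissue_rgb: tuple[int, int, int] = TISSUE_RGB
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB

    def __post_init__(self) -> None:
        if self.geometry not in ("disc", "annulus", "half-annulus"):
            raise ValueError("geometry must be disc, annulus or half-annulus")
        inner, outer = self.radii
        h, w = self.canvas
        if not (0 <= inner < outer):
            raise ValueError("radii must satisfy 0 <= inner < outer")
        if outer > min(h, w) / 2.0:
            raise ValueError("outer radius exceeds the canvas half-size")
        frac = np.asarray(self.fiber_fraction, dtype=np.float64)
        if frac.min() < 0 or frac.max() > 1:
            raise ValueError("fiber_fraction must lie in [0, 1]")


def _geometry_mask(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.canvas
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    inner, outer = spec.radii
    if spec.geometry == "disc":
        mask = r <= outer
    else:
        mask = (r >= inner) & (r <= outer)
        if spec.geometry == "half-annulus":
            mask &= yy <= cy
    return mask


def _fraction_field(spec: PhantomSpec) -> np.ndarray:
    frac = np.asarray(spec.fiber_fraction, dtype=np.float64)
    if frac.ndim == 0:
        return np.full(spec.canvas, float(frac))
    if frac.shape != tuple(spec.canvas):
        raise ValueError("fiber_fraction field shape must match the canvas")
    return frac


def _curvilinear_mask(tissue: np.ndarray, target_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Random smooth polylines inside the tissue until the requested
    fibre-pixel fraction is (approximately) reached."""
    fiber = np.zeros_like(tissue)
    goal = int(target_fraction * tissue.sum())
    rows, cols = np.nonzero(tissue)
    if len(rows) == 0 or goal == 0:
        return fiber
    attempts = 0
    while fiber.sum() < goal and attempts < 10_000:
        attempts += 1
        k = rng.integers(0, len(rows))
        y, x = float(rows[k]), float(cols[k])
        theta = rng.uniform(0, 2 * np.pi)
        for _ in range(int(rng.integers(20, 80))):
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < tissue.shape[0] and 0 <= ix < tissue.shape[1]) or not tissue[iy, ix]:
                break
            fiber[iy, ix] = True
            theta += rng.normal(0, 0.3)
            y += np.sin(theta)
            x += np.cos(theta)
    return fiber


def make_phantom_slide(spec: PhantomSpec) -> tuple[SlideImage, FiberMask]:
    """Render one synthetic slide and its exact fibre truth mask."""
    tissue = _geometry_mask(spec)
    if not tissue.any():
        raise ValueError("degenerate geometry: no tissue pixels")
    rng = np.random.default_rng(spec.seed)
    if spec.curvilinear:
        frac = _fraction_field(spec)
        fiber = _curvilinear_mask(tissue, float(frac[tissue].mean()), rng)
    else:
        fiber = tissue & (rng.random(spec.canvas) < _fraction_field(spec))
    img = np.empty(spec.canvas + (3,), dtype=np.uint8)
    img[:] = spec.background_rgb
    img[tissue] = spec.tissue_rgb
    img[fiber] = spec.fiber_rgb
    slide = SlideImage(
        pixels=img,
        mpp_base=spec.mpp_eff,
        downscale=1,
        source_id=f"phantom_seed{spec.seed}",
    )
    truth = FiberMask(mask=fiber, slide_ref=slide.source_id, mpp_eff=spec.mpp_eff)
    return slide, truth


def inverse_placement(pl: FragmentPlacement, shape: tuple[int, int]) -> FragmentPlacement:
    """The placement that undoes ``pl`` on a fragment of the given shape
    (square-canvas rigid placements compose in flip-then-rotate order)."""
    th = np.deg2rad(pl.rotation)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    fl = np.array([[-1.0, 0.0], [0.0, 1.0]]) if pl.flip else np.eye(2)
    a = rot @ fl
    a_inv = np.linalg.inv(a)
    t2 = -a_inv @ np.asarray(pl.translation, dtype=np.float64)
    if np.linalg.det(a_inv) > 0:
        flip2 = False
        rmat = a_inv
    else:
        flip2 = True
        rmat = a_inv @ np.array([[-1.0, 0.0], [0.0, 1.0]])
    theta2 = float(np.degrees(np.arctan2(rmat[1, 0], rmat[0, 0])))
    return FragmentPlacement(
        fragment_id=pl.fragment_id,
        translation=(float(t2[0]), float(t2[1])),
        rotation=theta2,
        flip=flip2,
        z_order=pl.z_order,
    )


def _default_displacements(n: int) -> list[tuple[tuple[int, int], float, bool]]:
    """Exactly invertible displacements (integer shifts, 90-degree
    rotations, one flip) cycling over the fragments."""
    out = []
    for i in range(n):
        dx = (-1) ** i * (5 + 3 * (i % 3))
        dy = (-1) ** (i // 2) * (4 + 2 * (i % 2))
        rot = 90.0 * (i % 4)
        flip = i % 3 == 2
        out.append(((dx, dy), rot, flip))
    return out


def make_phantom_ring(
    spec: PhantomSpec,
    n_fragments: int = 3,
    placements: list[FragmentPlacement] | None = None,
    seam_jitter: float = 0.0,
    window_mm2: float = 1.0,
) -> tuple[dict[str, Fragment], FragmentLayout, RingComposite]:
    """Cut a phantom annulus into angular fragments with known rigid
    displacements.

    Returns the displaced fragments, the layout that reassembles them
    (the exact inverse placements) and the uncut ground-truth composite.
    ``seam_jitter`` shaves tissue within jitter/2 px of each cut line to
    emulate processing losses (creating seam gaps for refinement to fix).
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    slide, truth_fibers = make_phantom_slide(spec)
    tissue = _geometry_mask(spec)
    h, w = spec.canvas
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
    r = np.hypot(yy - cy, xx - cx)
    sector = np.minimum((theta / (2 * np.pi) * n_fragments).astype(int), n_fragments - 1)

    cut_angles = [2 * np.pi * k / n_fragments for k in range(n_fragments)]
    keep = np.ones(spec.canvas, dtype=bool)
    if seam_jitter > 0 and n_fragments > 1:
        for phi in cut_angles:
            d_ang = np.abs(np.mod(theta - phi + np.pi, 2 * np.pi) - np.pi)
            keep &= (d_ang * r) >= seam_jitter / 2.0

    if placements is None:
        disp = _default_displacements(n_fragments)
        placements = [
            FragmentPlacement(f"frag{i}", translation=d[0], rotation=d[1], flip=d[2], z_order=i)
            for i, d in enumerate(disp)
        ]
    if len(placements) != n_fragments:
        raise ValueError("need one placement per fragment")

    from .ring import _place, _placement_matrix  # displaced-fragment rendering

    fragments: dict[str, Fragment] = {}
    layout_entries = []
    for i, pl in enumerate(placements):
        part = tissue & keep & (sector == i) if n_fragments > 1 else tissue
        fib = truth_fibers.mask & part
        img = np.empty(spec.canvas + (3,), dtype=np.uint8)
        img[:] = spec.background_rgb
        img[part] = spec.tissue_rgb
        img[fib] = spec.fiber_rgb
        a, t = _placement_matrix(pl, spec.canvas)
        fragments[pl.fragment_id] = Fragment(
            image=np.clip(_place(img, a, t, spec.canvas, 255.0), 0, 255).astype(np.uint8),
            fiber=_place(fib, a, t, spec.canvas, 0.0) > 0.5,
            tissue=_place(part, a, t, spec.canvas, 0.0) > 0.5,
        )
        layout_entries.append(inverse_placement(pl, spec.canvas))
    layout = FragmentLayout(
        ring_id=f"phantom_ring_seed{spec.seed}", fragments=layout_entries, canvas_size=spec.canvas
    )

    truth_density = compute_density_map(truth_fibers, window_mm2=window_mm2, tissue=tissue)
    truth = RingComposite(
        ring_id=layout.ring_id,
        image=slide.pixels,
        tissue=tissue,
        fiber=truth_fibers.mask,
        provenance=np.where(tissue, 0, -1).astype(np.int32),
        fragment_ids=["truth"],
        density=truth_density,
        mpp_eff=spec.mpp_eff,
        window_mm2=window_mm2,
    )
    return fragments, layout, truth


@dataclass
class HeartTruth:
    """Ground truth of a phantom heart stack: the per-slice mean fibre
    fractions and the full per-slice fibre-probability fields."""

    fractions: np.ndarray
    fields: list[np.ndarray]


def _sector_field(
    spec: PhantomSpec,
    mean_fraction: float,
    background: float,
    hot: float,
    center_angle: float,
) -> np.ndarray:
    """Fibre-probability field with an explicit high-density region: a hot
    annular sector (probability ``hot``) over a sparse background, with
    the sector's angular width set so the tissue-mean equals
    ``mean_fraction``. Models hotspots the way the density metric defines
    them (contiguous regions of elevated fibre fraction)."""
    if not background <= mean_fraction <= hot:
        raise ValueError("mean_fraction must lie between background and hot fractions")
    h, w = spec.canvas
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2(yy - cy, xx - cx)
    phi = 2 * np.pi * (mean_fraction - background) / (hot - background)
    d_ang = np.abs(np.mod(theta - center_angle + np.pi, 2 * np.pi) - np.pi)
    field = np.full(spec.canvas, background)
    field[d_ang <= phi / 2.0] = hot
    return field


def make_phantom_heart(
    n_slices: int,
    gradient: list[float] | np.ndarray,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
    dz_mm: float = 4.0,
    mode: str = "sector",
    background_fraction: float = 0.002,
    hot_fraction: float = 0.5,
) -> tuple[list[tuple[SlideImage, FiberMask]], Volume3D, HeartTruth]:
    """An apex -> base stack of phantom annulus slides whose per-slice
    mean fibre fraction follows ``gradient``.

    mode "sector" (default) concentrates the fibres of each slice in a hot
    annular sector over a sparse background, so every slice carries an
    explicit high-density region whose size tracks the gradient — a
    spatially structured distribution (clustered, positive spatial
    autocorrelation) resembling regional innervation. mode "uniform"
    spreads the fraction evenly over the tissue instead.

    Returns the per-slice (slide, truth fibre mask) pairs, a reference
    Volume3D built from blurred grayscale renderings of the slides (a
    stand-in anatomical volume at the stated slice spacing), and the
    ground truth (mean fractions + full probability fields).
    """
    if n_slices < 2:
        raise ValueError("a heart stack needs at least 2 slices")
    gradient = np.asarray(gradient, dtype=np.float64)
    if len(gradient) != n_slices:
        raise ValueError("gradient length must equal n_slices")
    if mode not in ("sector", "uniform"):
        raise ValueError("mode must be 'sector' or 'uniform'")
    template = spec_template or PhantomSpec()
    seeds = np.random.SeedSequence(seed).generate_state(n_slices) % (2**31)
    slides: list[tuple[SlideImage, FiberMask]] = []
    ref_slices = []
    fields: list[np.ndarray] = []
    for i in range(n_slices):
        if mode == "sector":
            field = _sector_field(
                template, float(gradient[i]), background_fraction, hot_fraction,
                center_angle=np.pi / 2.0,
            )
        else:
            field = np.full(template.canvas, float(gradient[i]))
        spec = PhantomSpec(
            seed=int(seeds[i]),
            canvas=template.canvas,
            mpp_eff=template.mpp_eff,
            geometry=template.geometry,
            radii=template.radii,
            fiber_fraction=field,
            curvilinear=template.curvilinear,
            fiber_rgb=template.fiber_rgb,
            tissue_rgb=template.tissue_rgb,
            background_rgb=template.background_rgb,
        )
        slide, truth = make_phantom_slide(spec)
        slides.append((slide, truth))
        fields.append(field)
        gray = luminance(slide.pixels) / 255.0
        ref_slices.append(ndimage.gaussian_filter(gray, sigma=2.0))
    ref = build_volume(
        ref_slices,
        dz=dz_mm,
        in_plane_spacing=template.mpp_eff / 1000.0,
        provenance=[f"slice_{i + 1}" for i in range(n_slices)],
    )
    return slides, ref, HeartTruth(fractions=gradient.copy(), fields=fields)
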