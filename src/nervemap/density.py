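"""Sliding-window fibre density maps and log-scaled heatmap rendering.

Density is the fraction of fibre pixels per analysis window. The window is
specified physically (mm², typically 1 mm²) and converted to pixels with
the effective microns-per-pixel, so maps from slides scanned at different
resolutions are directly comparable. Windows tile the mask without overlap
(a stride parameter allows overlapping maps); partial windows at the right
and bottom edges are normalised by their true pixel count, so borders do
not read artificially sparse.

Rendering blends a fixed logarithmic red palette over the histology at a
configurable opacity, with an optional window grid and legend strip. A
fixed scale keeps colours comparable across slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiber_detect import FiberMask
from .slide_io import SlideImage

__all__ = [
    "DensityMap",
    "HeatmapStyle",
    "window_px_from_mm2",
    "compute_density_map",
    "bin_density",
    "render_heatmap",
    "DEFAULT_BIN_EDGES",
]

# 8 bins spanning [1e-4, 1] at constant log spacing: lower edges
# 10^-4, 10^-3.5, ..., 10^-0.5; densities below 1e-4 are "background".
DEFAULT_BIN_EDGES: tuple[float, ...] = tuple(np.logspace(-4, -0.5, 8))

# light -> dark red, one colour per bin
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (255, 230, 220),
    (254, 211, 192),
    (252, 176, 152),
    (250, 137, 113),
    (243, 94, 79),
    (222, 45, 48),
    (176, 16, 34),
    (103, 0, 13),
)


def window_px_from_mm2(window_mm2: float, mpp_eff: float) -> int:
    """Window side length in pixels: floor(sqrt(area) * 1000 / mpp)."""
    if window_mm2 <= 0:
        raise ValueError("window_mm2 must be > 0")
    if mpp_eff <= 0:
        raise ValueError("mpp_eff must be > 0")
    w = int(np.sqrt(window_mm2) * 1000.0 / mpp_eff)
    if w < 1:
        raise ValueError(
            f"window of {window_mm2} mm^2 is smaller than one pixel at {mpp_eff} um/px"
        )
    return w


@dataclass
class DensityMap:
    """Per-window fibre-pixel fraction grid.

    grid : R x C densities in [0, 1]
    cell_area : R x C true pixel count per window (partial edge windows
        have smaller areas)
    tissue_frac : R x C fraction of each window covered by tissue, or None
    window_px : window side length in px; window_mm2 : physical window area
    origin : (row, col) slide pixel of grid cell (0, 0)
    """

    grid: np.ndarray
    cell_area: np.ndarray
    window_px: int
    window_mm2: float
    mpp_eff: float
    origin: tuple[int, int] = (0, 0)
    tissue_frac: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.cell_area = np.asarray(self.cell_area)
        if self.grid.shape != self.cell_area.shape:
            raise ValueError("grid and cell_area shapes differ")
        if self.grid.size and (self.grid.min() < 0 or self.grid.max() > 1):
            raise ValueError("densities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def fiber_pixels(self) -> float:
        """Total fibre pixel count implied by the map (exact for
        non-overlapping tiling: sum of density x cell area)."""
        return float(np.sum(self.grid * self.cell_area))


def _tile_sums(mask: np.ndarray, window: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window sums and true areas for a boolean grid."""
    h, w = mask.shape
    r0 = np.arange(0, h, stride)
    c0 = np.arange(0, w, stride)
    ii = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    ii = np.pad(ii, ((1, 0), (1, 0)))
    r1 = np.minimum(r0 + window, h)
    c1 = np.minimum(c0 + window, w)
    sums = (
        ii[np.ix_(r1, c1)]
        - ii[np.ix_(r0, c1)]
        - ii[np.ix_(r1, c0)]
        + ii[np.ix_(r0, c0)]
    )
    areas = np.outer(r1 - r0, c1 - c0)
    return sums, areas


def compute_density_map(
    fibers: FiberMask,
    window_mm2: float = 1.0,
    mpp_eff: float | None = None,
    tissue: np.ndarray | None = None,
    stride_px: int | None = None,
) -> DensityMap:
    """Tile the fibre mask into windows and compute per-window density.

    Parameters
    ----------
    fibers : binary fibre mask (downscaled slide coordinates).
    window_mm2 : physical window area; converted to a square window of
        ``floor(sqrt(area)*1000/mpp)`` px.
    mpp_eff : effective µm/px; defaults to ``fibers.mpp_eff``.
    tissue : optional tissue mask of the same shape; records the tissue
        coverage fraction per window (used by the spatial statistics).
    stride_px : window stride; defaults to the window size
        (non-overlapping tiling). Note the count-conservation identity
        sum(density x cell_area) == fibre pixel count holds only for the
        non-overlapping default.
    """
    mpp = mpp_eff if mpp_eff is not None else fibers.mpp_eff
    window = window_px_from_mm2(window_mm2, mpp)
    mask = fibers.mask
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("fibre mask must be a non-empty 2-D grid")
    stride = stride_px if stride_px is not None else window
    if stride < 1:
        raise ValueError("stride_px must be >= 1")
    sums, areas = _tile_sums(mask, window, stride)
    grid = sums / areas
    tf = None
    if tissue is not None:
        tissue = np.asarray(tissue).astype(bool)
        if tissue.shape != mask.shape:
            raise ValueError("tissue mask shape differs from fibre mask")
        tsums, _ = _tile_sums(tissue, window, stride)
        tf = tsums / areas
    return DensityMap(
        grid=grid,
        cell_area=areas,
        window_px=window,
        window_mm2=window_mm2,
        mpp_eff=mpp,
        tissue_frac=tf,
    )


@dataclass
class HeatmapStyle:
    """Fixed logarithmic colour scale for heatmap overlays.

    bin_edges are ascending lower edges; a density below the first edge
    falls in a designated background bin (index -1) and is not painted.
    """

    alpha: float = 0.3
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    palette: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE
    draw_grid: bool = True
    draw_legend: bool = False
    grid_color: tuple[int, int, int] = (90, 90, 90)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 1:
            raise ValueError("bin_edges must be a non-empty 1-D sequence")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if edges[0] < 0 or edges[-1] > 1:
            raise ValueError("bin_edges must lie within [0, 1]")
        if len(self.palette) != len(edges):
            raise ValueError("palette length must equal the number of bins")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


def bin_density(d: float | np.ndarray, style: HeatmapStyle) -> int | np.ndarray:
    """Largest bin index i with bin_edges[i] <= d; -1 = background bin.

    Lower edges are inclusive: d exactly on an edge belongs to that bin.
    """
    edges = np.asarray(style.bin_edges)
    idx = np.searchsorted(edges, d, side="right") - 1
    if np.isscalar(d) or np.ndim(d) == 0:
        return int(idx)
    return idx


def render_heatmap(slide: SlideImage, dm: DensityMap, style: HeatmapStyle | None = None) -> np.ndarray:
    """Alpha-blend the binned density colours over the histology image.

    out = round_half_up(alpha * heat + (1 - alpha) * base) inside cells
    above the background bin; the base image is untouched elsewhere. Grid
    lines are drawn at window boundaries when ``draw_grid``; a legend strip
    is appended on the right when ``draw_legend``.
    """
    style = style or HeatmapStyle()
    base = slide.pixels
    h, w = base.shape[:2]
    expected_rows = -(-h // dm.window_px)
    expected_cols = -(-w // dm.window_px)
    if dm.shape != (expected_rows, expected_cols):
        raise ValueError(
            f"density map {dm.shape} does not tile a {h}x{w} slide "
            f"with {dm.window_px}px windows"
        )
    out = base.astype(np.float64).copy()
    bins = bin_density(dm.grid, style)
    win = dm.window_px
    for (r, c), b in np.ndenumerate(bins):
        if b < 0:
            continue
        heat = np.array(style.palette[b], dtype=np.float64)
        y0, x0 = r * win, c * win
        y1, x1 = min(y0 + win, h), min(x0 + win, w)
        out[y0:y1, x0:x1] = style.alpha * heat + (1.0 - style.alpha) * out[y0:y1, x0:x1]
    out = np.floor(out + 0.5).clip(0, 255).astype(np.uint8)
    if style.draw_grid:
        gc = np.array(style.grid_color, dtype=np.uint8)
        out[::win, :] = gc
        out[:, ::win] = gc
    if style.draw_legend:
        out = np.concatenate([out, _legend_strip(h, style)], axis=1)
    return out


def _legend_strip(height: int, style: HeatmapStyle) -> np.ndarray:
    """Vertical strip of the palette, darkest (highest density) on top."""
    n = len(style.palette)
    strip = np.full((height, 24, 3), 255, dtype=np.uint8)
    box = max(1, height // max(n, 1))
    for i, colour in enumerate(reversed(style.palette)):
        y0 = i * box
        y1 = min((i + 1) * box, height)
        strip[y0:y1, 4:20] = colour
    return strip
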