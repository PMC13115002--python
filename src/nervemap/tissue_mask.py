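"""Tissue-versus-glass segmentation on the downscaled slide.

A pixel counts as tissue when it is dark (blurred grayscale below a
brightness threshold) or lies on an intensity edge (Sobel gradient above a
gradient threshold); small connected components are discarded and the
surviving mask is dilated so that fibres at tissue borders are not lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .slide_io import SlideImage

__all__ = ["MaskParams", "TissueMask", "compute_tissue_mask", "filter_components"]

# 8-connectivity structuring element for component labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class MaskParams:
    """Parameters of the background-removal stage.

    blur_sigma : Gaussian blur std-dev in px (>= 0)
    brightness_max : grayscale threshold in 0-255; darker pixels are tissue
    gradient_min : Sobel gradient-magnitude threshold (>= 0)
    min_area_px : connected components smaller than this are removed
    dilate_radius : binary dilation radius in px applied last
    combine : "or" (default) keeps dark OR edge pixels; "and" requires both
    """

    blur_sigma: float = 2.0
    brightness_max: float = 220.0
    gradient_min: float = 10.0
    min_area_px: int = 500
    dilate_radius: int = 3
    combine: str = "or"

    def __post_init__(self) -> None:
        if self.blur_sigma < 0 or self.gradient_min < 0:
            raise ValueError("blur_sigma and gradient_min must be >= 0")
        if not 0 <= self.brightness_max <= 255:
            raise ValueError("brightness_max must be in [0, 255]")
        if self.min_area_px < 0 or self.dilate_radius < 0:
            raise ValueError("min_area_px and dilate_radius must be >= 0")
        if self.combine not in ("or", "and"):
            raise ValueError("combine must be 'or' or 'and'")


@dataclass
class TissueMask:
    mask: np.ndarray  # H x W bool, aligned with the slide raster
    params: MaskParams = field(default_factory=MaskParams)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec.601 luma 0.299 R + 0.587 G + 0.114 B as float."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114


def filter_components(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    """Remove 8-connected components with area < ``min_area_px`` (inclusive
    threshold: a component of exactly ``min_area_px`` pixels survives)."""
    mask = np.asarray(mask).astype(bool)
    if min_area_px <= 1 or not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area_px
    keep[0] = False
    return keep[labels]


def compute_tissue_mask(slide: SlideImage, params: MaskParams | None = None) -> TissueMask:
    """Segment intact tissue from glass/background.

    Pipeline: grayscale -> Gaussian blur -> (brightness < max) OR
    (Sobel gradient >= min) -> small-component removal -> dilation.
    An empty mask is a valid result (e.g. a blank slide).
    """
    params = params or MaskParams()
    gray = luminance(slide.pixels)
    if params.blur_sigma > 0:
        gray = ndimage.gaussian_filter(gray, sigma=params.blur_sigma)
    gx = ndimage.sobel(gray, axis=1)
    gy = ndimage.sobel(gray, axis=0)
    grad = np.hypot(gx, gy)
    dark = gray < params.brightness_max
    edge = grad >= params.gradient_min
    # zero-gradient everywhere (flat image) carries no edge information:
    # a uniform bright field must stay background even if gradient_min == 0
    if params.gradient_min == 0:
        edge &= grad > 0
    mask = (dark | edge) if params.combine == "or" else (dark & edge)
    mask = filter_components(mask, params.min_area_px)
    if params.dilate_radius > 0 and mask.any():
        r = params.dilate_radius
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        selem = (yy * yy + xx * xx) <= r * r
        mask = ndimage.binary_dilation(mask, structure=selem)
    return TissueMask(mask=mask, params=params)
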