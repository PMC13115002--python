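"""Nerve-fiber pixel classification by HSV range filtering.

DAB chromogen (brown) on a hematoxylin counterstain separates well in HSV
space. The 8-bit convention used throughout is H in 0-179 (half-degrees)
and S, V in 0-255, which matches the magnitudes of the default range
``H (0,80), S (12,125), V (31,162)``. That range is calibrated per staining
batch/scanner in practice, so it is a required parameter with these values
as the default, not a constant.

Classification is restricted to the tissue mask: a fibre pixel is a tissue
pixel whose H, S and V each fall inside the configured closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .slide_io import SlideImage, effective_mpp
from .tissue_mask import TissueMask

__all__ = ["HsvRange", "FiberMask", "rgb_to_hsv8", "classify_fibers", "DEFAULT_HSV_RANGE"]


@dataclass(frozen=True)
class HsvRange:
    """Closed per-channel intervals on the 8-bit HSV scales.

    h on 0-179, s and v on 0-255; lo <= hi per channel (no hue wraparound:
    DAB brown does not cross the hue origin under this convention).
    """

    h: tuple[int, int] = (0, 80)
    s: tuple[int, int] = (12, 125)
    v: tuple[int, int] = (31, 162)

    def __post_init__(self) -> None:
        for name, (lo, hi), top in (("h", self.h, 179), ("s", self.s, 255), ("v", self.v, 255)):
            if not (0 <= lo <= hi <= top):
                raise ValueError(f"invalid {name} bounds ({lo},{hi}); need 0 <= lo <= hi <= {top}")


DEFAULT_HSV_RANGE = HsvRange()


@dataclass
class FiberMask:
    """Binary grid of fibre-classified pixels in downscaled slide coordinates."""

    mask: np.ndarray  # H x W bool
    slide_ref: str = ""
    mpp_eff: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if not self.mpp_eff > 0:
            raise ValueError("mpp_eff must be > 0")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def rgb_to_hsv8(image: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB to 8-bit HSV: H in [0,179], S and V in [0,255].

    V = max(R,G,B); S = round(255 * (V - min) / V) (0 where V = 0);
    H = round(hue_degrees / 2) mod 180. Achromatic pixels get H = S = 0.
    """
    rgb = np.asarray(image)
    if rgb.dtype != np.uint8:
        raise ValueError("expected 8-bit RGB input")
    f = rgb.astype(np.float64)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    v = np.max(f, axis=-1)
    mn = np.min(f, axis=-1)
    delta = v - mn

    s = np.zeros_like(v)
    nz = v > 0
    s[nz] = 255.0 * delta[nz] / v[nz]

    h = np.zeros_like(v)
    d = delta.copy()
    d[d == 0] = 1.0  # avoid 0/0; h stays 0 where delta == 0
    chroma = delta > 0
    is_r = chroma & (v == r)
    is_g = chroma & ~is_r & (v == g)
    is_b = chroma & ~is_r & ~is_g
    h[is_r] = 30.0 * (g[is_r] - b[is_r]) / d[is_r]
    h[is_g] = 60.0 + 30.0 * (b[is_g] - r[is_g]) / d[is_g]
    h[is_b] = 120.0 + 30.0 * (r[is_b] - g[is_b]) / d[is_b]
    h = np.mod(np.rint(h), 180.0)

    out = np.empty(rgb.shape[:-1] + (3,), dtype=np.uint8)
    out[..., 0] = h.astype(np.uint8)
    out[..., 1] = np.rint(s).astype(np.uint8)
    out[..., 2] = np.rint(v).astype(np.uint8)
    return out


def classify_fibers(
    slide: SlideImage,
    tissue: TissueMask,
    hsv_range: HsvRange = DEFAULT_HSV_RANGE,
) -> FiberMask:
    """Binary fibre mask: tissue pixels whose HSV lies inside ``hsv_range``.

    Classification is performed exclusively within the tissue mask; spatial
    coordinates are preserved relative to the (downscaled) slide.
    """
    if tissue.mask.shape != slide.shape:
        raise ValueError(
            f"tissue mask shape {tissue.mask.shape} != slide shape {slide.shape}"
        )
    hsv = rgb_to_hsv8(slide.pixels)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    inside = (
        (h >= hsv_range.h[0]) & (h <= hsv_range.h[1])
        & (s >= hsv_range.s[0]) & (s <= hsv_range.s[1])
        & (v >= hsv_range.v[0]) & (v <= hsv_range.v[1])
    )
    return FiberMask(
        mask=inside & tissue.mask,
        slide_ref=slide.source_id,
        mpp_eff=effective_mpp(slide),
    )
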