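"""Whole-slide and plain raster image IO with physical resolution metadata.

Slides are held as 8-bit RGB arrays together with the microns-per-pixel
(mpp) of the native scan and the integer downscale factor applied to it.
All downstream physical arithmetic (window sizes in mm², nearest-neighbour
distances in µm) flows from ``effective_mpp``.

Coordinates are 0-based, row-major, origin at the top-left; physical
quantities are in µm and mm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image

__all__ = ["SlideImage", "load_slide", "save_png", "effective_mpp"]

# PIL refuses very large rasters by default; whole-slide scans are large by
# design, so raise the ceiling rather than silently failing on real data.
Image.MAX_IMAGE_PIXELS = None


@dataclass
class SlideImage:
    """An RGB slide raster plus its resolution metadata.

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3), dtype uint8
        The image at the current downscale.
    mpp_base : float
        Microns per pixel at the native (downscale=1) resolution. > 0.
    downscale : int
        Integer factor by which ``pixels`` is coarser than native. >= 1.
    source_id : str
        Opaque identifier of the originating file or phantom.
    """

    pixels: np.ndarray
    mpp_base: float
    downscale: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1 x 1")
        if not self.mpp_base > 0:
            raise ValueError("mpp_base must be > 0")
        if int(self.downscale) != self.downscale or self.downscale < 1:
            raise ValueError("downscale must be an integer >= 1")
        self.downscale = int(self.downscale)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def effective_mpp(slide: SlideImage) -> float:
    """Microns per pixel of the working (downscaled) raster."""
    return slide.mpp_base * slide.downscale


def _box_resize(rgb: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Area (box) resampling to an exact output shape.

    Box filtering averages source pixels per output pixel, which preserves
    the mean stain fraction that the density metric depends on.
    """
    if rgb.shape[:2] == (out_h, out_w):
        return rgb
    im = Image.fromarray(rgb, mode="RGB")
    return np.asarray(im.resize((out_w, out_h), resample=Image.BOX))


def _read_tiff(path: str, downscale: int) -> tuple[np.ndarray, float | None]:
    """Read a (possibly pyramidal) TIFF: nearest coarser pyramid level,
    then box resampling to the exact requested factor."""
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        levels = getattr(series, "levels", [series])
        base_shape = levels[0].shape
        base_h = base_shape[0] if len(base_shape) >= 2 else 1
        # pick the coarsest level whose downsample does not exceed the request
        chosen, chosen_factor = levels[0], 1.0
        for lvl in levels:
            f = base_h / lvl.shape[0]
            if f <= downscale + 1e-9 and f > chosen_factor:
                chosen, chosen_factor = lvl, f
        arr = chosen.asarray()
        mpp = _tiff_mpp(tf)
    arr = _as_rgb8(arr)
    return arr, mpp


def _tiff_mpp(tf: "tifffile.TiffFile") -> float | None:
    page = tf.pages[0]
    # Aperio-style: mpp embedded in the ImageDescription
    desc = page.description or ""
    for token in desc.replace("\n", "|").split("|"):
        token = token.strip()
        if token.upper().startswith("MPP"):
            try:
                return float(token.split("=")[1])
            except (IndexError, ValueError):
                pass
    tags = page.tags
    if "XResolution" in tags and "ResolutionUnit" in tags:
        num, den = tags["XResolution"].value
        if num:
            px_per_unit = num / den
            unit = tags["ResolutionUnit"].value
            unit = getattr(unit, "value", unit)
            if unit == 2:  # inch
                return 25400.0 / px_per_unit
            if unit == 3:  # centimetre
                return 10000.0 / px_per_unit
    return None


def _as_rgb8(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return np.ascontiguousarray(arr)


def _read_raster(path: str) -> tuple[np.ndarray, float | None]:
    im = Image.open(path)
    mpp = None
    dpi = im.info.get("dpi")
    if dpi and dpi[0]:
        mpp = 25400.0 / float(dpi[0])
    arr = _as_rgb8(np.asarray(im.convert("RGB")))
    return arr, mpp


def load_slide(
    path: str | os.PathLike,
    downscale: int = 1,
    mpp: float | None = None,
    source_id: str | None = None,
) -> SlideImage:
    """Load a slide image, downscale it, and attach resolution metadata.

    Parameters
    ----------
    path : path to a pyramidal/plain TIFF (``.tif``, ``.tiff``, ``.svs``)
        or any raster readable by Pillow (e.g. PNG).
    downscale : integer factor >= 1; the output raster has shape
        ``ceil-free round(H / downscale)`` via box resampling after the
        nearest coarser pyramid level is selected.
    mpp : optional microns-per-pixel override. Required when the file
        carries no resolution metadata.

    Raises
    ------
    ValueError
        If ``downscale < 1`` or no mpp is available from either the file
        or the ``mpp`` argument.
    FileNotFoundError
        If ``path`` does not exist.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if int(downscale) != downscale or downscale < 1:
        raise ValueError("downscale must be an integer >= 1")
    downscale = int(downscale)

    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff", ".svs"):
        arr, file_mpp = _read_tiff(path, downscale)
        # _read_tiff may return a coarser pyramid level; resize from what we got
    else:
        arr, file_mpp = _read_raster(path)

    mpp_base = mpp if mpp is not None else file_mpp
    if mpp_base is None:
        raise ValueError(
            f"missing mpp: {path!r} carries no resolution metadata; "
            "pass mpp= explicitly"
        )

    if ext in (".tif", ".tiff", ".svs"):
        # target shape is defined w.r.t. the native level
        with tifffile.TiffFile(path) as tf:
            base_shape = tf.series[0].levels[0].shape if hasattr(tf.series[0], "levels") else tf.series[0].shape
        h0, w0 = base_shape[0], base_shape[1]
    else:
        h0, w0 = arr.shape[0], arr.shape[1]
    out_h = max(1, round(h0 / downscale))
    out_w = max(1, round(w0 / downscale))
    arr = _box_resize(arr, out_h, out_w)

    return SlideImage(
        pixels=arr,
        mpp_base=float(mpp_base),
        downscale=downscale,
        source_id=source_id or os.path.basename(path),
    )


def save_png(slide: SlideImage, path: str | os.PathLike) -> None:
    """Write the slide raster as an 8-bit RGB PNG (lossless)."""
    Image.fromarray(slide.pixels, mode="RGB").save(os.fspath(path), format="PNG")
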