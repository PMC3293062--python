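"""Micrograph I/O, gray-scale conversion and gray-level quantization.

Histology fields are acquired as 24-bit RGB rasters (the study design this
package emulates used 744 x 744 px BMP micrographs).  All texture statistics
downstream operate on a single-channel, integer-quantized raster, so this
module owns the three preprocessing steps: reading the file, collapsing RGB
to luminance, and mapping the luminance range onto a small number of gray
levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "RGBImage",
    "GrayImage",
    "ALLOWED_LEVELS",
    "read_image",
    "to_gray",
    "quantize",
]

#: Admissible quantization depths.  Fewer than 16 levels destroys the
#: co-occurrence statistics of cell-scale structure; more than 256 is
#: meaningless for 8-bit sources.
ALLOWED_LEVELS = (16, 32, 64, 128, 256)

#: Minimum side length for which texture matrices are still meaningful.
MIN_SIZE = 16

# ITU-R BT.601 luminance weights; fixed so features are bit-reproducible.
_LUMA = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit-per-channel RGB raster of shape (H, W, 3)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) array, got shape {px.shape}")
        if px.shape[0] < MIN_SIZE or px.shape[1] < MIN_SIZE:
            raise ValueError(
                f"image is {px.shape[0]}x{px.shape[1]}; texture statistics need "
                f"at least {MIN_SIZE}x{MIN_SIZE}"
            )
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """A quantized gray-level raster.

    Parameters
    ----------
    pixels
        (H, W) integer array with values in ``[0, levels - 1]``.
    levels
        Number of gray levels after quantization; one of `ALLOWED_LEVELS`.
    source_range
        The (min, max) source intensities that were mapped onto
        ``[0, levels - 1]``; recorded for provenance.
    """

    pixels: np.ndarray
    levels: int = 256
    source_range: tuple[float, float] = field(default=(0.0, 255.0))

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {px.shape}")
        if self.levels not in ALLOWED_LEVELS:
            raise ValueError(f"levels must be one of {ALLOWED_LEVELS}, got {self.levels}")
        if px.size and (px.min() < 0 or px.max() > self.levels - 1):
            raise ValueError(f"pixel values must lie in [0, {self.levels - 1}]")
        object.__setattr__(self, "pixels", px.astype(np.int64))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_image(path: str | Path) -> RGBImage:
    """Read a BMP or PNG micrograph as an `RGBImage`.

    8-bit grayscale files are promoted to three identical channels.  Corrupt
    or unreadable files raise ``IOError`` naming the path; images smaller
    than 16 x 16 raise ``ValueError``.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode != "RGB":
                im = im.convert("RGB")
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    return RGBImage(arr)


def to_gray(img: RGBImage) -> GrayImage:
    """Collapse RGB to 256-level luminance, 0.299 R + 0.587 G + 0.114 B.

    Rounding is half-up to the nearest integer so the conversion is exact
    and platform-independent.  Pixels with R = G = B keep their value.
    """
    px = img.pixels.astype(np.float64)
    lum = _LUMA[0] * px[..., 0] + _LUMA[1] * px[..., 1] + _LUMA[2] * px[..., 2]
    gray = np.floor(lum + 0.5).astype(np.int64)
    return GrayImage(gray, levels=256, source_range=(0.0, 255.0))


def quantize(img: GrayImage, levels: int = 64, mode: str = "minmax") -> GrayImage:
    """Requantize a gray image to ``levels`` gray levels.

    Modes
    -----
    ``"minmax"``
        Linear map of the observed ``[min, max]`` onto ``[0, levels - 1]``.
        A constant image maps to all zeros.
    ``"3sigma"``
        Linear map of ``[mean - 3 sd, mean + 3 sd]`` onto ``[0, levels - 1]``
        with clipping of the tails.
    ``"none"``
        Plain integer rescale from the nominal ``[0, 255]`` range; with
        ``levels=256`` this is the identity.
    """
    if levels not in ALLOWED_LEVELS:
        raise ValueError(f"levels must be one of {ALLOWED_LEVELS}, got {levels}")
    if mode not in ("minmax", "3sigma", "none"):
        raise ValueError(f"unknown normalization mode {mode!r}")

    px = img.pixels
    if mode == "none":
        if img.levels != 256:
            raise ValueError('mode "none" expects a 256-level source image')
        out = (px * levels) // 256
        return GrayImage(out, levels=levels, source_range=(0.0, 255.0))

    if mode == "minmax":
        lo, hi = float(px.min()), float(px.max())
        if hi == lo:  # constant image: degenerate range rule
            return GrayImage(np.zeros_like(px), levels=levels, source_range=(lo, hi))
        # equal-width bins over [lo, hi]; the top value alone would land in
        # bin `levels`, so it is folded back into levels-1
        out = np.floor((px - lo) * levels / (hi - lo)).astype(np.int64)
        out = np.minimum(out, levels - 1)
        return GrayImage(out, levels=levels, source_range=(lo, hi))

    # 3sigma
    mu = float(px.mean())
    sigma = float(px.std())
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    if sigma == 0.0:
        return GrayImage(np.zeros_like(px), levels=levels, source_range=(lo, hi))
    out = np.floor((px - lo) * levels / (hi - lo)).astype(np.int64)
    out = np.clip(out, 0, levels - 1)
    return GrayImage(out, levels=levels, source_range=(lo, hi))
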