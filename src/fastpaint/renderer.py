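"""Render localization tables into oversampled histogram images.

A super-resolution reconstruction of an SMLM experiment is, at its simplest,
a 2D histogram: the camera field of view is divided into an oversampled grid
(here 16 super-resolution pixels per camera pixel) and each localization
increments the bin containing it.  Bins are half-open, ``[k, k+1)`` in
super-resolution pixel units, so a localization at camera coordinate
``(x, y)`` lands in column ``floor(x * oversampling)`` and row
``floor(y * oversampling)``; a point exactly on the right or bottom FOV edge
is out of FOV and dropped.  Pixel values are counts, clipped to the 16-bit
range on output; before clipping the pixel sum equals the number of in-FOV
localizations.

The widefield (diffraction-limited) companion image lives on the camera grid
and is upscaled by integer block replication to the same super-resolution
grid so the two can be compared and fed to the network pixel-aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage

from fastpaint.errors import FormatError
from fastpaint.localization_io import LocalizationTable

logger = logging.getLogger(__name__)

U16_MAX = 65535


@dataclass(frozen=True)
class RenderConfig:
    """Rendering geometry: oversampling factor and output bit depth."""

    oversampling: int = 16
    bit_depth: int = 16

    def __post_init__(self):
        if self.oversampling < 1:
            raise ValueError(f"oversampling must be >= 1, got {self.oversampling}")
        if self.bit_depth != 16:
            raise ValueError("only 16-bit output is supported")

    def output_shape(self, fov_width: int, fov_height: int) -> tuple[int, int]:
        """(rows, cols) of the super-resolution grid for a given FOV."""
        return fov_height * self.oversampling, fov_width * self.oversampling


@dataclass
class RenderedImage:
    """A 2D grayscale image on the super-resolution grid.

    ``grid_scale`` is the oversampling relative to camera pixels (1 for a
    native camera-resolution image); ``role`` tags the image as one of
    ``ground_truth``, ``sparse`` or ``widefield``.
    """

    pixels: np.ndarray
    grid_scale: int
    role: str = "ground_truth"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("RenderedImage requires a 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def render_counts(table: LocalizationTable, config: RenderConfig = RenderConfig()) -> np.ndarray:
    """Raw (unclipped) int64 histogram of localizations on the SR grid."""
    h, w = config.output_shape(table.fov_width, table.fov_height)
    counts = np.zeros((h, w), dtype=np.int64)
    if len(table) == 0:
        return counts
    s = config.oversampling
    cols = np.floor(table.locs["x"].astype(np.float64) * s).astype(np.int64)
    rows = np.floor(table.locs["y"].astype(np.float64) * s).astype(np.int64)
    inside = (cols >= 0) & (cols < w) & (rows >= 0) & (rows < h)
    np.add.at(counts, (rows[inside], cols[inside]), 1)
    return counts


def render_histogram(
    table: LocalizationTable,
    config: RenderConfig = RenderConfig(),
    role: str = "ground_truth",
) -> RenderedImage:
    """Histogram-render a localization table to a 16-bit SR image.

    Each localization increments exactly one pixel (half-open bins, floor);
    counts are clipped to 65535 afterwards.  Rendering is additive and
    permutation-invariant in the record order.
    """
    counts = render_counts(table, config)
    clipped = np.minimum(counts, U16_MAX).astype(np.uint16)
    return RenderedImage(clipped, grid_scale=config.oversampling, role=role)


def upscale_widefield(image, factor: int = 16, method: str = "nearest") -> RenderedImage:
    """Upscale a camera-resolution widefield image onto the SR grid.

    The widefield image must be scaled by the oversampling factor (16 by
    default) so its grid matches the rendered reconstruction.  Nearest-
    neighbour block replication is the default (each camera pixel becomes a
    ``factor x factor`` block, values untouched); ``method="bilinear"``
    smooths instead.
    """
    if isinstance(image, RenderedImage):
        image = image.pixels
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("widefield image must be 2D")
    if int(factor) != factor or factor < 1:
        raise ValueError(f"upscaling factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if method == "nearest":
        out = np.repeat(np.repeat(image, factor, axis=0), factor, axis=1)
    elif method == "bilinear":
        out = ndimage.zoom(image.astype(np.float64), factor, order=1)
        if np.issubdtype(image.dtype, np.integer):
            out = np.clip(np.rint(out), 0, U16_MAX).astype(image.dtype)
    else:
        raise ValueError(f"unknown upscaling method {method!r}")
    return RenderedImage(out, grid_scale=factor, role="widefield")


def save_tiff(image, path) -> None:
    """Write a 16-bit single-channel grayscale TIFF (lossless)."""
    if isinstance(image, RenderedImage):
        image = image.pixels
    image = np.asarray(image)
    if image.ndim != 2:
        raise FormatError("only single-channel 2D images can be saved")
    if image.dtype != np.uint16:
        if np.issubdtype(image.dtype, np.integer) and image.min() >= 0 and image.max() <= U16_MAX:
            image = image.astype(np.uint16)
        else:
            raise FormatError(f"expected uint16 pixels, got dtype {image.dtype}")
    tifffile.imwrite(path, image, photometric="minisblack")


def load_tiff(path, role: str = "ground_truth") -> RenderedImage:
    """Load a grayscale TIFF as a 16-bit :class:`RenderedImage`.

    8-bit input is promoted to 16-bit with values unchanged (and a logged
    warning); multi-channel or floating-point TIFFs are rejected.
    """
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel grayscale TIFF, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        logger.warning("%s: 8-bit TIFF promoted to 16-bit (values unchanged)", path)
        arr = arr.astype(np.uint16)
    elif arr.dtype != np.uint16:
        raise FormatError(f"{path}: unsupported TIFF dtype {arr.dtype} (need uint8/uint16 grayscale)")
    return RenderedImage(arr, grid_scale=1, role=role)
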