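"""Calibrated image and ROI input/output.

Images are grayscale TIFFs; multi-plane stacks are flattened by
maximum-intensity projection (the standard reduction for sparse bright
vasculature) before any analysis.  The physical pixel size in µm/pixel is
taken from TIFF resolution metadata when present and can always be
overridden; analysis never silently assumes a calibration.

The region of interest (the manually delineated lobe border) is an input —
a binary mask image congruent with the intensity image — not something the
pipeline computes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class CalibratedImage:
    """A 2D intensity raster with a physical pixel size (µm/pixel)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D raster")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size**2


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Pixel size in µm/pixel from TIFF resolution tags, if stored."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    pixels_per_unit = num / den
    unit_tag = tags.get("ResolutionUnit")
    unit = getattr(unit_tag, "value", None)
    # ImageJ-style TIFFs carry the unit in the ImageJ metadata block
    ij = tif.imagej_metadata or {}
    ij_unit = ij.get("unit", "")
    if ij_unit in ("um", "µm", "micron", "micrometer"):
        return 1.0 / pixels_per_unit
    if unit is not None and getattr(unit, "name", str(unit)).upper() in (
        "CENTIMETER",
        "3",
    ):
        return 1e4 / pixels_per_unit
    return None


def read_image(path, pixel_size_override: float | None = None) -> CalibratedImage:
    """Read a single- or multi-plane grayscale TIFF as a calibrated 2D image.

    Multi-plane stacks are flattened by per-pixel maximum-intensity
    projection over the plane axis.  The pixel size is taken from the file's
    resolution metadata; ``pixel_size_override`` (µm/pixel) takes precedence
    when given.  A file with no usable calibration and no override raises a
    ``ValueError`` rather than assuming 1 µm/pixel.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_px = _pixel_size_from_tiff(tif)
    data = np.asarray(data)
    if data.ndim == 3:
        data = data.max(axis=0)
    elif data.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2D image or plane stack, got ndim={data.ndim}")
    pixel_size = pixel_size_override if pixel_size_override is not None else meta_px
    if pixel_size is None:
        raise ValueError(
            f"{path.name}: no pixel size in TIFF metadata; pass pixel_size_override"
        )
    return CalibratedImage(data.astype(float), float(pixel_size))


def read_roi(path, image: CalibratedImage) -> np.ndarray:
    """Read a binary ROI mask congruent with ``image``.

    Any nonzero pixel is inside the ROI.  Raises on shape mismatch or on an
    empty ROI (an all-background mask cannot normalise any density).
    """
    path = Path(path)
    mask = np.asarray(tifffile.imread(path))
    if mask.ndim == 3:
        mask = mask.max(axis=0)
    if mask.shape != image.shape:
        raise ValueError(
            f"{path.name}: ROI shape {mask.shape} does not match image {image.shape}"
        )
    roi = mask != 0
    if not roi.any():
        raise ValueError(f"{path.name}: empty ROI")
    return roi


def roi_area_um2(roi: np.ndarray, pixel_size: float) -> float:
    """Physical ROI area: foreground pixel count x pixel_size^2."""
    return float(roi.sum()) * pixel_size**2
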