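"""Raster containers shared across the pipeline.

Images are plain 2-D float arrays with a physical calibration (µm per
pixel) and a provenance trail recording the operations applied so far.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default spatial calibration in µm per pixel.  Derived from the printed
#: size-filter pair: a 5,000-pixel minimum colony area corresponds to
#: 33,282 µm², hence sqrt(33282 / 5000) = 2.58 µm/px.
DEFAULT_PIXEL_SIZE = 2.58


@dataclass(frozen=True)
class RasterImage:
    """A single-channel 2-D image with spatial calibration.

    Parameters
    ----------
    pixels
        2-D array of intensities.  Stored as float64; all values must be
        finite.
    pixel_size
        Physical side length of a pixel in µm.
    provenance
        Tuple of human-readable processing steps applied so far, starting
        with the source (a file path or generator description).
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"image must be 2-D single channel, got ndim={px.ndim}")
        if px.size == 0:
            raise ValueError("image is empty")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixel values")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def derive(self, pixels: np.ndarray, step: str) -> "RasterImage":
        """Return a new image with ``step`` appended to the provenance."""
        return RasterImage(pixels, self.pixel_size, self.provenance + (step,))


@dataclass(frozen=True)
class BinaryMask:
    """A boolean foreground mask, same shape and calibration as its source."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2-D boolean array")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_raster(img, pixel_size: float = DEFAULT_PIXEL_SIZE, source: str = "array") -> RasterImage:
    """Coerce an array (or pass through a RasterImage) into a RasterImage."""
    if isinstance(img, RasterImage):
        return img
    return RasterImage(np.asarray(img, dtype=np.float64), pixel_size, (source,))
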