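"""Segmentation of colonies from stitched brightfield well images.

The chain mirrors the ImageJ/Fiji recipe used for 3-D co-culture wells:
Sobel edge filter → unsharp mask (radius 4, weight 0.8) → Gaussian blur
(σ = 4) → threshold → fill holes → size filter (area strictly greater than
5,000 px survives).  The edge filter turns textured colony interiors and
dark colony rims into high-intensity foreground on a quiet background, so a
global threshold separates colonies regardless of absolute brightfield
levels.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .image import DEFAULT_PIXEL_SIZE, BinaryMask, RasterImage, as_raster

_EIGHT = np.ones((3, 3), dtype=bool)

# 3×3 Sobel kernels (unnormalized, ImageJ "Find Edges" convention).
_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class PipelineParams:
    """Parameters of the colony segmentation chain.

    Attributes
    ----------
    unsharp_radius, unsharp_weight
        Unsharp-mask radius (Gaussian σ, px) and mask weight; defaults 4 and
        0.8 follow the published recipe.
    gaussian_sigma
        Pre-threshold Gaussian blur σ in px (default 4).
    threshold_method
        ``"auto"`` (Otsu on a 256-bin histogram) or ``"manual"``.
    manual_threshold
        Required when ``threshold_method="manual"``.
    threshold_offset
        Additive offset applied to the automatic threshold; a deterministic
        stand-in for the interactive per-well adjustment of the original
        workflow.
    min_area
        Size filter: components with area strictly greater than this survive
        (default 5,000 px, i.e. 33,282 µm² at the default calibration).
    pixel_size
        µm per pixel (default 2.58).
    fill_holes
        Fill interior holes so the perimeter measures the outer contour only.
    exclude_edge_touching
        Drop components touching the image border (truncated shapes bias the
        hull-to-perimeter ratio).
    """

    unsharp_radius: float = 4.0
    unsharp_weight: float = 0.8
    gaussian_sigma: float = 4.0
    threshold_method: str = "auto"
    manual_threshold: float | None = None
    threshold_offset: float = 0.0
    min_area: int = 5000
    pixel_size: float = DEFAULT_PIXEL_SIZE
    fill_holes: bool = True
    exclude_edge_touching: bool = True

    def __post_init__(self) -> None:
        if not self.unsharp_radius > 0:
            raise ValueError(f"unsharp_radius must be > 0, got {self.unsharp_radius}")
        if not 0 < self.unsharp_weight < 1:
            raise ValueError(f"unsharp_weight must be in (0, 1), got {self.unsharp_weight}")
        if not self.gaussian_sigma > 0:
            raise ValueError(f"gaussian_sigma must be > 0, got {self.gaussian_sigma}")
        if self.min_area < 0:
            raise ValueError(f"min_area must be >= 0, got {self.min_area}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.threshold_method not in ("auto", "manual"):
            raise ValueError(f"threshold_method must be 'auto' or 'manual', got {self.threshold_method!r}")
        if self.threshold_method == "manual" and self.manual_threshold is None:
            raise ValueError("threshold_method='manual' requires manual_threshold")


def find_edges(img: RasterImage | np.ndarray) -> RasterImage:
    """Sobel gradient magnitude √(Gx² + Gy²) with replicate-edge handling."""
    img = as_raster(img)
    gx = ndi.correlate(img.pixels, _SOBEL_X, mode="nearest")
    gy = ndi.correlate(img.pixels, _SOBEL_Y, mode="nearest")
    return img.derive(np.hypot(gx, gy), "find_edges(sobel)")


def unsharp_mask(img: RasterImage | np.ndarray, radius: float = 4.0,
                 weight: float = 0.8) -> RasterImage:
    """ImageJ-style unsharp mask: (I − w·G_r(I)) / (1 − w).

    ``radius`` maps to the Gaussian σ, matching ImageJ semantics.  A constant
    image is a fixed point; weight ≥ 1 is rejected (the renormalization
    blows up).
    """
    img = as_raster(img)
    if not radius > 0:
        raise ValueError(f"unsharp radius must be > 0, got {radius}")
    if not 0 < weight < 1:
        raise ValueError(f"unsharp weight must be in (0, 1), got {weight}")
    blurred = ndi.gaussian_filter(img.pixels, sigma=radius, mode="nearest")
    out = (img.pixels - weight * blurred) / (1.0 - weight)
    return img.derive(out, f"unsharp_mask(r={radius}, w={weight})")


def gaussian_blur(img: RasterImage | np.ndarray, sigma: float = 4.0) -> RasterImage:
    """Isotropic Gaussian convolution with replicate boundary handling."""
    img = as_raster(img)
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    out = ndi.gaussian_filter(img.pixels, sigma=sigma, mode="nearest")
    return img.derive(out, f"gaussian_blur(sigma={sigma})")


def otsu_threshold(pixels: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold maximizing between-class variance over ``nbins`` bins."""
    if np.ptp(pixels) == 0:
        raise ValueError(
            "image is single-valued; automatic (Otsu) thresholding is undefined "
            "— supply a manual threshold instead")
    return float(threshold_otsu(pixels, nbins=nbins))


def threshold_mask(img: RasterImage | np.ndarray, params: PipelineParams | None = None
                   ) -> BinaryMask:
    """Binarize a preprocessed image; pixels strictly above threshold are
    foreground.  Interior holes of foreground components are filled when
    ``params.fill_holes`` is set."""
    img = as_raster(img)
    if params is None:
        params = PipelineParams()
    if params.threshold_method == "manual":
        thr = float(params.manual_threshold)
    else:
        thr = otsu_threshold(img.pixels) + params.threshold_offset
    fg = img.pixels > thr
    if params.fill_holes:
        fg = ndi.binary_fill_holes(fg)
    return BinaryMask(fg, img.pixel_size,
                      img.provenance + (f"threshold(> {thr:.6g})",))


def filter_components(mask: BinaryMask, min_area: int,
                      exclude_edge_touching: bool = False) -> BinaryMask:
    """Keep 8-connected components with area strictly greater than ``min_area``;
    optionally drop components touching the image border."""
    labels, n = ndi.label(mask.pixels, structure=_EIGHT)
    if n == 0:
        return mask
    keep = np.zeros(n + 1, dtype=bool)
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep[1:] = areas[1:] > min_area
    if exclude_edge_touching:
        border = np.unique(np.concatenate([
            labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
        keep[border] = False
    out = keep[labels]
    return BinaryMask(out, mask.pixel_size,
                      mask.provenance + (f"size_filter(area > {min_area})",))


def make_colony_mask(img: RasterImage | np.ndarray,
                     params: PipelineParams | None = None) -> BinaryMask:
    """Full segmentation chain from a stitched well image to a colony mask.

    edge filter → unsharp mask → Gaussian blur → threshold (+ hole filling)
    → size filter.  Deterministic: identical input and parameters give an
    identical mask.
    """
    if params is None:
        params = PipelineParams()
    img = as_raster(img, pixel_size=params.pixel_size)
    step = find_edges(img)
    step = unsharp_mask(step, params.unsharp_radius, params.unsharp_weight)
    step = gaussian_blur(step, params.gaussian_sigma)
    mask = threshold_mask(step, params)
    return filter_components(mask, params.min_area, params.exclude_edge_touching)
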