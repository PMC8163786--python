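"""File handling: images, montage assembly, CSV schemas, and config files."""
from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .image import DEFAULT_PIXEL_SIZE, BinaryMask, RasterImage
from .imgproc import PipelineParams
from .screen import ScreenParams


@dataclass(frozen=True)
class FieldGrid:
    """Microscope field layout of one well: 5 columns × 3 rows by default,
    with fields indexed row-major."""

    n_cols: int = 5
    n_rows: int = 3

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n_fields(self) -> int:
        return self.n_cols * self.n_rows

    def position(self, index: int) -> tuple[int, int]:
        """(row, col) of a zero-based field index in row-major order."""
        if not 0 <= index < self.n_fields:
            raise ValueError(f"field index {index} outside grid of {self.n_fields}")
        return divmod(index, self.n_cols)


def montage_fields(fields: list[RasterImage | np.ndarray],
                   grid: FieldGrid | None = None) -> RasterImage:
    """Abut per-field tiles into a whole-well image, row-major, no overlap.

    All fields must share one shape and the count must equal the grid size;
    output is (n_rows·h, n_cols·w).
    """
    if grid is None:
        grid = FieldGrid()
    arrays = [f.pixels if isinstance(f, RasterImage) else np.asarray(f, float)
              for f in fields]
    if len(arrays) != grid.n_fields:
        raise ValueError(
            f"expected {grid.n_fields} fields for a {grid.n_cols}x{grid.n_rows} "
            f"grid, got {len(arrays)}")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"fields have mismatched shapes: {sorted(shapes)}")
    rows = [np.hstack(arrays[r * grid.n_cols:(r + 1) * grid.n_cols])
            for r in range(grid.n_rows)]
    out = np.vstack(rows)
    ps = fields[0].pixel_size if isinstance(fields[0], RasterImage) else DEFAULT_PIXEL_SIZE
    return RasterImage(out, ps, (f"montage({grid.n_cols}x{grid.n_rows})",))


def read_image(path: str | Path, pixel_size: float = DEFAULT_PIXEL_SIZE) -> RasterImage:
    """Read a grayscale TIFF or PNG as a RasterImage (intensities as stored)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3:  # collapse trivial channel axes
        if px.shape[2] in (3, 4):
            px = px[..., :3].mean(axis=2)
        else:
            px = px.squeeze()
    return RasterImage(px.astype(np.float64), pixel_size, (str(path),))


def write_tiff(path: str | Path, img: RasterImage | np.ndarray) -> None:
    px = img.pixels if isinstance(img, RasterImage) else np.asarray(img)
    tifffile.imwrite(Path(path), px)


def write_mask_png(path: str | Path, mask: BinaryMask | np.ndarray) -> None:
    """Write a binary mask as an 8-bit 0/255 PNG for inspection."""
    px = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    iio.imwrite(Path(path), (px.astype(np.uint8) * 255))


def write_params_sidecar(path: str | Path, params: PipelineParams,
                         extra: dict | None = None) -> None:
    """JSON sidecar recording the exact parameters of a processing run."""
    d = {f.name: getattr(params, f.name) for f in fields(params)}
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path) -> dict:
    """Read a TOML config file."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def pipeline_params_from_config(cfg: dict) -> PipelineParams:
    """Build PipelineParams from the [segmentation] table of a config."""
    sect = cfg.get("segmentation", {})
    allowed = {f.name for f in fields(PipelineParams)}
    unknown = set(sect) - allowed
    if unknown:
        raise ValueError(f"unknown segmentation options: {sorted(unknown)}")
    return PipelineParams(**sect)


def screen_params_from_config(cfg: dict) -> ScreenParams:
    sect = cfg.get("screen", {})
    allowed = {f.name for f in fields(ScreenParams)}
    unknown = set(sect) - allowed
    if unknown:
        raise ValueError(f"unknown screen options: {sorted(unknown)}")
    return ScreenParams(**sect)
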