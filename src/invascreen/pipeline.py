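"""End-to-end pipeline: well images → colony mask → shape measurements →
nuclei counts → per-plate screen report.

Driven by a TOML config file, e.g.::

    [input]
    plate_map = "plate/plate_map.csv"
    images_3d = "plate/images3d"      # <plate>_<well>.tif stitched montages,
                                      # or <plate>_<well>_f<k>.tif field tiles
    images_2d = "plate/images2d"      # <plate>_<well>_f<k>.tif nuclei fields

    [grid]                            # only used when 3-D input is per-field
    n_cols = 5
    n_rows = 3

    [segmentation]                    # PipelineParams fields
    gaussian_sigma = 4.0

    [nuclei]
    spot_sigma = 3.0
    min_distance = 5
    threshold_rel = 0.3

    [screen]                          # ScreenParams fields
    alpha = 0.05

    [output]
    dir = "results"

All outputs (colonies.csv, viability.csv, screen_summary.csv, masks/, and a
run_log.json with the exact parameters and package versions) are written to
the output directory; a rerun with the same config reproduces them
byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .image import RasterImage
from .imgproc import make_colony_mask
from .io import (FieldGrid, load_config, montage_fields,
                 pipeline_params_from_config, read_image,
                 screen_params_from_config, write_mask_png)
from .nuclei import well_viability_counts
from .screen import PlateLayout, screen_report
from .shape import measure_well, measurements_to_frame


def run_synthetic_screen(spec, params=None, screen_params=None,
                         nuclei_kwargs: dict | None = None) -> dict:
    """Render a synthetic plate in memory and push it through the full
    analysis chain (segmentation → shape measurement → nuclei counting →
    normalization → hit calling).

    Exercises exactly the same library code as :func:`run_pipeline` but skips
    the file round-trip, which keeps replicate simulation studies fast.
    Returns the colonies, viability and summary tables plus the per-colony
    ground truth.
    """
    from .imgproc import PipelineParams
    from .screen import ScreenParams
    from .synthetic import (ConditionEffect, _condition_amplitude,
                            _place_colonies, build_layout,
                            render_nuclei_field, render_well_montage)

    params = params or PipelineParams()
    screen_params = screen_params or ScreenParams()
    nuclei_kwargs = nuclei_kwargs or {}
    layout = build_layout(spec)
    children = np.random.SeedSequence(spec.seed).spawn(len(layout))
    colony_frames: list[pd.DataFrame] = []
    via_rows: list[dict] = []
    truth_rows: list[dict] = []
    for (_, row), child in zip(layout.iterrows(), children):
        rng = np.random.default_rng(child)
        well, cond, role = row["well"], row["condition"], row["role"]
        if role != "control_tox":
            amp = _condition_amplitude(spec, cond, role)
            colonies = _place_colonies(spec, amp, rng)
            montage = render_well_montage(spec, colonies, rng)
            mask = make_colony_mask(montage, params)
            colony_frames.append(measurements_to_frame(
                measure_well(mask, params), row["plate_id"], well, cond, role))
            for j, c in enumerate(colonies, start=1):
                truth_rows.append(dict(plate_id=row["plate_id"], well=well,
                                       condition=cond, role=role, colony_id=j,
                                       true_ratio=c.ground_truth_ratio()))
        if role != "tumor_alone":
            vf = spec.targets.get(cond, ConditionEffect()).viability_factor \
                if role == "target" else (0.005 if role == "control_tox" else 1.0)
            fields = []
            for _k in range(spec.n_fields_2d):
                n_nuc = int(rng.poisson(spec.nuclei_per_field * vf))
                f, _ = render_nuclei_field(
                    n_nuc, spec.nuclei_min_separation,
                    (spec.field_size, spec.field_size),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    noise_level=spec.noise_level)
                fields.append(f)
            rec = well_viability_counts(fields, row["plate_id"], well, cond,
                                        role, **nuclei_kwargs)
            via_rows.append(dict(plate_id=row["plate_id"], well=well,
                                 condition=cond, role=role,
                                 n_fields=len(rec.field_counts),
                                 well_count=rec.well_count))
    colonies = pd.concat(colony_frames, ignore_index=True)
    viability = pd.DataFrame(via_rows)
    summary = screen_report(colonies, viability if via_rows else None,
                            screen_params)
    return {"colonies": colonies, "viability": viability, "summary": summary,
            "ground_truth": pd.DataFrame(truth_rows), "layout": layout}


class InputError(ValueError):
    """Bad or missing input (plate map, images, config)."""


class ProcessingError(RuntimeError):
    """Failure inside the processing chain."""


_FIELD_RE = re.compile(r"_f(\d+)$")


def _well_images_3d(image_dir: Path, plate: str, well: str, grid: FieldGrid
                    ) -> RasterImage | None:
    """Stitched montage for a well: pre-stitched file, or abutted field tiles."""
    for ext in (".tif", ".tiff", ".png"):
        p = image_dir / f"{plate}_{well}{ext}"
        if p.exists():
            return read_image(p)
    tiles = sorted(image_dir.glob(f"{plate}_{well}_f*.*"),
                   key=lambda p: int(_FIELD_RE.search(p.stem).group(1)))
    if tiles:
        return montage_fields([read_image(t) for t in tiles], grid)
    return None


def run_pipeline(config_path: str | Path) -> dict[str, pd.DataFrame]:
    """Execute the full pipeline described by a config file.

    The plate map is validated (including the presence of control_nt wells)
    before any image is read.  Returns the colonies, viability and screen
    summary tables; writes them plus mask PNGs and a JSON run log to the
    configured output directory.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise InputError(f"config file not found: {config_path}")
    cfg = load_config(config_path)
    inp = cfg.get("input", {})
    if "plate_map" not in inp:
        raise InputError("config [input] must name a plate_map CSV")
    plate_map = (config_path.parent / inp["plate_map"]).resolve() \
        if not Path(inp["plate_map"]).is_absolute() else Path(inp["plate_map"])
    if not plate_map.exists():
        raise InputError(f"plate map not found: {plate_map}")
    try:
        layout = PlateLayout.from_csv(plate_map)
    except ValueError as e:
        raise InputError(str(e)) from e

    def _dir(key: str) -> Path | None:
        if key not in inp:
            return None
        p = Path(inp[key])
        if not p.is_absolute():
            p = (config_path.parent / p).resolve()
        if not p.exists():
            raise InputError(f"[input] {key} directory not found: {p}")
        return p

    dir3d = _dir("images_3d")
    dir2d = _dir("images_2d")
    if dir3d is None:
        raise InputError("config [input] must name an images_3d directory")

    grid_cfg = cfg.get("grid", {})
    grid = FieldGrid(grid_cfg.get("n_cols", 5), grid_cfg.get("n_rows", 3))
    params = pipeline_params_from_config(cfg)
    sparams = screen_params_from_config(cfg)
    ncfg = cfg.get("nuclei", {})
    out_dir = Path(cfg.get("output", {}).get("dir", "results"))
    if not out_dir.is_absolute():
        out_dir = config_path.parent / out_dir
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    colony_frames: list[pd.DataFrame] = []
    via_rows: list[dict] = []
    for _, row in layout.table.iterrows():
        plate, well, cond, role = (row["plate_id"], row["well"],
                                   row["condition"], row["role"])
        montage = _well_images_3d(dir3d, plate, well, grid)
        if montage is not None:
            try:
                mask = make_colony_mask(montage, params)
                measurements = measure_well(mask, params)
            except Exception as e:
                raise ProcessingError(
                    f"segmentation failed for {plate}/{well}: {e}") from e
            write_mask_png(out_dir / "masks" / f"{plate}_{well}_mask.png", mask)
            colony_frames.append(
                measurements_to_frame(measurements, plate, well, cond, role))
        if dir2d is not None:
            tiles = sorted(dir2d.glob(f"{plate}_{well}_f*.*"),
                           key=lambda p: int(_FIELD_RE.search(p.stem).group(1)))
            if tiles:
                rec = well_viability_counts(
                    [read_image(t) for t in tiles], plate, well, cond, role,
                    spot_sigma=ncfg.get("spot_sigma", 3.0),
                    min_distance=ncfg.get("min_distance", 5),
                    threshold_rel=ncfg.get("threshold_rel", 0.3))
                via_rows.append(dict(plate_id=plate, well=well, condition=cond,
                                     role=role, n_fields=len(rec.field_counts),
                                     well_count=rec.well_count))

    colonies = (pd.concat(colony_frames, ignore_index=True) if colony_frames
                else pd.DataFrame())
    if colonies.empty:
        raise ProcessingError(
            f"no 3-D well images matched the plate map under {dir3d}")
    viability = pd.DataFrame(
        via_rows, columns=["plate_id", "well", "condition", "role", "n_fields",
                           "well_count"])
    summary = screen_report(colonies, viability if len(via_rows) else None, sparams)

    colonies.to_csv(out_dir / "colonies.csv", index=False)
    viability.to_csv(out_dir / "viability.csv", index=False)
    summary.to_csv(out_dir / "screen_summary.csv", index=False)
    log = dict(
        invascreen_version=__version__,
        config=str(config_path),
        plate_map=str(plate_map),
        n_wells=int(len(layout.table)),
        n_colonies=int(len(colonies)),
        segmentation=dataclasses.asdict(params),
        screen=dataclasses.asdict(sparams),
        nuclei=dict(spot_sigma=ncfg.get("spot_sigma", 3.0),
                    min_distance=ncfg.get("min_distance", 5),
                    threshold_rel=ncfg.get("threshold_rel", 0.3)),
        grid=dict(n_cols=grid.n_cols, n_rows=grid.n_rows),
    )
    (out_dir / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n")
    return {"colonies": colonies, "viability": viability, "summary": summary}
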