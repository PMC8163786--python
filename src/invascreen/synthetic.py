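"""Synthetic well images, nuclei fields, and whole plates with known ground
truth.

The generator emulates the statistical structure of a real high-content
3-D co-culture screen so every pipeline stage is testable offline:

* colonies are radial star polygons r(θ) = R₀·(1 + a·cos(kθ)) whose exact
  hull-to-perimeter ratio is computable from the vertex list — smooth
  (a ≈ 0) colonies stand in for tumour cells held in check by myoepithelial
  cells, spiky (large a) colonies for invasive growth;
* brightfield appearance is a textured colony interior with a darker rim on
  a lighter noisy background, which is what the edge-filter segmentation
  chain expects;
* nuclei fields are isotropic Gaussian spots on a noisy background, standing
  in for Hoechst-stained 2-D viability plates.

Everything is deterministic under a fixed seed, down to the bytes of the
written files.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .image import DEFAULT_PIXEL_SIZE, RasterImage

# Rendering constants (intensity fractions of full scale).
_BG_LEVEL = 0.80
_INTERIOR_LEVEL = 0.55
_RIM_LEVEL = 0.45
_RIM_WIDTH = 1.5          # px
_TEXTURE_SIGMA = 1.0      # px, smoothing of the interior speckle
_TEXTURE_AMPLITUDE = 1.5  # scale of the speckle before smoothing
_COLONY_MARGIN = 8.0      # px of clearance demanded inside the image


@dataclass(frozen=True)
class SyntheticColonySpec:
    """A parametric star-polygon colony with analytically known shape.

    The generating polygon samples r(θ) = base_radius·(1 + spike_amplitude·
    cos(n_spikes·θ)) at ``n_vertices`` angles, optionally with multiplicative
    radial jitter.  Radial polygons are always simple, and the exact
    hull-to-perimeter ratio of the polygon is available as ground truth.
    """

    center: tuple[float, float]        # (row, col) px
    base_radius: float                 # px
    n_spikes: int = 0
    spike_amplitude: float = 0.0       # fraction of base_radius, in [0, 1)
    n_vertices: int = 256
    radial_jitter: float = 0.0         # multiplicative, fraction of radius
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.base_radius > 0:
            raise ValueError(f"base_radius must be > 0, got {self.base_radius}")
        if self.n_spikes < 0:
            raise ValueError(f"n_spikes must be >= 0, got {self.n_spikes}")
        if not 0 <= self.spike_amplitude < 1:
            raise ValueError(
                f"spike_amplitude must be in [0, 1), got {self.spike_amplitude}")
        if self.n_vertices < 32:
            raise ValueError(f"n_vertices must be >= 32, got {self.n_vertices}")
        if not 0 <= self.radial_jitter < 0.5:
            raise ValueError(
                f"radial_jitter must be in [0, 0.5), got {self.radial_jitter}")

    @property
    def max_radius(self) -> float:
        return self.base_radius * (1 + self.spike_amplitude) * (1 + self.radial_jitter)

    def polygon(self) -> np.ndarray:
        """Vertices of the generating polygon, (n_vertices, 2) as (row, col).

        Radial jitter is spatially smooth (circularly filtered noise, ~6
        vertex correlation length) so the perturbation lives at a scale the
        pixel grid can actually represent; per-vertex white noise would
        inflate the true perimeter with sub-pixel wiggles no measurement
        could see."""
        rng = np.random.default_rng(self.seed)
        theta = np.linspace(0.0, 2 * np.pi, self.n_vertices, endpoint=False)
        r = self.base_radius * (1 + self.spike_amplitude * np.cos(self.n_spikes * theta))
        if self.radial_jitter > 0:
            noise = ndi.gaussian_filter1d(
                rng.normal(0.0, 1.0, self.n_vertices), 6.0, mode="wrap")
            noise = noise / max(noise.std(), 1e-12)
            r = r * (1 + self.radial_jitter * noise)
        rows = self.center[0] + r * np.sin(theta)
        cols = self.center[1] + r * np.cos(theta)
        return np.column_stack([rows, cols])

    def ground_truth_ratio(self) -> float:
        """Exact hull-perimeter / polygon-perimeter ratio of the generating
        polygon (planar geometry on the vertex list, independent of any
        rasterization)."""
        return polygon_hull_ratio(self.polygon())


def polygon_hull_ratio(vertices: np.ndarray) -> float:
    """Exact convex-hull-length / perimeter ratio of a simple polygon."""
    poly = Polygon(np.asarray(vertices, dtype=float))
    if not poly.is_valid or poly.exterior.length == 0:
        raise ValueError("vertices do not form a valid simple polygon")
    return poly.convex_hull.exterior.length / poly.exterior.length


def rasterize_polygon(vertices: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    """Boolean raster of a polygon (pixels whose centers fall inside)."""
    v = np.asarray(vertices, dtype=float)
    rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=tuple(image_size))
    out = np.zeros(tuple(image_size), dtype=bool)
    out[rr, cc] = True
    return out


def _check_fits(spec: SyntheticColonySpec, image_size: tuple[int, int]) -> None:
    reach = spec.max_radius + _COLONY_MARGIN
    r0, c0 = spec.center
    if (r0 - reach < 0 or c0 - reach < 0
            or r0 + reach > image_size[0] or c0 + reach > image_size[1]):
        raise ValueError(
            f"base_radius {spec.base_radius} with spike_amplitude "
            f"{spec.spike_amplitude} at center {spec.center} does not fit in a "
            f"{image_size[0]}x{image_size[1]} image with a {_COLONY_MARGIN} px margin")


def _paint_colony(canvas: np.ndarray, spec: SyntheticColonySpec,
                  rng: np.random.Generator) -> None:
    """Paint one colony (textured interior, darker rim) onto ``canvas`` in place.

    Work is confined to the colony's bounding window for speed."""
    poly = spec.polygon()
    pad = 4
    r0 = max(int(np.floor(poly[:, 0].min())) - pad, 0)
    c0 = max(int(np.floor(poly[:, 1].min())) - pad, 0)
    r1 = min(int(np.ceil(poly[:, 0].max())) + pad, canvas.shape[0])
    c1 = min(int(np.ceil(poly[:, 1].max())) + pad, canvas.shape[1])
    window = canvas[r0:r1, c0:c1]
    interior = rasterize_polygon(poly - [r0, c0], window.shape)
    # Distance from inside the colony to its boundary → rim band.
    dist_in = ndi.distance_transform_edt(interior)
    rim = interior & (dist_in <= _RIM_WIDTH)
    core = interior & ~rim
    texture = ndi.gaussian_filter(
        rng.normal(0.0, _TEXTURE_AMPLITUDE, window.shape), _TEXTURE_SIGMA)
    window[core] = _INTERIOR_LEVEL + texture[core]
    window[rim] = _RIM_LEVEL


def render_colony(spec: SyntheticColonySpec, image_size: tuple[int, int] = (256, 256),
                  noise_level: float = 0.02) -> tuple[RasterImage, np.ndarray]:
    """Render a single colony as a brightfield-like image.

    Returns the image (float intensities in ~[0, 1]) and the exact generating
    polygon.  Deterministic under the spec's seed.
    """
    _check_fits(spec, image_size)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC01]))
    canvas = np.full(tuple(image_size), _BG_LEVEL)
    _paint_colony(canvas, spec, rng)
    if noise_level > 0:
        canvas = canvas + rng.normal(0.0, noise_level, canvas.shape)
    img = RasterImage(np.clip(canvas, 0.0, 1.0), DEFAULT_PIXEL_SIZE,
                      (f"render_colony(seed={spec.seed})",))
    return img, spec.polygon()


def render_nuclei_field(n_nuclei: int, min_separation: float = 12.0,
                        image_size: tuple[int, int] = (256, 256), seed: int = 0,
                        spot_sigma: float = 3.0, noise_level: float = 0.02
                        ) -> tuple[RasterImage, np.ndarray]:
    """Render a Hoechst-like nuclei field of Gaussian spots.

    Spot centers are rejection-sampled to keep pairwise distances at least
    ``min_separation``; if that is infeasible within the attempt budget an
    error suggests lowering ``n_nuclei`` or ``min_separation``.  Returns the
    image and the (n, 2) array of (row, col) spot centers.
    """
    if n_nuclei < 0:
        raise ValueError(f"n_nuclei must be >= 0, got {n_nuclei}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0E]))
    h, w = image_size
    margin = 2.0 * spot_sigma
    positions: list[np.ndarray] = []
    placed = np.empty((0, 2))
    attempts = 0
    max_attempts = max(1000, 300 * max(n_nuclei, 1))
    while len(positions) < n_nuclei:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n_nuclei} nuclei at min_separation "
                f"{min_separation} in a {h}x{w} field; lower n_nuclei or "
                f"min_separation")
        attempts += 1
        cand = np.array([rng.uniform(margin, h - margin),
                         rng.uniform(margin, w - margin)])
        if len(positions) == 0 or np.all(
                np.hypot(*(placed - cand).T) >= min_separation):
            positions.append(cand)
            placed = np.asarray(positions)
    pos = np.asarray(positions).reshape(-1, 2)

    canvas = np.full((h, w), 0.08)
    if noise_level > 0:
        canvas = canvas + rng.normal(0.0, noise_level, canvas.shape)
    half = int(np.ceil(4 * spot_sigma))
    for (r0, c0) in pos:
        amp = rng.uniform(0.5, 0.8)
        ri, ci = int(round(r0)), int(round(c0))
        rlo, rhi = max(ri - half, 0), min(ri + half + 1, h)
        clo, chi = max(ci - half, 0), min(ci + half + 1, w)
        yy, xx = np.mgrid[rlo:rhi, clo:chi]
        canvas[rlo:rhi, clo:chi] += amp * np.exp(
            -((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * spot_sigma ** 2))
    img = RasterImage(np.clip(canvas, 0.0, 1.2), DEFAULT_PIXEL_SIZE,
                      (f"render_nuclei_field(seed={seed})",))
    return img, pos


@dataclass(frozen=True)
class ConditionEffect:
    """Per-condition perturbation relative to the non-targeting baseline.

    ``amplitude_shift`` is added to the baseline mean spike amplitude of the
    condition's colonies (more protrusive growth = loss of myoepithelial
    control); ``viability_factor`` scales the expected nuclei count of the
    condition's 2-D wells (transfection lethality).
    """

    amplitude_shift: float = 0.0
    viability_factor: float = 1.0


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """One synthetic screening plate (a 3-D co-culture plate plus its 2-D
    viability companion).

    Control well composition follows the real plate design: one
    non-targeting (control_nt) and one mock well per 3-D plate, four
    tumour-alone wells, and two lethal-control (control_tox) wells imaged in
    2-D only.  Remaining defaults are desk-scale study conditions: 5×3 fields
    of 256×256 px per 3-D well montage, ~11 colonies per well, four 2-D
    fields per well at ~120 nuclei per field at full viability.
    """

    plate_id: str = "P1"
    targets: dict[str, ConditionEffect] = field(default_factory=dict)
    n_control_nt: int = 1
    n_mock: int = 1
    n_tumor_alone: int = 4
    n_control_tox: int = 2
    field_size: int = 256
    grid_cols: int = 5
    grid_rows: int = 3
    colonies_min: int = 6
    colonies_poisson_mean: float = 5.0
    base_radius_range: tuple[float, float] = (45.0, 60.0)
    baseline_amplitude: float = 0.08
    amplitude_sd: float = 0.05
    tumor_alone_amplitude: float = 0.45
    radial_jitter: float = 0.03
    n_fields_2d: int = 4
    nuclei_per_field: float = 120.0
    nuclei_min_separation: float = 10.0
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control_nt < 1:
            raise ValueError("every plate needs at least one control_nt well")

    @property
    def montage_shape(self) -> tuple[int, int]:
        return (self.grid_rows * self.field_size, self.grid_cols * self.field_size)


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGH"
    return [f"{rows[i // 12]}{i % 12 + 1:02d}" for i in range(n)]


def build_layout(spec: SyntheticPlateSpec) -> pd.DataFrame:
    """Plate map for a synthetic plate: columns plate_id, well, condition, role."""
    entries: list[tuple[str, str]] = []
    for name in spec.targets:
        entries.append((name, "target"))
    entries += [("siOTP-NT", "control_nt")] * spec.n_control_nt
    entries += [("mock", "mock")] * spec.n_mock
    entries += [("tumor_alone", "tumor_alone")] * spec.n_tumor_alone
    entries += [("siTOX", "control_tox")] * spec.n_control_tox
    wells = _well_names(len(entries))
    return pd.DataFrame({
        "plate_id": spec.plate_id,
        "well": wells,
        "condition": [c for c, _ in entries],
        "role": [r for _, r in entries],
    })


def _condition_amplitude(spec: SyntheticPlateSpec, condition: str, role: str) -> float:
    if role == "tumor_alone":
        return spec.tumor_alone_amplitude
    shift = spec.targets.get(condition, ConditionEffect()).amplitude_shift if role == "target" else 0.0
    return spec.baseline_amplitude + shift


def _place_colonies(spec: SyntheticPlateSpec, amplitude_mean: float,
                    rng: np.random.Generator) -> list[SyntheticColonySpec]:
    """Sample non-overlapping colony specs for one well montage."""
    h, w = spec.montage_shape
    n = spec.colonies_min + int(rng.poisson(spec.colonies_poisson_mean))
    colonies: list[SyntheticColonySpec] = []
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(colonies) < n and attempts < 200 * n:
        attempts += 1
        base_r = rng.uniform(*spec.base_radius_range)
        amp = float(np.clip(rng.normal(amplitude_mean, spec.amplitude_sd), 0.0, 0.85))
        reach = base_r * (1 + amp) * (1 + spec.radial_jitter) + _COLONY_MARGIN
        center = (rng.uniform(reach, h - reach), rng.uniform(reach, w - reach))
        ok = all(np.hypot(center[0] - c[0], center[1] - c[1]) > reach + rr + 6
                 for c, rr in zip(centers, radii))
        if not ok:
            continue
        colonies.append(SyntheticColonySpec(
            center=center, base_radius=base_r,
            n_spikes=int(rng.integers(4, 10)), spike_amplitude=amp,
            radial_jitter=spec.radial_jitter,
            seed=int(rng.integers(0, 2**31 - 1))))
        centers.append(center)
        radii.append(base_r * (1 + amp) * (1 + spec.radial_jitter))
    return colonies


def render_well_montage(spec: SyntheticPlateSpec, colonies: list[SyntheticColonySpec],
                        rng: np.random.Generator) -> RasterImage:
    """Render a whole stitched 3-D well image containing the given colonies."""
    canvas = np.full(spec.montage_shape, _BG_LEVEL)
    for c in colonies:
        _paint_colony(canvas, c, np.random.default_rng(
            np.random.SeedSequence([c.seed, 0xC01])))
    if spec.noise_level > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_level, canvas.shape)
    return RasterImage(np.clip(canvas, 0.0, 1.0), DEFAULT_PIXEL_SIZE,
                       ("render_well_montage",))


def to_uint16(img: RasterImage) -> np.ndarray:
    return np.round(np.clip(img.pixels, 0.0, 1.2) / 1.2 * 65535).astype(np.uint16)


def generate_plate(spec: SyntheticPlateSpec, out_dir: str | Path
                   ) -> dict[str, object]:
    """Write a full synthetic plate to disk and return its ground truth.

    Output tree::

        out_dir/
          plate_map.csv                 plate_id, well, condition, role
          ground_truth.csv              per-colony true ratios + per-well nuclei counts
          images3d/<plate>_<well>.tif   stitched brightfield montages (16-bit)
          images2d/<plate>_<well>_f<k>.tif   per-field nuclei images (16-bit)

    control_tox wells get 2-D fields only (the lethal control is a 2-D
    transfection-efficiency control); tumor_alone wells get 3-D montages
    only.  Byte-identical outputs under the same spec and seed.
    """
    out = Path(out_dir)
    (out / "images3d").mkdir(parents=True, exist_ok=True)
    (out / "images2d").mkdir(parents=True, exist_ok=True)
    layout = build_layout(spec)
    root_ss = np.random.SeedSequence(spec.seed)
    truth_rows: list[dict] = []

    children = root_ss.spawn(len(layout))  # one deterministic stream per well
    for (_, row), child in zip(layout.iterrows(), children):
        rng = np.random.default_rng(child)
        well, cond, role = row["well"], row["condition"], row["role"]
        if role != "control_tox":
            amp = _condition_amplitude(spec, cond, role)
            colonies = _place_colonies(spec, amp, rng)
            montage = render_well_montage(spec, colonies, rng)
            tifffile.imwrite(out / "images3d" / f"{spec.plate_id}_{well}.tif",
                             to_uint16(montage))
            for j, c in enumerate(colonies, start=1):
                truth_rows.append(dict(
                    plate_id=spec.plate_id, well=well, condition=cond, role=role,
                    record="colony", colony_id=j,
                    true_ratio=c.ground_truth_ratio(), nuclei_count=np.nan))
        if role != "tumor_alone":
            vf = spec.targets.get(cond, ConditionEffect()).viability_factor \
                if role == "target" else (0.005 if role == "control_tox" else 1.0)
            total = 0
            for k in range(1, spec.n_fields_2d + 1):
                n_nuc = int(rng.poisson(spec.nuclei_per_field * vf))
                field, _ = render_nuclei_field(
                    n_nuc, spec.nuclei_min_separation,
                    (spec.field_size, spec.field_size),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    noise_level=spec.noise_level)
                tifffile.imwrite(
                    out / "images2d" / f"{spec.plate_id}_{well}_f{k}.tif",
                    to_uint16(field))
                total += n_nuc
            truth_rows.append(dict(
                plate_id=spec.plate_id, well=well, condition=cond, role=role,
                record="nuclei", colony_id=np.nan, true_ratio=np.nan,
                nuclei_count=total))

    truth = pd.DataFrame(truth_rows, columns=[
        "plate_id", "well", "condition", "role", "record", "colony_id",
        "true_ratio", "nuclei_count"])
    layout.to_csv(out / "plate_map.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    return {"layout": layout, "ground_truth": truth, "out_dir": out}
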