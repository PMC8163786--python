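"""Colony shape measurement: perimeter, convex hull, and the hull-to-perimeter
invasiveness ratio.

Length convention
-----------------
Both the colony outline and its convex hull are measured as 8-connected
chain codes through pixel centers (orthogonal step = 1, diagonal step = √2).
The hull polygon is rasterized back onto the pixel grid and re-traced before
measuring, so numerator and denominator carry the same digitization bias:
digital chain codes overestimate smooth Euclidean curves by ~5% on average,
and measuring both lengths in the same digital metric cancels that bias.
A smooth convex colony therefore calibrates to a ratio of 1, which is the
property the score's interpretation rests on (1 = smooth, →0 = protrusive).
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

from .image import BinaryMask
from .imgproc import PipelineParams

#: Discretization allowance on the ratio: values in (1, 1+RATIO_EPS] are
#: clamped to exactly 1.0 (rasterization can make the digital hull length
#: marginally exceed the outline length on near-convex shapes).
RATIO_EPS = 0.01

_SQRT2 = float(np.sqrt(2.0))

# Moore neighborhood in clockwise screen order (row down), starting north.
_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
    dtype=np.intp,
)
_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass(frozen=True)
class ColonyMeasurement:
    """Measurements of a single segmented colony.

    ``ratio`` is hull perimeter / outline perimeter, both measured as digital
    chain-code lengths (see module docstring); 1 means smooth/non-invasive,
    values toward 0 mean protrusive/invasive.
    """

    colony_id: int
    area_px: int
    area_um2: float
    perimeter_px: float
    hull_perimeter_px: float
    ratio: float
    centroid: tuple[float, float]  # (row, col) in pixels
    edge_touching: bool


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the closed outer boundary of a single filled 8-connected component.

    Moore-neighbor tracing with Jacob's stopping criterion.  Returns an
    (N, 2) array of (row, col) pixel centers forming a closed cycle
    (the first point is not repeated at the end), oriented counter-clockwise
    with respect to conventional x-right / y-up axes.

    Pixels on one-pixel-wide protrusions appear twice (the trace runs out and
    back), which is the correct behaviour for perimeter measurement.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot trace the boundary of an empty component")
    # Pad so neighbor lookups never leave the array.
    m = np.pad(mask, 1)
    rows, cols = np.nonzero(m)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost

    if rows.size == 1:
        return np.array([[start[0] - 1, start[1] - 1]], dtype=np.intp)

    contour: list[tuple[int, int]] = [start]
    # Backtrack starts at the pixel west of start, guaranteed background.
    prev = (start[0], start[1] - 1)
    cur = start
    second: tuple[int, int] | None = None
    max_steps = 4 * int(m.size)
    for _ in range(max_steps):
        d = (prev[0] - cur[0], prev[1] - cur[1])
        base = next(i for i in range(8) if tuple(_MOORE[i]) == d)
        nxt = None
        for k in range(1, 9):
            idx = (base + k) % 8
            cand = (cur[0] + int(_MOORE[idx][0]), cur[1] + int(_MOORE[idx][1]))
            if m[cand]:
                nxt = cand
                prev_idx = (base + k - 1) % 8
                new_prev = (cur[0] + int(_MOORE[prev_idx][0]),
                            cur[1] + int(_MOORE[prev_idx][1]))
                break
        if nxt is None:  # isolated pixel (cannot happen for size > 1)
            break
        if second is None:
            second = nxt
        elif cur == start and nxt == second:
            # Jacob's stopping criterion: we are back at the start and about
            # to repeat the very first move — the cycle is complete.
            break
        contour.append(nxt)
        prev, cur = new_prev, nxt
    else:
        raise RuntimeError("boundary tracing did not terminate")

    pts = np.asarray(contour, dtype=np.intp) - 1  # undo padding
    if len(pts) > 1 and tuple(pts[-1]) == tuple(pts[0]):
        pts = pts[:-1]  # drop the trailing re-entry into the start pixel
    return _orient_ccw(pts)


def _orient_ccw(pts: np.ndarray) -> np.ndarray:
    """Orient a closed pixel cycle counter-clockwise in x-right/y-up axes."""
    if len(pts) < 3:
        return pts
    x = pts[:, 1].astype(float)
    y = -pts[:, 0].astype(float)  # flip row axis so y points up
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        pts = pts[::-1]
    return pts


def perimeter_length(boundary: np.ndarray) -> float:
    """Chain-code length of a closed boundary through pixel centers.

    Orthogonal moves weigh 1, diagonal moves √2.  The closing step from the
    last point back to the first is included.
    """
    pts = np.asarray(boundary, dtype=float)
    if len(pts) < 3:
        raise ValueError("boundary has fewer than 3 points; degenerate component")
    steps = np.roll(pts, -1, axis=0) - pts
    ad = np.abs(steps)
    if np.any(ad > 1):
        # Non-adjacent consecutive points: fall back to Euclidean step length
        # (only reachable for caller-supplied point lists, not traced ones).
        return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    diag = (ad[:, 0] == 1) & (ad[:, 1] == 1)
    ortho = (ad.sum(axis=1) == 1)
    return float(np.sum(ortho) + _SQRT2 * np.sum(diag))


def convex_hull(points: Sequence[Sequence[float]]) -> np.ndarray:
    """Convex hull of a 2-D point set by Andrew's monotone chain.

    Returns hull vertices in counter-clockwise order (x-right/y-up axes for
    (row, col) input), with collinear interior vertices removed.  If all
    points are collinear the two extreme endpoints are returned (degenerate
    hull; see :func:`hull_perimeter`).
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return pts
    # Sort lexicographically by (col, row) i.e. x then y.
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[1] - o[1]) * (b[0] - o[0]) - (a[0] - o[0]) * (b[1] - o[1])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:  # all points collinear
        return np.array([pts[0], pts[-1]])
    # cross() above is signed for (row, col) with row pointing down; the
    # resulting chain is counter-clockwise in x-right/y-up convention.
    return hull


def hull_perimeter(hull: np.ndarray) -> float:
    """Closed Euclidean length of a hull vertex polygon.

    A degenerate 2-point hull (collinear input) measures twice the segment
    length: the 'polygon' is the segment traversed out and back.
    """
    hull = np.asarray(hull, dtype=float)
    if len(hull) < 2:
        raise ValueError("hull needs at least 2 vertices")
    if len(hull) == 2:
        return 2.0 * float(np.hypot(*(hull[1] - hull[0])))
    d = np.roll(hull, -1, axis=0) - hull
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def digital_hull_perimeter(hull: np.ndarray) -> float:
    """Chain-code length of the rasterized convex hull outline.

    The hull polygon is filled on a local pixel grid, its boundary re-traced,
    and measured with the same (1, √2) chain code as the colony outline, so
    both lengths share one digital metric (see module docstring).
    """
    hull = np.asarray(hull, dtype=float)
    if len(hull) < 3:
        return hull_perimeter(hull)
    rmin, cmin = np.floor(hull.min(axis=0)).astype(int)
    local = hull - [rmin, cmin] + 1  # 1-px margin
    shape = tuple(np.ceil(local.max(axis=0)).astype(int) + 2)
    rr, cc = draw_polygon(local[:, 0], local[:, 1], shape=shape)
    canvas = np.zeros(shape, dtype=bool)
    canvas[rr, cc] = True
    # draw_polygon can miss vertex pixels on acute corners; stamp them in.
    vr = np.clip(np.round(local[:, 0]).astype(int), 0, shape[0] - 1)
    vc = np.clip(np.round(local[:, 1]).astype(int), 0, shape[1] - 1)
    canvas[vr, vc] = True
    return perimeter_length(trace_boundary(canvas))


def colony_ratio(boundary: np.ndarray) -> float:
    """Hull-to-perimeter ratio of a traced colony boundary.

    R = (digital hull chain length) / (digital outline chain length),
    clamped to 1.0 when inside the (1, 1+RATIO_EPS] discretization band.
    1 indicates a smooth colony; values toward 0 indicate protrusions.
    """
    p = perimeter_length(boundary)
    h = digital_hull_perimeter(convex_hull(boundary))
    r = h / p
    if 1.0 < r <= 1.0 + RATIO_EPS:
        r = 1.0
    return r


def measure_well(mask: BinaryMask | np.ndarray, params: PipelineParams | None = None
                 ) -> list[ColonyMeasurement]:
    """Measure every colony in a binary well mask that passes the size filter.

    Components are labelled with 8-connectivity in row-major order; only
    components with area strictly greater than ``params.min_area`` are
    measured (smaller objects are treated as debris or single-cell origins).
    """
    if params is None:
        params = PipelineParams()
    if isinstance(mask, BinaryMask):
        px = mask.pixels
        s = mask.pixel_size
    else:
        px = np.asarray(mask, dtype=bool)
        s = params.pixel_size
    labels, n = ndi.label(px, structure=_EIGHT)
    out: list[ColonyMeasurement] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area <= params.min_area:
            continue
        rows, cols = np.nonzero(comp)
        touches = (rows.min() == 0 or cols.min() == 0
                   or rows.max() == px.shape[0] - 1 or cols.max() == px.shape[1] - 1)
        # Crop to the component (with margin) before tracing for speed.
        r0, r1 = rows.min(), rows.max()
        c0, c1 = cols.min(), cols.max()
        sub = comp[r0:r1 + 1, c0:c1 + 1]
        boundary = trace_boundary(sub)
        p = perimeter_length(boundary)
        h = digital_hull_perimeter(convex_hull(boundary))
        r = h / p
        if 1.0 < r <= 1.0 + RATIO_EPS:
            r = 1.0
        out.append(ColonyMeasurement(
            colony_id=len(out) + 1,
            area_px=area,
            area_um2=area * s * s,
            perimeter_px=p,
            hull_perimeter_px=h,
            ratio=r,
            centroid=(float(rows.mean()), float(cols.mean())),
            edge_touching=bool(touches),
        ))
    return out


def measurements_to_frame(measurements: Sequence[ColonyMeasurement],
                          plate_id: str = "", well: str = "",
                          condition: str = "", role: str = "") -> pd.DataFrame:
    """Tabulate colony measurements with plate/well annotations."""
    rows = []
    for m in measurements:
        d = asdict(m)
        d.pop("centroid")
        d.update(plate_id=plate_id, well=well, condition=condition, role=role,
                 centroid_row=m.centroid[0], centroid_col=m.centroid[1])
        rows.append(d)
    cols = ["plate_id", "well", "condition", "role", "colony_id", "area_px",
            "area_um2", "perimeter_px", "hull_perimeter_px", "ratio",
            "edge_touching", "centroid_row", "centroid_col"]
    return pd.DataFrame(rows, columns=cols)
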