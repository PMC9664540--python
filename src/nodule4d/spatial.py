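"""Spatial analyses: IN/ON vs OUT compartment classification, Delaunay
crowding, subROI count-vs-matrix-increase correlation, and the binarized
SHG/EGFP maximum-intensity-projection area ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import MultiPoint, Point

from . import statkit
from .morpho import CellRecord
from .segment import SurfaceModel, auto_threshold
from .stackio import ImageStack

log = logging.getLogger(__name__)


def footprint_polygon(surface: SurfaceModel, shrink: float = 0.5):
    """Concave boundary polygon of the surface's XY footprint.

    Mesh vertices are projected to XY and wrapped with a concave hull;
    ``shrink = 0`` gives the convex hull, larger values tighten the boundary
    monotonically (never adding area).
    """
    if not 0.0 <= shrink <= 1.0:
        raise ValueError("shrink must lie in [0, 1]")
    if surface.is_empty or len(surface.vertices) < 3:
        return None
    pts = MultiPoint(surface.vertices[:, :2])
    if shrink == 0.0:
        return pts.convex_hull
    poly = shapely.concave_hull(pts, ratio=1.0 - shrink)
    if poly.is_empty or poly.area == 0.0:
        return pts.convex_hull
    return poly


def classify_compartment(
    records: list[CellRecord], surface: SurfaceModel, shrink: float = 0.5
) -> list[CellRecord]:
    """Label each cell IN/ON or OUT.

    A cell is IN/ON iff its centroid lies inside the surface's XY boundary
    polygon (boundary points count as inside) AND its centroid z is at or
    above the lowest point of the surface.  Everything else is OUT.
    """
    poly = footprint_polygon(surface, shrink)
    if poly is None:
        log.warning("classify_compartment: empty surface, all cells OUT")
        for rec in records:
            rec.compartment = "OUT"
        return records
    for rec in records:
        x, y, z = rec.centroid
        inside = poly.covers(Point(x, y))  # covers: boundary ties are inside
        rec.compartment = "IN/ON" if (inside and z >= surface.z_min) else "OUT"
    n_in = sum(r.compartment == "IN/ON" for r in records)
    log.info("classify_compartment shrink=%.2f: %d IN/ON of %d", shrink, n_in, len(records))
    return records


def delaunay_mean_area(points_xy: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Delaunay triangulation of XY points; returns (mean area, areas, simplices).

    Degenerate (zero-area) triangles are excluded from the mean.
    """
    pts = np.asarray(points_xy, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 XY points")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # qhull raises on collinear input
        raise ValueError(f"Delaunay triangulation undefined: {exc}") from exc
    p = pts[tri.simplices]
    u = p[:, 1] - p[:, 0]
    v = p[:, 2] - p[:, 0]
    areas = 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    keep = areas > 1e-12 * max(areas.max(), 1.0)
    if not keep.any():
        raise ValueError("all Delaunay triangles are degenerate (collinear points)")
    return float(areas[keep].mean()), areas[keep], tri.simplices[keep]


@dataclass
class SubRoiTable:
    grid: tuple[int, int]
    table: pd.DataFrame  # row, col, n_high_sphericity, delta_shg
    rho: float
    p_value: float
    category: str


def subroi_correlation(
    records: list[CellRecord],
    surface_t: SurfaceModel,
    surface_t1: SurfaceModel,
    grid: tuple[int, int] = (4, 4),
    use_area: bool = False,
) -> SubRoiTable:
    """Tile the field into a grid (default 4 x 4 = 16 subROIs) and correlate
    the count of high-sphericity IN/ON cells at t with the local SHG increase
    from t to t+1 (Spearman, with the banded strength category).

    Cells are assigned to tiles by centroid; SHG change by voxel XY position.
    ``use_area`` switches the change measure from volume to projected area.
    """
    cal = surface_t.calibration
    mask_t, mask_t1 = surface_t.mask, surface_t1.mask
    if mask_t.shape != mask_t1.shape:
        raise ValueError("surfaces must come from the same registered field")
    Z, Y, X = mask_t.shape
    rows, cols = grid
    if Y % rows or X % cols:
        raise ValueError(f"grid {grid} does not tile the {Y} x {X} field exactly")
    ty, tx = Y // rows, X // cols

    if use_area:
        proj_t = mask_t.any(axis=0).astype(np.int64)
        proj_t1 = mask_t1.any(axis=0).astype(np.int64)
        unit = cal.dx * cal.dy
    else:
        proj_t = mask_t.sum(axis=0, dtype=np.int64)
        proj_t1 = mask_t1.sum(axis=0, dtype=np.int64)
        unit = cal.voxel_volume

    entries = []
    for r in range(rows):
        for c in range(cols):
            ys, xs = slice(r * ty, (r + 1) * ty), slice(c * tx, (c + 1) * tx)
            delta = float(proj_t1[ys, xs].sum() - proj_t[ys, xs].sum()) * unit
            n_high = 0
            for rec in records:
                if rec.compartment != "IN/ON" or not rec.high_sphericity:
                    continue
                cx, cy = rec.centroid[0] / cal.dx, rec.centroid[1] / cal.dy
                if r * ty <= cy < (r + 1) * ty and c * tx <= cx < (c + 1) * tx:
                    n_high += 1
            entries.append(
                {"row": r, "col": c, "n_high_sphericity": n_high, "delta_shg": delta}
            )
    df = pd.DataFrame(entries)
    x = df.n_high_sphericity.to_numpy(dtype=float)
    y = df.delta_shg.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        rho, p, cat = np.nan, np.nan, "undefined"
    else:
        res = statkit.spearman_with_category(x, y)
        rho, p, cat = res.rho, res.p_value, res.category
    log.info("subroi_correlation grid=%s rho=%.3f (%s)", grid, rho, cat)
    return SubRoiTable(grid=grid, table=df, rho=rho, p_value=p, category=cat)


def mip_ratio(
    stack: ImageStack,
    timepoint: int,
    shg_channel: str = "SHG",
    egfp_channel: str = "EGFP",
    threshold: float | str = "otsu",
) -> float:
    """SHG / EGFP binarized-area ratio of the Z maximum-intensity projections."""
    ratios = {}
    for name in (shg_channel, egfp_channel):
        mip = np.asarray(stack.channel(name)[timepoint], dtype=np.float64).max(axis=0)
        thr = auto_threshold(mip, threshold) if isinstance(threshold, str) else float(threshold)
        ratios[name] = int((mip > thr).sum())
    if ratios[egfp_channel] == 0:
        raise ValueError(f"empty {egfp_channel} mask at t={timepoint}: ratio undefined")
    return ratios[shg_channel] / ratios[egfp_channel]


def mip_ratio_series(stack: ImageStack, **kwargs) -> pd.DataFrame:
    """Per-timepoint MIP ratio and its change relative to the first timepoint."""
    rows = []
    for t in range(stack.n_timepoints):
        r = mip_ratio(stack, t, **kwargs)
        rows.append({"timepoint": t, "ratio": r})
    df = pd.DataFrame(rows)
    df["ratio_change"] = df.ratio - df.ratio.iloc[0]
    return df
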