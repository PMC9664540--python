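"""Membrane-bleb detection and tracking, bleb polarity, and cell motility.

Blebs are transient bright regions revealed by temporal background removal:
the 2D route subtracts the per-pixel temporal minimum, thresholds, and links
per-frame components by mask overlap; the 4D route takes frame-by-frame
differences and spot-detects each difference frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from . import preproc
from .segment import auto_threshold, detect_spots, log_response, remove_small
from .stackio import Calibration

log = logging.getLogger(__name__)


@dataclass
class BlebTrack:
    track_id: int
    cell_id: int  # -1 when no host assignment was made
    birth_frame: int
    duration: float  # seconds: n_frames x frame interval
    n_frames: int
    areas: list[float]  # μm² per frame
    max_area: float  # μm²
    centroids: list[tuple[float, float]]  # x, y μm per frame
    theta_xy: float = np.nan  # degrees from host-cell centre


@dataclass
class CellTrack:
    cell_id: int
    frames: list[int]
    centroids: list[tuple[float, float, float]]  # x, y, z μm
    mean_speed: float  # μm/h
    group: str = "unassigned"


def detect_blebs_2d(
    movie: np.ndarray,
    calibration: Calibration,
    min_area_um2: float = 1.0,
    min_frames: int = 1,
    threshold: float | str = "robust",
) -> list[BlebTrack]:
    """Detect and track blebs in a (T, Y, X) movie.

    temporal-min subtraction -> automatic threshold -> per-frame connected
    components above ``min_area_um2`` -> frame-to-frame linking by mask
    overlap (nearest-centroid tie-break) -> tracks of >= ``min_frames``.

    The default threshold is the robust background model (median + 6 MAD):
    bleb pixels occupy far below 1% of a movie, where Otsu collapses into
    the background mode.  Pass ``threshold='otsu'`` or a number to override.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError(f"expected a (T, Y, X) movie, got shape {movie.shape}")
    cal = calibration
    if cal.frame_unit != "s":
        raise ValueError("bleb movies must be calibrated in seconds")
    sub = preproc.temporal_min_subtract(movie)
    thr = auto_threshold(sub, threshold) if isinstance(threshold, str) else float(threshold)
    px_area = cal.dx * cal.dy
    min_px = max(1, int(round(min_area_um2 / px_area)))

    frame_regions: list[list[dict]] = []
    for t in range(sub.shape[0]):
        mask = sub[t] > thr
        mask = remove_small(mask, min_px)
        labels = measure.label(mask)
        regs = []
        for r in measure.regionprops(labels):
            regs.append(
                {
                    "mask": labels == r.label,
                    "area": r.num_pixels * px_area,
                    "centroid": (r.centroid[1] * cal.dx, r.centroid[0] * cal.dy),
                }
            )
        frame_regions.append(regs)

    # link by mask overlap; ambiguous overlaps resolved by nearest centroid
    tracks: list[dict] = []
    active: list[dict] = []
    for t, regs in enumerate(frame_regions):
        assigned = [False] * len(regs)
        still_active = []
        for tr in active:
            prev_mask = tr["mask"]
            prev_cent = np.array(tr["centroids"][-1])
            best, best_dist = None, np.inf
            for i, reg in enumerate(regs):
                if assigned[i]:
                    continue
                if np.logical_and(prev_mask, reg["mask"]).any():
                    d = np.hypot(*(np.array(reg["centroid"]) - prev_cent))
                    if d < best_dist:
                        best, best_dist = i, d
            if best is not None:
                assigned[best] = True
                reg = regs[best]
                tr["mask"] = reg["mask"]
                tr["areas"].append(reg["area"])
                tr["centroids"].append(reg["centroid"])
                still_active.append(tr)
            else:
                tracks.append(tr)
        active = still_active
        for i, reg in enumerate(regs):
            if not assigned[i]:
                active.append(
                    {
                        "birth": t,
                        "mask": reg["mask"],
                        "areas": [reg["area"]],
                        "centroids": [reg["centroid"]],
                    }
                )
    tracks.extend(active)

    out: list[BlebTrack] = []
    tid = 0
    for tr in sorted(tracks, key=lambda d: (d["birth"], d["centroids"][0])):
        n = len(tr["areas"])
        if n < min_frames:
            continue
        out.append(
            BlebTrack(
                track_id=tid,
                cell_id=-1,
                birth_frame=tr["birth"],
                duration=n * cal.frame_interval,
                n_frames=n,
                areas=tr["areas"],
                max_area=float(max(tr["areas"])),
                centroids=tr["centroids"],
            )
        )
        tid += 1
    log.info("detect_blebs_2d: %d tracks (threshold %.4g)", len(out), thr)
    return out


@dataclass
class BlebSpot:
    frame: int
    position: tuple[float, float, float]  # x, y, z μm
    cell_id: int
    score: float = 0.0


def detect_blebs_4d(
    movie: np.ndarray,
    calibration: Calibration,
    host_centroids: dict[int, tuple[float, float, float]],
    host_radii: dict[int, float] | None = None,
    expected_radius_um: float = 1.5,
    distance_cap_factor: float = 1.5,
    threshold_rel: float = 0.3,
) -> list[BlebSpot]:
    """Detect bleb spots in a (T, Z, Y, X) movie via frame differences.

    Each difference frame is spot-detected (LoG) and every spot is assigned
    to the nearest host cell within ``distance_cap_factor`` x the host's
    equivalent radius (ties broken deterministically toward the lower cell
    id).  Raises if no host cells are provided.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 4:
        raise ValueError(f"expected a (T, Z, Y, X) movie, got shape {movie.shape}")
    if not host_centroids:
        raise ValueError("no segmented cells: host assignment impossible")
    diff = preproc.frame_difference(movie)
    ids = sorted(host_centroids)
    centres = np.array([host_centroids[i] for i in ids], dtype=float)
    if host_radii is None:
        caps = np.full(len(ids), np.inf)
    else:
        caps = np.array([distance_cap_factor * host_radii[i] for i in ids])
    # one detection threshold for the whole movie: per-frame maxima would
    # promote pure-noise peaks in frames without any appearing bleb
    global_max = max(
        float(log_response(diff[t], expected_radius_um, calibration).max())
        for t in range(diff.shape[0])
    )
    if global_max <= 0:
        return []
    spots: list[BlebSpot] = []
    for t in range(diff.shape[0]):
        cents, scores = detect_spots(
            diff[t], expected_radius_um, calibration,
            threshold_abs=threshold_rel * global_max,
        )
        for pos, sc in zip(cents, scores):
            d = np.linalg.norm(centres - pos, axis=1)
            order = np.lexsort((ids, d))  # nearest first, lower id on ties
            best = order[0]
            if d[best] <= caps[best]:
                spots.append(
                    BlebSpot(frame=t + 1, position=tuple(pos), cell_id=ids[best], score=float(sc))
                )
    log.info("detect_blebs_4d: %d spots over %d difference frames", len(spots), diff.shape[0])
    return spots


def bleb_polarity(
    spots: list[BlebSpot],
    host_centroids: dict[int, tuple[float, float, float]],
    bin_width_deg: float = 15.0,
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]], float]:
    """Angles of bleb spots around their host-cell centres.

    For displacement (dx, dy, dz): theta_xy = atan2(dy, dx),
    theta_zy = atan2(dz, dy), theta_zx = atan2(dz, dx), all in degrees in
    [-180, 180).  Returns the per-spot angle table, 15-degree histograms per
    plane, and the fraction of spots below the host (dz < 0).
    """
    rows = []
    n_skipped = 0
    for s in spots:
        host = np.asarray(host_centroids[s.cell_id], dtype=float)
        d = np.asarray(s.position, dtype=float) - host
        if np.allclose(d, 0):
            n_skipped += 1
            log.info("bleb_polarity: zero-displacement spot at frame %d skipped", s.frame)
            continue
        wrap = lambda a: ((np.degrees(a) + 180.0) % 360.0) - 180.0
        rows.append(
            {
                "frame": s.frame,
                "cell_id": s.cell_id,
                "dx": d[0],
                "dy": d[1],
                "dz": d[2],
                "theta_xy": wrap(np.arctan2(d[1], d[0])),
                "theta_zy": wrap(np.arctan2(d[2], d[1])),
                "theta_zx": wrap(np.arctan2(d[2], d[0])),
            }
        )
    df = pd.DataFrame(
        rows, columns=["frame", "cell_id", "dx", "dy", "dz", "theta_xy", "theta_zy", "theta_zx"]
    )
    edges = np.arange(-180.0, 180.0 + bin_width_deg, bin_width_deg)
    hists = {}
    for plane in ("theta_xy", "theta_zy", "theta_zx"):
        counts, _ = np.histogram(df[plane].to_numpy(), bins=edges)
        hists[plane] = (counts, edges)
    below = float((df.dz < 0).mean()) if len(df) else 0.0
    return df, hists, below


def track_cells(
    per_frame: list[list[tuple[int, tuple[float, float, float]]]],
    calibration: Calibration,
    max_step_um: float = 20.0,
    groups: dict[int, str] | None = None,
) -> list[CellTrack]:
    """Greedy nearest-centroid linking of per-timepoint segmented cells.

    ``per_frame[t]`` is a list of (cell id at t, centroid) pairs.  Mean speed
    is the mean consecutive step length divided by the frame interval,
    reported in μm/h.  A too-small gate fragments tracks; a warning is logged
    when the mean track length drops below 3 frames.
    """
    cal = calibration
    interval_h = {"s": cal.frame_interval / 3600.0, "min": cal.frame_interval / 60.0,
                  "h": cal.frame_interval, "day": cal.frame_interval * 24.0}[cal.frame_unit]
    tracks: list[dict] = []
    active: list[dict] = []
    for t, cells in enumerate(per_frame):
        taken = [False] * len(cells)
        nxt = []
        # greedy: shortest links first
        cands = []
        for ti, tr in enumerate(active):
            last = np.asarray(tr["centroids"][-1])
            for ci, (_, cent) in enumerate(cells):
                d = np.linalg.norm(np.asarray(cent) - last)
                if d <= max_step_um:
                    cands.append((d, ti, ci))
        used_tr = set()
        for d, ti, ci in sorted(cands):
            if ti in used_tr or taken[ci]:
                continue
            used_tr.add(ti)
            taken[ci] = True
            active[ti]["frames"].append(t)
            active[ti]["centroids"].append(cells[ci][1])
            active[ti]["ids"].append(cells[ci][0])
        for ti, tr in enumerate(active):
            (nxt if ti in used_tr else tracks).append(tr)
        active = nxt
        for ci, (cid, cent) in enumerate(cells):
            if not taken[ci]:
                active.append({"frames": [t], "centroids": [cent], "ids": [cid]})
    tracks.extend(active)

    out = []
    for k, tr in enumerate(sorted(tracks, key=lambda d: (d["frames"][0], d["centroids"][0]))):
        pts = np.asarray(tr["centroids"], dtype=float)
        if len(pts) > 1:
            steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            speed = float(steps.mean() / interval_h)
        else:
            speed = 0.0
        group = "unassigned"
        if groups is not None:
            group = groups.get(tr["ids"][0], "unassigned")
        out.append(
            CellTrack(
                cell_id=k,
                frames=tr["frames"],
                centroids=[tuple(p) for p in pts],
                mean_speed=speed,
                group=group,
            )
        )
    if out and np.mean([len(tr.frames) for tr in out]) < 3:
        log.warning("track_cells: mean track length < 3 frames; gate may be too small")
    return out
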