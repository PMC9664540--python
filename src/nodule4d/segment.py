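"""Segmentation: SHG surface model, labelled cells, lacuna spots, blob spots.

All physical outputs are in micrometres; point coordinates are (x, y, z) with
z = 0 at the dish bottom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from . import preproc
from .stackio import Calibration, ImageStack

log = logging.getLogger(__name__)


def remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components with fewer than ``min_size`` voxels."""
    if min_size <= 1:
        return mask
    # skimage >= 0.26 spells the threshold max_size (inclusive removal)
    return morphology.remove_small_objects(mask, max_size=min_size - 1)


def auto_threshold(values: np.ndarray, method: str = "otsu", k: float = 6.0) -> float:
    """Automatic global intensity threshold.

    ``otsu`` is the default for volumes with a substantial foreground
    fraction.  ``robust`` models the background as median + k * 1.4826 * MAD,
    which stays stable when the foreground occupies well under 1% of pixels
    (Otsu then tends to split the background mode instead).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot threshold an empty array")
    if method == "otsu":
        if np.ptp(values) == 0:
            return float(values[0]) + np.finfo(float).eps
        return float(threshold_otsu(values))
    if method == "robust":
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        return float(med + k * 1.4826 * mad)
    raise ValueError(f"unknown threshold method {method!r}")


@dataclass
class SurfaceModel:
    """Triangulated SHG isosurface with its voxel mask and summary measures."""

    vertices: np.ndarray  # (N, 3) x, y, z in μm
    faces: np.ndarray  # (M, 3) vertex indices
    volume: float  # μm³, mask voxel count x voxel volume
    area: float  # μm², triangle mesh area
    mask: np.ndarray  # (Z, Y, X) bool
    z_min: float  # μm, lowest mask voxel
    height_map: np.ndarray  # (Y, X) top surface height in μm, NaN outside
    calibration: Calibration = field(default_factory=Calibration)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    def mesh_volume(self) -> float:
        """Volume enclosed by the triangle mesh (divergence theorem), μm³."""
        if self.faces.size == 0:
            return 0.0
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(abs(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0))


@dataclass
class LabeledCells:
    labels: np.ndarray  # (Z, Y, X) int, background 0
    voxel_counts: dict[int, int]
    channel: str
    calibration: Calibration = field(default_factory=Calibration)

    @property
    def n_cells(self) -> int:
        return len(self.voxel_counts)


@dataclass
class LacunaSpot:
    centroid: tuple[float, float, float]  # x, y, z μm
    radius: float  # equivalent radius μm


def _mask_to_surface(mask: np.ndarray, cal: Calibration) -> SurfaceModel:
    mask = np.asarray(mask, dtype=bool)
    Z, Y, X = mask.shape
    if not mask.any():
        return SurfaceModel(
            vertices=np.zeros((0, 3)),
            faces=np.zeros((0, 3), dtype=int),
            volume=0.0,
            area=0.0,
            mask=mask,
            z_min=np.nan,
            height_map=np.full((Y, X), np.nan),
            calibration=cal,
        )
    volume = float(mask.sum()) * cal.voxel_volume
    padded = np.pad(mask.astype(np.float64), 1)
    smooth = ndi.gaussian_filter(padded, sigma=0.7)
    # keep the 0.5 level inside the data range even for thin objects
    level = min(0.5, 0.99 * smooth.max())
    verts, faces, _, _ = measure.marching_cubes(smooth, level=level, spacing=cal.spacing_zyx)
    verts -= np.array(cal.spacing_zyx)  # undo padding offset
    area = float(measure.mesh_surface_area(verts, faces))
    verts_xyz = verts[:, ::-1].copy()

    zi, yi, xi = np.nonzero(mask)
    z_min = float(zi.min()) * cal.dz
    height = np.full((Y, X), np.nan)
    top = np.where(mask.any(axis=0), mask.shape[0] - 1 - np.argmax(mask[::-1], axis=0), -1)
    cols = top >= 0
    height[cols] = top[cols] * cal.dz
    return SurfaceModel(
        vertices=verts_xyz,
        faces=faces,
        volume=volume,
        area=area,
        mask=mask,
        z_min=z_min,
        height_map=height,
        calibration=cal,
    )


def segment_shg(
    stack: ImageStack,
    channel: str = "SHG",
    timepoint: int = 0,
    threshold: float | str = "otsu",
    min_size: int = 50,
) -> SurfaceModel:
    """Binary SHG mask -> largest components -> isosurface mesh and measures.

    Volume is mask voxel count x voxel volume; area is the triangle-mesh
    area.  An empty mask is a valid early-timepoint outcome and yields a
    zero-volume model with a logged warning.
    """
    vol = np.asarray(stack.channel(channel)[timepoint], dtype=np.float64)
    thr = auto_threshold(vol, threshold) if isinstance(threshold, str) else float(threshold)
    mask = vol > thr
    mask = remove_small(mask, min_size)
    if not mask.any():
        log.warning("segment_shg: empty mask at t=%d (threshold %.4g)", timepoint, thr)
    surf = _mask_to_surface(mask, stack.calibration)
    log.info(
        "segment_shg t=%d thr=%.4g V=%.1f um3 A=%.1f um2", timepoint, thr, surf.volume, surf.area
    )
    return surf


def segment_cells(
    stack: ImageStack,
    channel: str = "EGFP",
    timepoint: int = 0,
    threshold: float | str = "otsu",
    min_volume: int = 200,
    seed_min_distance_um: float = 8.0,
) -> LabeledCells:
    """Threshold -> 3D connected components -> watershed split of touching cells.

    Watershed seeds are maxima of the smoothed Euclidean distance transform;
    components below ``min_volume`` voxels are discarded.  Zero cells is a
    valid outcome.
    """
    cal = stack.calibration
    vol = np.asarray(stack.channel(channel)[timepoint], dtype=np.float64)
    thr = auto_threshold(vol, threshold) if isinstance(threshold, str) else float(threshold)
    mask = vol > thr
    mask = remove_small(mask, min_volume)
    if not mask.any():
        return LabeledCells(np.zeros(mask.shape, dtype=np.int32), {}, channel, cal)

    dist = ndi.distance_transform_edt(mask, sampling=cal.spacing_zyx)
    dist_s = ndi.gaussian_filter(dist, sigma=1.0)
    cc = measure.label(mask)
    min_dist_vox = max(1, int(round(seed_min_distance_um / cal.dx)))
    peaks = peak_local_max(
        dist_s, labels=cc, min_distance=min_dist_vox, exclude_border=False
    )
    seeds = np.zeros(mask.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        seeds[tuple(p)] = i
    if seeds.max() == 0:  # degenerate: fall back to connected components
        labels = cc
    else:
        labels = segmentation.watershed(-dist_s, markers=seeds, mask=mask)
    # drop fragments below the minimum volume and relabel contiguously
    out = np.zeros(mask.shape, dtype=np.int32)
    counts: dict[int, int] = {}
    next_id = 1
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        n = int(sel.sum())
        if n < min_volume:
            continue
        out[sel] = next_id
        counts[next_id] = n
        next_id += 1
    log.info("segment_cells t=%d thr=%.4g -> %d cells", timepoint, thr, len(counts))
    return LabeledCells(out, counts, channel, cal)


def extract_lacunae(
    stack: ImageStack,
    channel: str = "SHG",
    timepoint: int = 0,
    h_depth: float = 0.1,
    min_size: int = 9,
    shg_mask: np.ndarray | None = None,
    median_radius: int = 1,
    basin_level: float = 0.5,
) -> list[LacunaSpot]:
    """Extract lacuna voids inside the SHG signal.

    Chain: median filter -> local contrast -> median filter (noise removal)
    -> regional-minima extraction (h-minima at depth ``h_depth`` of the
    contrast-enhanced dynamic range) -> cleanup by growing each minima seed
    into its dark basin (voxels below ``basin_level``) and dropping basins
    smaller than ``min_size`` voxels.  Only minima inside the filled matrix
    volume count: lacunae are voids *within* the nodule, so they lie inside
    its filled mask but outside the bright-voxel mask itself.
    """
    cal = stack.calibration
    sub = ImageStack(
        data=stack.channel(channel)[timepoint][None, :, None],
        calibration=cal,
        channel_names=(channel,),
    )
    filt = preproc.median_filter(sub, radius=median_radius)
    contr = preproc.local_contrast(filt)
    img = ndi.median_filter(contr.data[0, :, 0], size=(3, 3, 3))
    if shg_mask is None:
        shg_mask = segment_shg(stack, channel=channel, timepoint=timepoint).mask
    filled = ndi.binary_fill_holes(shg_mask)
    # seeds must sit clear of the matrix boundary, where local-contrast tile
    # artifacts create shallow dark rims that are not voids
    interior = ndi.binary_erosion(filled, iterations=3)

    seeds = (morphology.extrema.h_minima(img, h=h_depth * max(np.ptp(img), 1e-9)) > 0) & interior
    basins = measure.label((img < basin_level) & filled)
    keep = np.unique(basins[seeds])
    spots: list[LacunaSpot] = []
    for region in measure.regionprops(basins):
        if region.label not in keep or region.num_pixels < min_size:
            continue
        cz, cy, cx = region.centroid
        vol_um3 = region.num_pixels * cal.voxel_volume
        radius = (3.0 * vol_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        spots.append(LacunaSpot(centroid=(cx * cal.dx, cy * cal.dy, cz * cal.dz), radius=radius))
    log.info("extract_lacunae t=%d -> %d spots", timepoint, len(spots))
    return spots


def log_response(
    volume: np.ndarray, expected_radius_um: float, calibration: Calibration
) -> np.ndarray:
    """Scale-normalised (negated) Laplacian-of-Gaussian response at one scale.

    Sigmas are anisotropic in voxels so the physical scale is isotropic.
    """
    if expected_radius_um <= 0:
        raise ValueError("expected radius must be positive")
    vol = np.asarray(volume, dtype=np.float64)
    sigma_um = expected_radius_um / np.sqrt(vol.ndim)
    sigma_vox = tuple(sigma_um / s for s in calibration.spacing_zyx[-vol.ndim:])
    return -ndi.gaussian_laplace(vol, sigma=sigma_vox) * sigma_um**2


def detect_spots(
    volume: np.ndarray,
    expected_radius_um: float,
    calibration: Calibration,
    threshold_rel: float = 0.3,
    threshold_abs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale-matched blob detection (Laplacian-of-Gaussian contract).

    Returns (centroids, scores): centroids as (N, 3) x, y, z in μm.  The
    detection threshold is ``threshold_abs`` when given (useful to share one
    threshold across the frames of a movie), else ``threshold_rel`` x the
    response maximum of this volume.
    """
    vol = np.asarray(volume, dtype=np.float64)
    response = log_response(vol, expected_radius_um, calibration)
    if response.max() <= 0:
        return np.zeros((0, 3)), np.zeros(0)
    thr = threshold_abs if threshold_abs is not None else threshold_rel * response.max()
    peaks = peak_local_max(
        response,
        min_distance=max(1, int(round(expected_radius_um / calibration.dx))),
        threshold_abs=thr,
        exclude_border=False,
    )
    if peaks.size == 0:
        return np.zeros((0, 3)), np.zeros(0)
    scores = response[tuple(peaks.T)]
    d = np.array([calibration.dz, calibration.dy, calibration.dx])[-vol.ndim:]
    cent = (peaks * d)[:, ::-1]
    if vol.ndim == 2:  # pad to (x, y, z) with z = 0
        cent = np.column_stack([cent, np.zeros(len(cent))])
    return cent, scores
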