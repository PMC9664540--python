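"""Ground-truthed synthetic two-channel 4D scene generator.

Three scenarios are emulated so every downstream stage is testable offline:

* a multi-day nodule time course: a dome-shaped collagen deposit (SHG
  channel) whose volume follows a saturating logistic curve, carrying
  ellipsoidal on-matrix cells whose mean sphericity follows a per-timepoint
  schedule, flat off-matrix cells on the bare dish, and lacuna voids carved
  into the matrix;
* a seconds-scale bleb movie: static cells with transient membrane
  protrusions whose duration (log-normal) and maximum area (shifted gamma)
  are drawn from configured distributions and recorded per event;
* a drug-response experiment: a treated arm whose on-matrix sphericity rises
  at intermediate timepoints and returns to baseline at the final one, with
  boosted matrix growth, against a vehicle arm on the flat schedule.

Cells are rendered as solid triaxial ellipsoids (anti-aliased), so every
morphometric has a closed form for validation.  All randomness flows through
one ``numpy`` generator: identical (config, seed) reproduces stacks
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq

from .stackio import Calibration, ImageStack, write_table

log = logging.getLogger(__name__)

CHANNELS = ("EGFP", "SHG")  # channel 0 = cells, channel 1 = collagen


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GrowthParams:
    """Logistic nodule-volume growth: rises early, slows late."""

    saturation_um3: float = 55_000.0
    initial_fraction: float = 0.5  # of saturation, at the first timepoint
    rate_per_day: float = 0.25

    def volume_at(self, days: np.ndarray, first_day: float) -> np.ndarray:
        v0 = self.initial_fraction * self.saturation_um3
        t_mid = first_day + np.log(self.saturation_um3 / v0 - 1.0) / self.rate_per_day if \
            self.initial_fraction < 1.0 else first_day
        return self.saturation_um3 / (1.0 + np.exp(-self.rate_per_day * (np.asarray(days, float) - t_mid)))


@dataclass
class BlebKinetics:
    event_rate: float = 0.1  # events per cell per frame
    duration_mean_s: float = 27.0
    duration_sigma: float = 0.5  # log-normal shape
    area_mean_um2: float = 5.0
    area_min_um2: float = 1.5
    area_max_um2: float = 16.0  # hard cap (keeps blebs inside their margin)
    area_shape: float = 3.0  # gamma shape of the part above the minimum
    exclusion: str = "contacts"  # 'none', 'contacts' or 'lower_hemisphere'
    min_angle_sep_deg: float = 40.0


@dataclass
class Motility:
    on_matrix_um_h: float = 0.0
    off_matrix_um_h: float = 0.0


@dataclass
class NoiseModel:
    amplitude: float = 1.0
    background: float = 0.05
    gaussian_sd: float = 0.05
    poisson: bool = False
    poisson_photons: float = 200.0


@dataclass
class TreatmentParams:
    treated: bool = True
    baseline_sphericity: float = 0.50
    activated_sphericity: float = 0.70
    growth_boost: float = 1.4  # volume multiplier after treatment, >= 1
    return_tolerance: float = 0.02


@dataclass
class SceneConfig:
    """Full description of one synthetic scene.  See module docstring."""

    shape: tuple[int, int, int, int] = (4, 56, 352, 352)  # T, Z, Y, X
    voxel_size: tuple[float, float, float] = (0.4, 0.4, 0.4)  # dx, dy, dz μm
    frame_interval: float = 1.0
    frame_unit: str = "day"
    timepoints_days: tuple[float, ...] = (7.0, 10.0, 14.0, 21.0)
    growth: GrowthParams = field(default_factory=GrowthParams)
    dome_aspect: tuple[float, float, float] = (1.0, 0.9, 0.18)  # Rx : Ry : Rz
    n_cells_on: int = 6
    n_cells_off: int = 4
    sphericity_schedule: tuple[float, ...] = (0.7026, 0.65, 0.55, 0.45)
    off_matrix_sphericity: float = 0.50
    sphericity_sd: float = 0.04
    cell_volume_um3: float = 800.0
    cell_volume_sd: float = 120.0
    off_volume_factor: float = 0.6  # off-matrix cell volume relative to on-matrix
    cell_radius_um: float = 9.0  # disk radius for 2D bleb movies
    placement_scale: float = 0.85  # on-matrix cells within this fraction of footprint
    min_gap_um: float = 1.5
    max_place_tries: int = 3000
    lacuna_per_um3: float = 2.5e-4
    lacuna_radius_um: float = 1.6
    kinetics: BlebKinetics = field(default_factory=BlebKinetics)
    motility: Motility = field(default_factory=Motility)
    noise: NoiseModel = field(default_factory=NoiseModel)
    treatment: TreatmentParams | None = None
    volumetric: bool = False  # bleb movies: True renders 3D frames
    seed: int = 0

    def __post_init__(self) -> None:
        T = self.shape[0]
        if T < 2:
            raise ValueError("T must be >= 2")
        if any(s <= 0 for s in self.shape):
            raise ValueError("all grid sizes must be strictly positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be strictly positive")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be strictly positive")
        for psi in tuple(self.sphericity_schedule) + (self.off_matrix_sphericity,):
            if not 0.0 < psi <= 1.0:
                raise ValueError(f"sphericity schedule values must lie in (0, 1], got {psi}")
        if self.n_cells_on < 0 or self.n_cells_off < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.kinetics.event_rate < 0:
            raise ValueError("event rate must be nonnegative")

    @property
    def calibration(self) -> Calibration:
        return Calibration(
            voxel_size=self.voxel_size,
            frame_interval=self.frame_interval,
            frame_unit=self.frame_unit,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"schema_version": 1, **dataclasses.asdict(self)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d.pop("schema_version", None)
        for key, sub in (
            ("growth", GrowthParams),
            ("kinetics", BlebKinetics),
            ("motility", Motility),
            ("noise", NoiseModel),
            ("treatment", TreatmentParams),
        ):
            if d.get(key) is not None:
                d[key] = sub(**d[key])
        for key in ("shape", "voxel_size", "timepoints_days", "sphericity_schedule", "dome_aspect"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_nodule_config() -> SceneConfig:
    return SceneConfig()


def default_bleb_config() -> SceneConfig:
    return SceneConfig(
        shape=(160, 1, 420, 420),
        voxel_size=(0.3, 0.3, 1.0),
        frame_interval=15.0,
        frame_unit="s",
        n_cells_on=6,
        n_cells_off=0,
        cell_radius_um=7.0,
        volumetric=False,
    )


def default_bleb4d_config() -> SceneConfig:
    cfg = SceneConfig(
        shape=(16, 48, 192, 192),
        voxel_size=(0.4, 0.4, 0.4),
        frame_interval=9.0,
        frame_unit="s",
        n_cells_on=3,
        n_cells_off=0,
        volumetric=True,
    )
    cfg.kinetics = BlebKinetics(event_rate=0.6, exclusion="lower_hemisphere")
    return cfg


def default_bio_config(treated: bool = True) -> SceneConfig:
    cfg = SceneConfig(
        shape=(4, 48, 320, 320),
        timepoints_days=(0.0, 3.0, 7.0, 14.0),
        growth=GrowthParams(saturation_um3=40_000.0, initial_fraction=0.5, rate_per_day=0.15),
        n_cells_on=5,
        n_cells_off=0,
        cell_volume_um3=700.0,
        treatment=TreatmentParams(treated=treated),
    )
    return cfg


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class CellTruth:
    cell_id: int
    timepoint: int
    centroid: tuple[float, float, float]  # x, y, z μm
    semi_axes: tuple[float, float, float]  # a >= b >= c μm
    orientation_rad: float
    volume: float
    sphericity: float
    compartment: str  # IN/ON or OUT


@dataclass
class LacunaTruth:
    lacuna_id: int
    centroid: tuple[float, float, float]
    radius: float


@dataclass
class BlebEventTruth:
    event_id: int
    cell_id: int
    birth_frame: int
    duration_s: float  # sampled value
    n_frames: int  # rendered frames (0 when skipped)
    max_area_um2: float
    direction: tuple[float, float, float]  # unit vector
    rendered: bool


@dataclass
class TrajectoryTruth:
    cell_id: int
    group: str  # on-matrix or off-matrix
    positions: np.ndarray  # (T, 3) x, y, z μm
    speed_um_h: float  # true mean step speed


@dataclass
class GroundTruth:
    """The generator's record of every rendered object and event."""

    config: SceneConfig
    shg_volume: list[float] = field(default_factory=list)  # per timepoint, μm³
    shg_area: list[float] = field(default_factory=list)  # per timepoint, μm²
    cells: list[CellTruth] = field(default_factory=list)
    lacunae: list[LacunaTruth] = field(default_factory=list)
    blebs: list[BlebEventTruth] = field(default_factory=list)
    trajectories: list[TrajectoryTruth] = field(default_factory=list)

    def cells_at(self, timepoint: int, compartment: str | None = None) -> list[CellTruth]:
        out = [c for c in self.cells if c.timepoint == timepoint]
        if compartment is not None:
            out = [c for c in out if c.compartment == compartment]
        return out

    def rendered_blebs(self) -> list[BlebEventTruth]:
        return [b for b in self.blebs if b.rendered]

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        write_table(self.cells, out / "truth_cells.csv")
        write_table(self.lacunae, out / "truth_lacunae.csv")
        write_table(self.blebs, out / "truth_blebs.csv")
        rows = [
            {"timepoint": t, "shg_volume_um3": v, "shg_area_um2": a}
            for t, (v, a) in enumerate(zip(self.shg_volume, self.shg_area))
        ]
        write_table(rows, out / "truth_shg.csv")
        traj_rows = []
        for tr in self.trajectories:
            for t, p in enumerate(tr.positions):
                traj_rows.append(
                    {"cell_id": tr.cell_id, "group": tr.group, "frame": t,
                     "x": p[0], "y": p[1], "z": p[2], "speed_um_h": tr.speed_um_h}
                )
        write_table(traj_rows, out / "truth_trajectories.csv")


# ---------------------------------------------------------------------------
# geometry helpers


def ellipsoid_area(a: float, b: float, c: float) -> float:
    """Thomsen's approximation to the triaxial ellipsoid surface area (<~1.1% error)."""
    p = 1.6075
    return 4.0 * np.pi * ((a**p * b**p + a**p * c**p + b**p * c**p) / 3.0) ** (1.0 / p)


def ellipsoid_sphericity(a: float, b: float, c: float) -> float:
    v = 4.0 / 3.0 * np.pi * a * b * c
    return float(np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / ellipsoid_area(a, b, c))


def solve_flattening(psi: float, beta: float = 1.0) -> float:
    """c/a ratio of an ellipsoid with b = beta * a and target sphericity psi."""
    if not 0 < psi <= 1:
        raise ValueError("sphericity must lie in (0, 1]")
    hi = beta * 0.999
    f = lambda r: ellipsoid_sphericity(1.0, beta, r) - psi
    if f(hi) < 0:  # target above the family's maximum; use the roundest member
        return hi
    return float(brentq(f, 1e-4, hi))


def axes_for(psi: float, volume: float, beta: float) -> tuple[float, float, float]:
    """Semi-axes (a, b, c) of an ellipsoid with given sphericity and volume."""
    r = solve_flattening(psi, beta)
    a = (3.0 * volume / (4.0 * np.pi * beta * r)) ** (1.0 / 3.0)
    return a, beta * a, r * a


def _render_ellipsoid(
    channel: np.ndarray,
    spacing_zyx: tuple[float, float, float],
    centre_xyz: tuple[float, float, float],
    axes_xyz: tuple[float, float, float],
    phi: float = 0.0,
    amplitude: float = 1.0,
    half: bool = False,
) -> None:
    """Add (or carve) an anti-aliased solid ellipsoid into a (Z, Y, X) volume.

    ``axes_xyz`` are the semi-axes along the rotated x/y axes and z; ``phi``
    rotates the ellipsoid about z.  ``half=True`` renders only z >= 0 of an
    ellipsoid centred on the dish plane (a dome).
    """
    dz, dy, dx = spacing_zyx
    cx, cy, cz = centre_xyz
    ax, ay, az = axes_xyz
    w = 0.7 * (dx * dy * dz) ** (1 / 3)  # edge softness, physical units
    pad = 2.5 * w
    Z, Y, X = channel.shape
    zi0 = max(0, int((cz - az - pad) / dz)) if not half else max(0, int((cz - pad) / dz))
    zi1 = min(Z, int((cz + az + pad) / dz) + 2)
    ext = max(ax, ay) + pad
    yi0, yi1 = max(0, int((cy - ext) / dy)), min(Y, int((cy + ext) / dy) + 2)
    xi0, xi1 = max(0, int((cx - ext) / dx)), min(X, int((cx + ext) / dx) + 2)
    if zi0 >= zi1 or yi0 >= yi1 or xi0 >= xi1:
        return
    z = (np.arange(zi0, zi1) * dz - cz)[:, None, None]
    y = (np.arange(yi0, yi1) * dy - cy)[None, :, None]
    x = (np.arange(xi0, xi1) * dx - cx)[None, None, :]
    ct, st = np.cos(phi), np.sin(phi)
    xr = x * ct + y * st
    yr = -x * st + y * ct
    q = (xr / ax) ** 2 + (yr / ay) ** 2 + (z / az) ** 2
    g = np.sqrt(np.maximum(q, 1e-12))
    grad = np.sqrt((xr / ax**2) ** 2 + (yr / ay**2) ** 2 + (z / az**2) ** 2) / g
    dist = (g - 1.0) / np.maximum(grad, 1e-9)
    cov = np.clip(0.5 - dist / w, 0.0, 1.0)
    view = channel[zi0:zi1, yi0:yi1, xi0:xi1]
    np.maximum(view, amplitude * cov, out=view)


def _carve_ellipsoid(channel, spacing_zyx, centre_xyz, radius) -> None:
    """Multiply a (Z, Y, X) volume by (1 - coverage) of a sphere: a void."""
    dz, dy, dx = spacing_zyx
    cx, cy, cz = centre_xyz
    w = 0.7 * (dx * dy * dz) ** (1 / 3)
    pad = radius + 2.5 * w
    Z, Y, X = channel.shape
    zi0, zi1 = max(0, int((cz - pad) / dz)), min(Z, int((cz + pad) / dz) + 2)
    yi0, yi1 = max(0, int((cy - pad) / dy)), min(Y, int((cy + pad) / dy) + 2)
    xi0, xi1 = max(0, int((cx - pad) / dx)), min(X, int((cx + pad) / dx) + 2)
    if zi0 >= zi1 or yi0 >= yi1 or xi0 >= xi1:
        return
    z = (np.arange(zi0, zi1) * dz - cz)[:, None, None]
    y = (np.arange(yi0, yi1) * dy - cy)[None, :, None]
    x = (np.arange(xi0, xi1) * dx - cx)[None, None, :]
    dist = np.sqrt(x**2 + y**2 + z**2) - radius
    cov = np.clip(0.5 - dist / w, 0.0, 1.0)
    channel[zi0:zi1, yi0:yi1, xi0:xi1] *= 1.0 - cov


def _ellipse_points(centre, a, b, phi, n=48):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ct, st = np.cos(phi), np.sin(phi)
    x = a * np.cos(t)
    y = b * np.sin(t)
    return np.column_stack([centre[0] + x * ct - y * st, centre[1] + x * st + y * ct])


def _ellipses_overlap(c1, a1, b1, p1, c2, a2, b2, p2, gap=0.0) -> bool:
    """Conservative 2D ellipse-overlap test via boundary sampling."""
    d = np.hypot(c1[0] - c2[0], c1[1] - c2[1])
    if d > a1 + a2 + gap:
        return False
    if d <= max(b1, b2):
        return True

    def inside(pts, c, a, b, p, g):
        ct, st = np.cos(p), np.sin(p)
        x = pts[:, 0] - c[0]
        y = pts[:, 1] - c[1]
        xr = x * ct + y * st
        yr = -x * st + y * ct
        return np.any((xr / (a + g)) ** 2 + (yr / (b + g)) ** 2 < 1.0)

    return inside(_ellipse_points(c1, a1, b1, p1), c2, a2, b2, p2, gap) or inside(
        _ellipse_points(c2, a2, b2, p2), c1, a1, b1, p1, gap
    )


def _apply_noise(frame: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = noise.background + frame
    if noise.poisson:
        out = rng.poisson(np.maximum(out, 0) * noise.poisson_photons) / noise.poisson_photons
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None).astype(np.float32)


# ---------------------------------------------------------------------------
# nodule time course


def _dome_axes(volume: float, aspect: tuple[float, float, float]) -> tuple[float, float, float]:
    """Semi-axes of a half-ellipsoid dome of the given volume, V = 2/3 pi Rx Ry Rz."""
    rx, ry, rz = aspect
    k = volume / (2.0 / 3.0 * np.pi * rx * ry * rz)
    s = k ** (1.0 / 3.0)
    return rx * s, ry * s, rz * s


def _dome_height(x, y, Rx, Ry, Rz, cx, cy) -> float:
    q = 1.0 - ((x - cx) / Rx) ** 2 - ((y - cy) / Ry) ** 2
    return Rz * np.sqrt(q) if q > 0 else 0.0


def _place_on_matrix_cells(
    cfg: SceneConfig, rng, Rx, Ry, cx, cy, psis, volumes
) -> list[dict]:
    """Random sequential placement of non-overlapping ellipsoidal cells inside
    the dome footprint.  Raises when the configured density cannot be packed."""
    placed: list[dict] = []
    sx, sy = cfg.placement_scale * Rx, cfg.placement_scale * Ry
    order = np.argsort(volumes)[::-1]  # largest first packs more reliably
    for i in order:
        psi, vol = psis[i], volumes[i]
        beta = rng.uniform(0.78, 0.95)
        phi = rng.uniform(0.0, np.pi)
        ok = False
        # if a cell cannot be placed, retry at reduced volume before giving up
        for vol_try in (vol, 0.8 * vol, 0.64 * vol):
            a, b, c = axes_for(psi, vol_try, beta)
            for _ in range(cfg.max_place_tries):
                u, v = rng.uniform(-1, 1), rng.uniform(-1, 1)
                if u * u + v * v > 1.0:
                    continue
                x, y = cx + u * sx, cy + v * sy
                if any(
                    _ellipses_overlap((x, y), a, b, phi, p["xy"], p["a"], p["b"], p["phi"],
                                      gap=cfg.min_gap_um / 2)
                    for p in placed
                ):
                    continue
                placed.append({"xy": (x, y), "a": a, "b": b, "c": c, "phi": phi, "psi": psi,
                               "vol": vol_try})
                ok = True
                break
            if ok:
                break
        if not ok:
            raise RuntimeError(
                f"could not place on-matrix cell after {cfg.max_place_tries} tries: "
                f"configured density too high ({len(psis)} cells of "
                f"~{np.mean(volumes):.0f} um3 in a {sx:.0f} x {sy:.0f} um footprint)"
            )
    return placed


def _sample_sphericities(rng, n: int, target: float, sd: float) -> np.ndarray:
    """Sphericity sample with empirical mean pinned exactly to the target."""
    if n == 0:
        return np.zeros(0)
    psi = rng.normal(target, sd, size=n)
    psi = np.clip(psi, 0.42, 0.93)
    psi = psi + (target - psi.mean())
    return np.clip(psi, 0.40, 0.95)


def generate_nodule_timecourse(
    config: SceneConfig | None = None, seed: int | None = None
) -> tuple[ImageStack, GroundTruth]:
    """Render the multi-day nodule formation scene.  See module docstring."""
    cfg = config or default_nodule_config()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    T, Z, Y, X = cfg.shape
    days = cfg.timepoints_days
    if len(days) != T:
        raise ValueError(f"{T} timepoints but {len(days)} entries in timepoints_days")
    sched = cfg.sphericity_schedule
    if len(sched) != T:
        raise ValueError(f"{T} timepoints but {len(sched)} sphericity schedule entries")
    dx, dy, dz = cfg.voxel_size
    spacing = (dz, dy, dx)
    cx, cy = (X - 1) * dx / 2.0, (Y - 1) * dy / 2.0

    vols = cfg.growth.volume_at(np.asarray(days), days[0])
    boost = np.ones(T)
    if cfg.treatment is not None and cfg.treatment.treated:
        boost[1:] = cfg.treatment.growth_boost
    vols = vols * boost

    # lacunae: fixed positions inside the first-timepoint dome, so the
    # constellation is constant over time (the lacuna Delaunay control)
    Rx0, Ry0, Rz0 = _dome_axes(vols[0], cfg.dome_aspect)
    n_lac = int(round(cfg.lacuna_per_um3 * vols[0]))
    lacunae: list[LacunaTruth] = []
    tries = 0
    while len(lacunae) < n_lac and tries < cfg.max_place_tries:
        tries += 1
        u, v = rng.uniform(-0.7, 0.7), rng.uniform(-0.7, 0.7)
        if u * u + v * v > 0.49:
            continue
        x, y = cx + u * Rx0, cy + v * Ry0
        h = _dome_height(x, y, Rx0, Ry0, Rz0, cx, cy)
        r = cfg.lacuna_radius_um
        if h < 2.0 * r + 2.0:  # void must fit fully inside the matrix
            continue
        z = rng.uniform(r + 0.8, h - r - 0.8)
        if any(
            np.linalg.norm(np.subtract((x, y, z), l.centroid)) < 4.0 * cfg.lacuna_radius_um
            for l in lacunae
        ):
            continue
        lacunae.append(LacunaTruth(len(lacunae), (x, y, z), cfg.lacuna_radius_um))

    data = np.zeros((T, Z, 2, Y, X), dtype=np.float32)
    truth = GroundTruth(config=cfg, lacunae=lacunae)
    amp = cfg.noise.amplitude

    # off-matrix placement region: outside the final footprint
    Rxf, Ryf, _ = _dome_axes(vols[-1], cfg.dome_aspect)

    cell_id = 0
    for t in range(T):
        Rx, Ry, Rz = _dome_axes(vols[t], cfg.dome_aspect)
        if Rx * 2 > (X - 4) * dx or Ry * 2 > (Y - 4) * dy or Rz > (Z - 6) * dz:
            raise ValueError("configured nodule does not fit the grid")
        shg = np.zeros((Z, Y, X), dtype=np.float64)
        _render_ellipsoid(shg, spacing, (cx, cy, 0.0), (Rx, Ry, Rz), amplitude=1.0, half=True)
        for lac in lacunae:
            _carve_ellipsoid(shg, spacing, lac.centroid, lac.radius)
        # analytic truth, independent of rasterisation: half-ellipsoid minus voids
        true_vol = vols[t] - sum(4.0 / 3.0 * np.pi * l.radius**3 for l in lacunae)
        true_area = (
            0.5 * ellipsoid_area(Rx, Ry, Rz)
            + np.pi * Rx * Ry
            + sum(4.0 * np.pi * l.radius**2 for l in lacunae)
        )
        truth.shg_volume.append(float(true_vol))
        truth.shg_area.append(float(true_area))

        egfp = np.zeros((Z, Y, X), dtype=np.float64)
        psis_on = _sample_sphericities(rng, cfg.n_cells_on, sched[t], cfg.sphericity_sd)
        vols_on = np.clip(
            rng.normal(cfg.cell_volume_um3, cfg.cell_volume_sd, size=cfg.n_cells_on),
            0.6 * cfg.cell_volume_um3,
            1.4 * cfg.cell_volume_um3,
        )
        placed = _place_on_matrix_cells(cfg, rng, Rx, Ry, cx, cy, psis_on, vols_on)
        for p in placed:
            x, y = p["xy"]
            zc = _dome_height(x, y, Rx, Ry, Rz, cx, cy) + p["c"]
            _render_ellipsoid(
                egfp, spacing, (x, y, zc), (p["a"], p["b"], p["c"]), phi=p["phi"], amplitude=1.0
            )
            axes_sorted = tuple(sorted((p["a"], p["b"], p["c"]), reverse=True))
            truth.cells.append(
                CellTruth(cell_id, t, (x, y, zc), axes_sorted, p["phi"], p["vol"],
                          ellipsoid_sphericity(*axes_sorted), "IN/ON")
            )
            cell_id += 1

        # off-matrix: flat cells on the bare dish, outside the final footprint
        psis_off = _sample_sphericities(
            rng, cfg.n_cells_off, cfg.off_matrix_sphericity, cfg.sphericity_sd / 2
        )
        placed_off: list[dict] = []
        W, H = (X - 1) * dx, (Y - 1) * dy
        for i in range(cfg.n_cells_off):
            beta = rng.uniform(0.80, 0.95)
            a, b, c = axes_for(psis_off[i], cfg.off_volume_factor * cfg.cell_volume_um3, beta)
            phi = rng.uniform(0.0, np.pi)
            # off-matrix cells live on the bare dish outside the final nodule
            # footprint, i.e. in the field corners; cycle through the corners
            lo, box = a + 3.0, 34.0
            corners = [(lo, lo), (W - lo - box, lo), (lo, H - lo - box), (W - lo - box, H - lo - box)]
            ok = False
            for tri in range(cfg.max_place_tries):
                bx, by = corners[(i + tri) % 4]
                x = rng.uniform(bx, bx + box)
                y = rng.uniform(by, by + box)
                if ((x - cx) / (Rxf + a + 4.0)) ** 2 + ((y - cy) / (Ryf + a + 4.0)) ** 2 <= 1.0:
                    continue
                if any(
                    _ellipses_overlap((x, y), a, b, phi, q["xy"], q["a"], q["b"], q["phi"],
                                      gap=cfg.min_gap_um / 2)
                    for q in placed_off
                ):
                    continue
                placed_off.append({"xy": (x, y), "a": a, "b": b, "phi": phi})
                _render_ellipsoid(egfp, spacing, (x, y, c), (a, b, c), phi=phi, amplitude=1.0)
                axes_sorted = tuple(sorted((a, b, c), reverse=True))
                truth.cells.append(
                    CellTruth(cell_id, t, (x, y, c), axes_sorted, phi,
                              4 / 3 * np.pi * a * b * c,
                              ellipsoid_sphericity(*axes_sorted), "OUT")
                )
                cell_id += 1
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place off-matrix cell {i + 1}/{cfg.n_cells_off}: "
                    "no dish space outside the final nodule footprint"
                )

        data[t, :, 0] = _apply_noise(amp * egfp, cfg.noise, rng)
        data[t, :, 1] = _apply_noise(amp * shg, cfg.noise, rng)

    stack = ImageStack(data=data, calibration=cfg.calibration, channel_names=CHANNELS)
    log.info(
        "generate_nodule_timecourse: %d timepoints, %d cells, %d lacunae",
        T, len(truth.cells), len(lacunae),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# bleb movies


def _sample_direction(rng, exclusion: str) -> np.ndarray:
    while True:
        u = rng.normal(size=3)
        n = np.linalg.norm(u)
        if n < 1e-9:
            continue
        u = u / n
        if exclusion == "lower_hemisphere" and u[2] < 0.1:
            continue
        return u


def sample_bleb_events(
    cfg: SceneConfig, n_cells: int, rng: np.random.Generator
) -> list[BlebEventTruth]:
    """Draw the bleb event stream for a movie (the configured sampler).

    Durations are log-normal with the configured mean (in seconds); maximum
    areas are ``area_min + Gamma(shape)`` with the configured mean.  Events
    shorter than one frame interval are recorded with ``rendered=False`` and
    logged, never silently dropped.
    """
    kin = cfg.kinetics
    T = cfg.shape[0]
    dt = cfg.frame_interval
    mu = np.log(kin.duration_mean_s) - kin.duration_sigma**2 / 2.0
    gamma_mean = max(kin.area_mean_um2 - kin.area_min_um2, 1e-6)
    events: list[BlebEventTruth] = []
    active: dict[int, list[tuple[float, int]]] = {i: [] for i in range(n_cells)}
    eid = 0
    for t in range(T):
        for cell in range(n_cells):
            if rng.random() >= kin.event_rate:
                continue
            d = float(rng.lognormal(mu, kin.duration_sigma))
            n_frames = int(round(d / dt))
            area = float(
                min(kin.area_min_um2 + rng.gamma(kin.area_shape, gamma_mean / kin.area_shape),
                    kin.area_max_um2)
            )
            if cfg.volumetric:
                u = _sample_direction(rng, kin.exclusion)
            else:
                # free angles: avoid directions of recently active blebs
                ang = None
                recent = [a for a, last in active[cell] if last >= t - 1]
                for _ in range(12):
                    cand = rng.uniform(-np.pi, np.pi)
                    if all(
                        min(abs(cand - a), 2 * np.pi - abs(cand - a))
                        >= np.radians(kin.min_angle_sep_deg)
                        for a in recent
                    ):
                        ang = cand
                        break
                if ang is None:
                    continue  # no free surface direction right now
                u = np.array([np.cos(ang), np.sin(ang), 0.0])
            if n_frames < 1:
                log.info("bleb event %d shorter than one frame (%.1f s): skipped", eid, d)
                events.append(BlebEventTruth(eid, cell, t, d, 0, area, tuple(u), False))
                eid += 1
                continue
            if t + n_frames > T:
                continue  # would be truncated by the movie end; not an event
            events.append(BlebEventTruth(eid, cell, t, d, n_frames, area, tuple(u), True))
            if not cfg.volumetric:
                ang = float(np.arctan2(u[1], u[0]))
                active[cell].append((ang, t + n_frames - 1))
            eid += 1
    return events


def _bleb_area_profile(n: int) -> np.ndarray:
    """Per-frame area fractions: grows then shrinks, peak exactly 1."""
    x = (np.arange(n) + 0.5) / n
    p = 0.6 + 0.4 * np.sin(np.pi * x)
    return p / p.max()


def sample_trajectories(
    field_um: tuple[float, float],
    n_on: int,
    n_off: int,
    motility: Motility,
    n_frames: int,
    interval_h: float,
    rng: np.random.Generator,
    min_sep_um: float = 25.0,
    margin_um: float = 12.0,
    speed_jitter: float = 0.05,
) -> list[TrajectoryTruth]:
    """Collision-free random-walk trajectories with exact per-step speed.

    Each step has length speed x interval in a random XY direction,
    reflected at the field margin; candidate steps approaching another cell
    closer than ``min_sep_um`` are resampled.  ``speed_jitter`` is the
    relative SD of per-cell speed around the group mean.
    """
    W, H = field_um
    groups = ["on-matrix"] * n_on + ["off-matrix"] * n_off
    speeds = [motility.on_matrix_um_h] * n_on + [motility.off_matrix_um_h] * n_off
    if speed_jitter > 0:
        speeds = [s * max(0.2, rng.normal(1.0, speed_jitter)) for s in speeds]
    pos = []
    for _ in groups:
        for _ in range(5000):
            p = np.array([rng.uniform(margin_um, W - margin_um), rng.uniform(margin_um, H - margin_um)])
            if all(np.linalg.norm(p - q) >= min_sep_um for q in pos):
                pos.append(p)
                break
        else:
            raise RuntimeError(
                f"could not place {len(groups)} cells with {min_sep_um} um separation"
            )
    pos = np.array(pos)
    paths = np.zeros((n_frames, len(groups), 2))
    paths[0] = pos
    for t in range(1, n_frames):
        for i in range(len(groups)):
            step = speeds[i] * interval_h
            for _ in range(200):
                ang = rng.uniform(-np.pi, np.pi)
                cand = paths[t - 1, i] + step * np.array([np.cos(ang), np.sin(ang)])
                cand = np.clip(cand, margin_um, [W - margin_um, H - margin_um])
                others = [j for j in range(len(groups)) if j != i]
                ref = np.where(np.arange(len(groups))[others, None] < i, paths[t, others], paths[t - 1, others]) \
                    if others else np.zeros((0, 2))
                if all(np.linalg.norm(cand - r) >= min_sep_um * 0.8 for r in ref):
                    paths[t, i] = cand
                    break
            else:
                paths[t, i] = paths[t - 1, i]  # stuck this frame
    out = []
    for i, g in enumerate(groups):
        p3 = np.column_stack([paths[:, i], np.zeros(n_frames)])
        steps = np.linalg.norm(np.diff(paths[:, i], axis=0), axis=1)
        out.append(TrajectoryTruth(i, g, p3, float(steps.mean() / interval_h)))
    return out


def generate_bleb_movie(
    config: SceneConfig | None = None, seed: int | None = None
) -> tuple[ImageStack, GroundTruth]:
    """Render the seconds-scale bleb movie (2D frames by default, 3D when
    ``config.volumetric``).  Blebs appear only on free surfaces; an event
    rate of 0 gives a static movie with an empty truth list."""
    cfg = config or default_bleb_config()
    if cfg.frame_unit != "s":
        raise ValueError("bleb movies require a frame interval in seconds")
    if cfg.n_cells_on < 1:
        raise ValueError("bleb movies need at least one cell")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return (_generate_bleb_3d if cfg.volumetric else _generate_bleb_2d)(cfg, rng)


def _generate_bleb_2d(cfg: SceneConfig, rng) -> tuple[ImageStack, GroundTruth]:
    T, Z, Y, X = cfg.shape
    if Z != 1:
        raise ValueError("2D bleb movies require Z = 1")
    dx, dy, _ = cfg.voxel_size
    W, H = (X - 1) * dx, (Y - 1) * dy
    r_cell = cfg.cell_radius_um
    r_bleb_max = np.sqrt(cfg.kinetics.area_max_um2 / np.pi)
    bleb_ext = 1.8 * r_bleb_max  # centre offset (0.8 r) + radius, worst case
    margin = r_cell + bleb_ext + 3.0

    centres = []
    for i in range(cfg.n_cells_on):
        for _ in range(cfg.max_place_tries):
            p = np.array([rng.uniform(margin, W - margin), rng.uniform(margin, H - margin)])
            if all(np.linalg.norm(p - q) >= 2 * r_cell + 2 * bleb_ext + 2.0 for q in centres):
                centres.append(p)
                break
        else:
            raise RuntimeError(
                f"could not place {cfg.n_cells_on} cells of radius {r_cell} um "
                f"in a {W:.0f} x {H:.0f} um field"
            )

    events = sample_bleb_events(cfg, cfg.n_cells_on, rng)
    truth = GroundTruth(config=cfg, blebs=events)
    for i, c in enumerate(centres):
        truth.cells.append(
            CellTruth(i, 0, (c[0], c[1], 0.0), (r_cell, r_cell, r_cell), 0.0,
                      np.pi * r_cell**2, 1.0, "IN/ON")
        )

    # static base frame: cells + a matrix patch in the SHG channel
    base = np.zeros((Y, X), dtype=np.float64)
    yy = np.arange(Y)[:, None] * dy
    xx = np.arange(X)[None, :] * dx
    for c in centres:
        rr = np.hypot(xx - c[0], yy - c[1])
        np.maximum(base, np.clip(0.5 - (rr - r_cell) / (0.7 * dx), 0, 1), out=base)
    shg = np.zeros((Y, X), dtype=np.float64)
    rr = np.hypot(xx - W / 2, yy - H / 2)
    shg[rr < 0.45 * min(W, H)] = 1.0

    data = np.zeros((T, 1, 2, Y, X), dtype=np.float32)
    amp = cfg.noise.amplitude
    for t in range(T):
        frame = base.copy()
        for ev in events:
            if not ev.rendered or not (ev.birth_frame <= t < ev.birth_frame + ev.n_frames):
                continue
            prof = _bleb_area_profile(ev.n_frames)[t - ev.birth_frame]
            r_peak = np.sqrt(ev.max_area_um2 / np.pi)
            r_now = np.sqrt(prof) * r_peak
            cc = centres[ev.cell_id]
            bx = cc[0] + ev.direction[0] * (r_cell + 0.8 * r_peak)
            by = cc[1] + ev.direction[1] * (r_cell + 0.8 * r_peak)
            rr = np.hypot(xx - bx, yy - by)
            np.maximum(frame, np.clip(0.5 - (rr - r_now) / (0.7 * dx), 0, 1), out=frame)
        data[t, 0, 0] = _apply_noise(amp * frame, cfg.noise, rng)
        data[t, 0, 1] = _apply_noise(amp * shg, cfg.noise, rng)

    stack = ImageStack(data=data, calibration=cfg.calibration, channel_names=CHANNELS)
    log.info("generate_bleb_movie(2D): %d frames, %d rendered events",
             T, len(truth.rendered_blebs()))
    return stack, truth


def _generate_bleb_3d(cfg: SceneConfig, rng) -> tuple[ImageStack, GroundTruth]:
    T, Z, Y, X = cfg.shape
    dx, dy, dz = cfg.voxel_size
    spacing = (dz, dy, dx)
    W, H = (X - 1) * dx, (Y - 1) * dy
    axes = (8.0, 8.0, 5.0)  # cell semi-axes, μm
    r_bleb = 1.5
    margin = axes[0] + 4.0

    centres = []
    for i in range(cfg.n_cells_on):
        for _ in range(cfg.max_place_tries):
            p = np.array([rng.uniform(margin, W - margin), rng.uniform(margin, H - margin)])
            if all(np.linalg.norm(p - q) >= 2 * axes[0] + 8.0 for q in centres):
                centres.append(p)
                break
        else:
            raise RuntimeError(f"could not place {cfg.n_cells_on} volumetric cells")

    events = sample_bleb_events(cfg, cfg.n_cells_on, rng)
    truth = GroundTruth(config=cfg, blebs=events)
    base = np.zeros((Z, Y, X), dtype=np.float64)
    for i, c in enumerate(centres):
        zc = axes[2]
        _render_ellipsoid(base, spacing, (c[0], c[1], zc), axes, amplitude=1.0)
        truth.cells.append(
            CellTruth(i, 0, (c[0], c[1], zc), tuple(sorted(axes, reverse=True)), 0.0,
                      4 / 3 * np.pi * np.prod(axes), ellipsoid_sphericity(*axes), "IN/ON")
        )

    data = np.zeros((T, Z, 2, Y, X), dtype=np.float32)
    amp = cfg.noise.amplitude
    shg = np.zeros((Z, Y, X), dtype=np.float32)  # bare-dish scenario: empty SHG
    for t in range(T):
        frame = base.copy()
        for ev in events:
            if not ev.rendered or not (ev.birth_frame <= t < ev.birth_frame + ev.n_frames):
                continue
            u = np.asarray(ev.direction)
            cc = centres[ev.cell_id]
            # surface point along u of an axis-aligned ellipsoid, pushed out
            scale = 1.0 / np.sqrt((u[0] / axes[0]) ** 2 + (u[1] / axes[1]) ** 2 + (u[2] / axes[2]) ** 2)
            centre = np.array([cc[0], cc[1], axes[2]]) + u * (scale + 0.6 * r_bleb)
            _render_ellipsoid(frame, spacing, tuple(centre), (r_bleb, r_bleb, r_bleb),
                              amplitude=1.0)
        data[t, :, 0] = _apply_noise(amp * frame, cfg.noise, rng)
        data[t, :, 1] = _apply_noise(amp * shg, cfg.noise, rng)

    stack = ImageStack(data=data, calibration=cfg.calibration, channel_names=CHANNELS)
    log.info("generate_bleb_movie(3D): %d frames, %d rendered events",
             T, len(truth.rendered_blebs()))
    return stack, truth


# ---------------------------------------------------------------------------
# drug-response experiment


def generate_bio_experiment(
    config: SceneConfig | None = None, seed: int | None = None
) -> tuple[ImageStack, GroundTruth]:
    """Render one arm of the drug-response experiment.

    ``config.treatment.treated`` selects the arm: the treated schedule raises
    on-matrix sphericity to the activated level at intermediate timepoints
    and returns it to baseline at the final one, and multiplies post-baseline
    matrix growth by the configured boost; the vehicle arm keeps the flat
    schedule and unboosted growth.
    """
    cfg = config or default_bio_config()
    if cfg.treatment is None:
        raise ValueError("bio experiment requires config.treatment")
    tr = cfg.treatment
    T = cfg.shape[0]
    if tr.treated:
        sched = [tr.baseline_sphericity] + [tr.activated_sphericity] * (T - 2) + [tr.baseline_sphericity]
    else:
        sched = [tr.baseline_sphericity] * T
    run_cfg = dataclasses.replace(cfg, sphericity_schedule=tuple(sched))
    return generate_nodule_timecourse(run_cfg, seed=seed)


# ---------------------------------------------------------------------------
# provenance


def simulate_to_dir(scenario: str, cfg: SceneConfig, seed: int, out_dir) -> None:
    """Render a scenario and write TIFF + ground-truth CSVs + config YAML."""
    from pathlib import Path

    from .stackio import save_stack

    gen = {
        "nodule": generate_nodule_timecourse,
        "bleb": generate_bleb_movie,
        "bio": generate_bio_experiment,
    }[scenario]
    stack, truth = gen(cfg, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_stack(stack, out / f"{scenario}.tif")
    truth.save(out)
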