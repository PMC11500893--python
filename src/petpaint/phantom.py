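"""Activity-painting phantom: lesion templates, source trajectories, background decay.

The physical experiment this module emulates moves a long-lived ²²Na point
source through a 5×5×5 cm³ grid inside a water tank filled with ¹⁸F solution.
Dwelling longer at a grid position deposits more time-integrated activity
there, so an arbitrary heterogeneous "lesion" pattern can be painted into the
acquisition while the tank provides a realistic, decaying background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

F18_HALF_LIFE_S = 6586.2
"""¹⁸F half-life in seconds."""

CUBE_MM = 50.0
"""Edge length of the painting volume (the linear stages cover 5 cm per axis)."""

DEFAULT_GRID_SPACING_MM = 2.5
"""Default painting-grid pitch; 50 mm cube -> 21³ grid positions."""

MAX_TRAVEL_SPEED_MM_S = 2.0
"""Speed cap between grid points, chosen to avoid surface waves in the tank."""


class PhantomError(ValueError):
    """Raised for invalid phantom geometry or scheduling requests."""


@dataclass(frozen=True)
class LesionTemplate:
    """Target 3-D activity pattern on the painting grid.

    ``values`` are relative activities (arbitrary units, >= 0); the support
    (strictly positive cells) defines the lesion volume.
    """

    name: str
    grid_spacing: float  # mm, isotropic
    values: np.ndarray  # 3-D, non-negative

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise PhantomError("template values must be a 3-D array")
        if np.any(v < 0) or not np.any(v > 0):
            raise PhantomError("template values must be >=0 with at least one >0")
        extent = np.array(v.shape) * self.grid_spacing
        if np.any(extent > CUBE_MM + 1e-9):
            raise PhantomError(
                f"template extent {extent} mm exceeds the {CUBE_MM} mm painting cube"
            )
        object.__setattr__(self, "values", v)

    @property
    def cell_volume_ml(self) -> float:
        return self.grid_spacing**3 / 1000.0

    @property
    def volume_ml(self) -> float:
        """Volume of the support: positive cells × cell volume, in mL."""
        return float(np.count_nonzero(self.values > 0) * self.cell_volume_ml)

    @property
    def support(self) -> np.ndarray:
        return self.values > 0

    def cell_centers_mm(self) -> np.ndarray:
        """(n, 3) physical centres of all grid cells, cube-centred coordinates."""
        idx = np.indices(self.values.shape).reshape(3, -1).T
        return (idx - (np.array(self.values.shape) - 1) / 2.0) * self.grid_spacing


@dataclass(frozen=True)
class TrajectoryPlan:
    """Ordered waypoints with dwell times for the point source."""

    waypoints: np.ndarray  # (n, 3) mm
    dwell_times: np.ndarray  # (n,) s
    travel_speed: float  # mm/s

    def __post_init__(self) -> None:
        w = np.asarray(self.waypoints, dtype=float).reshape(-1, 3)
        d = np.asarray(self.dwell_times, dtype=float).ravel()
        if len(w) == 0:
            raise PhantomError("trajectory has no waypoints")
        if len(w) != len(d):
            raise PhantomError("waypoints and dwell_times length mismatch")
        if np.any(d < 0):
            raise PhantomError("dwell times must be non-negative")
        if not (0 < self.travel_speed <= MAX_TRAVEL_SPEED_MM_S):
            raise PhantomError(
                f"travel speed must be in (0, {MAX_TRAVEL_SPEED_MM_S}] mm/s"
            )
        object.__setattr__(self, "waypoints", w)
        object.__setattr__(self, "dwell_times", d)

    @property
    def travel_time(self) -> float:
        seg = np.diff(self.waypoints, axis=0)
        return float(np.linalg.norm(seg, axis=1).sum() / self.travel_speed)

    @property
    def total_time(self) -> float:
        return float(self.dwell_times.sum()) + self.travel_time


@dataclass(frozen=True)
class PhantomSession:
    """One acquisition: tank, background activity at start, source, timing."""

    tank_volume_l: float
    background_activity_mbq: float  # at acquisition start
    acquisition_time_s: float
    background_half_life_s: float = F18_HALF_LIFE_S
    source_activity_mbq: float = 1.1  # ²²Na, constant over a session
    source_diameter_mm: float = 0.25
    time_inaccuracy_s: float = 0.0  # recorded metadata, not used downstream

    @property
    def background_concentration_kbq_ml(self) -> float:
        """Background concentration at session start (MBq/L == kBq/mL)."""
        return self.background_activity_mbq / self.tank_volume_l

    def mean_decay_factor(self) -> float:
        """Time-average of 2^(-t/T) over the acquisition window."""
        x = self.acquisition_time_s / self.background_half_life_s
        if x == 0:
            return 1.0
        return (1.0 - 2.0**-x) / (x * np.log(2.0))


def decay_background(activity0: float, elapsed: float, half_life: float = F18_HALF_LIFE_S) -> float:
    """Radioactive decay: activity0 × 2^(−elapsed/half_life)."""
    if activity0 <= 0 or half_life <= 0 or elapsed < 0:
        raise PhantomError("activity, half-life must be >0 and elapsed >=0")
    return float(activity0 * 2.0 ** (-elapsed / half_life))


def _lumpy_field(shape: tuple[int, int, int], n_blobs: int, blob_sigma_mm: float,
                 amp_spread: float, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Sum of random Gaussian blobs inside the cube; the heterogeneity engine."""
    zz, yy, xx = np.indices(shape, dtype=float)
    coords = np.stack([zz, yy, xx]) * spacing
    extent = (np.array(shape) - 1) * spacing
    fieldv = np.zeros(shape)
    for _ in range(n_blobs):
        # keep blob centres away from the faces so the support stays inside
        c = rng.uniform(0.22, 0.78, size=3) * extent
        amp = rng.uniform(1.0 - amp_spread, 1.0 + amp_spread)
        sigma = blob_sigma_mm * rng.uniform(0.7, 1.3)
        d2 = sum((coords[a] - c[a]) ** 2 for a in range(3))
        fieldv += amp * np.exp(-d2 / (2 * sigma**2))
    return fieldv


#: Canonical lesion presets: target volumes from the study design and an
#: increasing heterogeneity ordering (L1 most compact, L3 most complex).
LESION_PRESETS = {
    "L1": dict(volume_ml=8.66, n_blobs=2, blob_sigma_mm=9.0, amp_spread=0.2),
    "L2": dict(volume_ml=11.55, n_blobs=5, blob_sigma_mm=7.0, amp_spread=0.5),
    "L3": dict(volume_ml=15.44, n_blobs=9, blob_sigma_mm=5.5, amp_spread=0.8),
}


def generate_lesion(
    preset: str | None = None,
    *,
    volume_ml: float | None = None,
    n_blobs: int = 4,
    blob_sigma_mm: float = 7.0,
    amp_spread: float = 0.5,
    grid_spacing: float = DEFAULT_GRID_SPACING_MM,
    seed: int = 0,
    name: str | None = None,
) -> LesionTemplate:
    """Procedurally generate a heterogeneous lesion template.

    A lumpy Gaussian-blob mixture is evaluated on the painting grid and
    thresholded to the requested volume (the highest-density cells are kept).
    Deterministic for a fixed seed. Presets ``L1``–``L3`` reproduce the study
    lesion volumes (8.66, 11.55, 15.44 mL) with increasing heterogeneity.
    """
    if preset is not None:
        if preset not in LESION_PRESETS:
            raise PhantomError(f"unknown preset {preset!r}; choose from {sorted(LESION_PRESETS)}")
        p = LESION_PRESETS[preset]
        volume_ml = p["volume_ml"]
        n_blobs, blob_sigma_mm, amp_spread = p["n_blobs"], p["blob_sigma_mm"], p["amp_spread"]
        name = name or preset
        # fixed per-preset seed offsets keep the three lesions distinct under one seed
        seed = seed + {"L1": 101, "L2": 202, "L3": 303}[preset]
    if volume_ml is None:
        raise PhantomError("either a preset or a target volume_ml is required")

    n_cells = round(CUBE_MM / grid_spacing)
    shape = (n_cells, n_cells, n_cells)
    cell_ml = grid_spacing**3 / 1000.0
    n_target = int(round(volume_ml / cell_ml))
    if n_target < 1 or n_target > n_cells**3:
        raise PhantomError(
            f"requested volume {volume_ml} mL does not fit the {CUBE_MM} mm cube "
            f"at {grid_spacing} mm pitch"
        )

    rng = np.random.default_rng(seed)
    fieldv = _lumpy_field(shape, n_blobs, blob_sigma_mm, amp_spread, grid_spacing, rng)
    # keep the n_target densest cells; ties broken by flat index for determinism
    order = np.argsort(fieldv, axis=None, kind="stable")[::-1]
    mask = np.zeros(fieldv.size, dtype=bool)
    mask[order[:n_target]] = True
    mask = mask.reshape(shape)
    values = np.where(mask, fieldv, 0.0)
    values /= values.max()
    return LesionTemplate(name=name or "lesion", grid_spacing=grid_spacing, values=values)


def generate_sphere(radius_mm: float, *, grid_spacing: float = DEFAULT_GRID_SPACING_MM,
                    value: float = 1.0, name: str = "sphere") -> LesionTemplate:
    """Homogeneous digital ball template (all positive cells share one value)."""
    n = round(CUBE_MM / grid_spacing)
    zz, yy, xx = np.indices((n, n, n), dtype=float)
    c = (n - 1) / 2.0
    r2 = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * grid_spacing**2
    values = np.where(r2 <= radius_mm**2, value, 0.0)
    return LesionTemplate(name=name, grid_spacing=grid_spacing, values=values)


def plan_trajectory(template: LesionTemplate, max_speed: float = MAX_TRAVEL_SPEED_MM_S,
                    base_dwell: float = 2.0) -> TrajectoryPlan:
    """Serpentine raster visit of the template support with proportional dwells.

    The source visits every positive cell once in a raster-serpentine order
    (alternating row/plane directions to minimise travel); the dwell at cell i
    is ``base_dwell × value_i / max(value)``.
    """
    if max_speed > MAX_TRAVEL_SPEED_MM_S:
        raise PhantomError(f"max_speed {max_speed} exceeds the {MAX_TRAVEL_SPEED_MM_S} mm/s cap")
    if base_dwell <= 0:
        raise PhantomError("base_dwell must be positive")
    vals = template.values
    if not np.any(vals > 0):
        raise PhantomError("empty template")
    nz = np.argwhere(vals > 0)  # (n, 3) index order (z, y, x)
    # serpentine: sort by z; within z flip y direction on odd planes; within
    # (z, y) flip x on odd rows
    z, y, x = nz[:, 0], nz[:, 1], nz[:, 2]
    y_key = np.where(z % 2 == 0, y, vals.shape[1] - 1 - y)
    x_key = np.where((z + y_key) % 2 == 0, x, vals.shape[2] - 1 - x)
    order = np.lexsort((x_key, y_key, z))
    nz = nz[order]
    centers = (nz - (np.array(vals.shape) - 1) / 2.0) * template.grid_spacing
    v = vals[nz[:, 0], nz[:, 1], nz[:, 2]]
    dwells = base_dwell * v / v.max()
    return TrajectoryPlan(waypoints=centers, dwell_times=dwells, travel_speed=max_speed)


@dataclass(frozen=True)
class ActivityMap:
    """High-resolution ground-truth map of time-averaged activity concentration.

    ``values`` are kBq/mL averaged over the acquisition window; ``painted``
    holds the raw time-integrated source deposit per cell in MBq·s (for
    conservation checks). Cube-centred coordinates; isotropic ``spacing`` mm.
    """

    values: np.ndarray
    painted: np.ndarray
    spacing: float
    session: PhantomSession

    @property
    def origin(self) -> np.ndarray:
        """Physical coordinate of voxel (0,0,0) centre."""
        return -(np.array(self.values.shape) - 1) / 2.0 * self.spacing


def paint_ground_truth(
    template: LesionTemplate,
    plan: TrajectoryPlan,
    session: PhantomSession,
    *,
    fine_spacing: float = 1.0,
    margin_mm: float = 15.0,
) -> ActivityMap:
    """Render the painted pattern plus decaying background on a fine grid.

    Each dwell deposits ``dwell × source_activity`` MBq·s into the fine cell
    containing the waypoint (the 0.25 mm source is far smaller than any voxel,
    so it is treated as a point). The deposit is converted to a time-averaged
    concentration over the acquisition window and superposed on the uniform
    background at its time-averaged decayed concentration. Travel segments
    deposit nothing (travel time is a small fraction of dwell time and keeping
    it out makes the painted total exactly conserved).
    """
    if fine_spacing > template.grid_spacing:
        raise PhantomError("fine grid must be at least as fine as the painting grid")
    half = CUBE_MM / 2.0 + margin_mm
    n = int(round(2 * half / fine_spacing))
    painted = np.zeros((n, n, n))
    origin = -(n - 1) / 2.0 * fine_spacing
    idx = np.rint((plan.waypoints - origin) / fine_spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= n):
        raise PhantomError("trajectory leaves the rendered volume")
    cube_half = CUBE_MM / 2.0 + template.grid_spacing  # tolerance of one cell
    if np.any(np.abs(plan.waypoints) > cube_half):
        raise PhantomError("trajectory leaves the painting cube")
    np.add.at(painted, (idx[:, 0], idx[:, 1], idx[:, 2]),
              plan.dwell_times * session.source_activity_mbq)

    cell_ml = fine_spacing**3 / 1000.0
    t = session.acquisition_time_s
    # MBq·s per cell -> mean concentration over the window (kBq/mL)
    source_conc = painted * 1000.0 / (cell_ml * t) if t > 0 else np.zeros_like(painted)
    bg = session.background_concentration_kbq_ml * session.mean_decay_factor()
    return ActivityMap(values=source_conc + bg, painted=painted,
                       spacing=fine_spacing, session=session)


# --- session scheduling -------------------------------------------------------

#: Measurement log per scanner: water volume (L) and, per lesion, the background
#: activity at acquisition start (MBq) and the acquisition time (s). The decline
#: of the start activities across the three sequential sessions encodes both
#: the in-scan decay and the between-scan gaps of the physical schedule.
MEASUREMENT_SCHEDULE = {
    "Siemens Biograph TruePoint 64": dict(
        volume_l=15.1,
        initial_activity_mbq=(87.2, 70.8, 55.8),
        acquisition_time_s=(1730.0, 1883.0, 2600.0),
        time_inaccuracy_s=(-20.0, -1.0, -18.0),
    ),
    "Mediso AnyScan PET/CT": dict(
        volume_l=15.0,
        initial_activity_mbq=(88.5, 72.6, 57.6),
        acquisition_time_s=(1730.0, 1883.0, 2600.0),
        time_inaccuracy_s=(-20.0, -10.0, -8.0),
    ),
    "GE Discovery IQ": dict(
        volume_l=15.2,
        initial_activity_mbq=(88.1, 71.9, 57.1),
        acquisition_time_s=(1730.0, 1883.0, 2600.0),
        time_inaccuracy_s=(-4.0, -4.0, -4.0),
    ),
    "Philips Gemini TF 64": dict(
        volume_l=15.0,
        initial_activity_mbq=(89.4, 72.5, 58.1),
        acquisition_time_s=(1730.0, 1883.0, 2600.0),
        time_inaccuracy_s=(-8.0, -10.0, -6.0),
    ),
    "GE Discovery MI": dict(
        volume_l=15.0,
        initial_activity_mbq=(89.7, 73.3, 59.1),
        acquisition_time_s=(1730.0, 1883.0, 2600.0),
        time_inaccuracy_s=(-9.0, -7.0, -2.0),
    ),
}

LESION_ORDER = ("L1", "L2", "L3")


def build_sessions(scanner_name: str,
                   schedule: dict | None = None) -> dict[str, PhantomSession]:
    """Three sequential acquisition sessions (one per lesion) for one scanner."""
    sched = (schedule or MEASUREMENT_SCHEDULE).get(scanner_name)
    if sched is None:
        raise PhantomError(f"no schedule for scanner {scanner_name!r}")
    sessions = {}
    for i, lesion in enumerate(LESION_ORDER):
        sessions[lesion] = PhantomSession(
            tank_volume_l=sched["volume_l"],
            background_activity_mbq=sched["initial_activity_mbq"][i],
            acquisition_time_s=sched["acquisition_time_s"][i],
            time_inaccuracy_s=sched["time_inaccuracy_s"][i],
        )
    return sessions


def end_of_measurement_fraction(scanner_name: str,
                                schedule: dict | None = None) -> float:
    """Background activity at the end of the last session over the initial value.

    The last session's start activity already reflects all decay and gaps since
    the first session began; propagating it through the final acquisition gives
    the end-of-measurement background as a fraction of the initial activity.
    """
    sched = (schedule or MEASUREMENT_SCHEDULE)[scanner_name]
    a0 = sched["initial_activity_mbq"][0]
    a_last = sched["initial_activity_mbq"][-1]
    a_end = decay_background(a_last, sched["acquisition_time_s"][-1])
    return a_end / a0


def mean_water_volume_l(schedule: dict | None = None) -> float:
    """Mean tank water volume across the scanners in the measurement log."""
    sched = schedule or MEASUREMENT_SCHEDULE
    return float(np.mean([s["volume_l"] for s in sched.values()]))
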