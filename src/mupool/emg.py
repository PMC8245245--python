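"""Surface EMG synthesis.

The muscle is a cylinder of parallel fibers under a skin/fat layer.  Each motor
unit owns an exponentially sized share of the fiber population, scattered
uniformly in a circular territory whose area keeps fiber density constant.
A fiber discharge launches two current tripoles at the innervation zone that
propagate toward the two tendons at the fiber's conduction velocity and are
extinguished there; the monopolar surface potential is the sum of the pole
contributions in a homogeneous volume conductor (the fat layer enters as pure
source-electrode distance).  A motor unit action potential (MUAP) is the sum
of its fibers' action potentials, and the surface EMG is the superposition of
MUAP templates at the discharge times of all active units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MuscleGeometry",
    "Fiber",
    "MuscleModel",
    "allocate_innervation",
    "place_territories",
    "conduction_velocity",
    "fiber_action_potential",
    "muap_template",
    "build_muscle",
    "compose_emg",
]

# current tripole: lead/mid/trail charges sum to zero; the 90:10 split between
# lead and trail sets the relative size of the terminal phase
TRIPOLE_CHARGES = (0.9, -1.0, 0.1)
TRIPOLE_OFFSETS_MM = (0.0, 2.0, 6.0)   # distance of each pole behind the lead
EXTINCTION_RAMP_MM = 2.0               # pole charge ramps to zero over this travel at the tendon

# conduction velocity-diameter map: v = CV_V0 + CV_SLOPE * (d - CV_D0)
CV_V0 = 2.2      # m/s
CV_SLOPE = 0.05  # m/s per um
CV_D0 = 25.0     # um


@dataclass(frozen=True)
class MuscleGeometry:
    """Cylindrical muscle, fiber population and electrode placement.

    Lengths in mm.  The fiber axis is z; the cross-section is the (x, y)
    plane with the muscle centred on the origin and the skin at
    ``y = muscle_radius_mm + skin_fat_mm``.  The default electrode sits on
    the skin over the muscle midline, midway between the innervation zone
    (z = 0) and one tendon.
    """

    muscle_radius_mm: float = 8.0
    skin_fat_mm: float = 2.5
    fiber_density_per_mm2: float = 20.0
    fiber_semilength_mm: float = 50.0
    iz_scatter_mm: float = 2.5
    diameter_mean_um: float = 55.0
    diameter_sd_um: float = 5.0
    fs: float = 4000.0
    electrode_xyz: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("muscle_radius_mm", "skin_fat_mm", "fiber_density_per_mm2",
                     "fiber_semilength_mm", "diameter_mean_um", "diameter_sd_um"):
            if getattr(self, name) < 0 or (name != "skin_fat_mm" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.iz_scatter_mm < 0:
            raise ValueError("iz_scatter_mm must be >= 0")
        if self.fs < 2000:
            raise ValueError("fs must be >= 2 kHz to resolve MUAP content")
        ex, ey, ez = self.electrode
        if math.hypot(ex, ey) < self.muscle_radius_mm:
            raise ValueError("electrode must lie outside the muscle tissue")

    @property
    def electrode(self) -> tuple[float, float, float]:
        if self.electrode_xyz is not None:
            return self.electrode_xyz
        return (0.0, self.muscle_radius_mm + self.skin_fat_mm, self.fiber_semilength_mm / 2.0)


@dataclass(frozen=True)
class Fiber:
    """One muscle fiber: owner, cross-section position, diameter, velocity, axial extent."""

    unit_index: int
    x: float
    y: float
    diameter_um: float
    velocity_m_s: float
    z_iz: float
    z_left: float
    z_right: float

    def __post_init__(self) -> None:
        if self.velocity_m_s <= 0:
            raise ValueError("conduction velocity must be positive")
        if not self.z_left < self.z_iz < self.z_right:
            raise ValueError("innervation zone must lie strictly between fiber ends")


def allocate_innervation(n_units: int, total_fibers: int, fold_range: float) -> np.ndarray:
    """Distribute ``total_fibers`` over ``n_units`` with an exponential size range.

    Counts are proportional to ``exp(ln(fold_range)/n * i)`` — the same
    ``fold_range``-fold spread as the twitch forces — scaled to the exact
    total and rounded by largest remainder so the integer counts sum to
    ``total_fibers``.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if total_fibers < n_units:
        raise ValueError(f"cannot give {n_units} units at least one fiber from {total_fibers}")
    if fold_range <= 0:
        raise ValueError("fold_range must be > 0")
    i = np.arange(1, n_units + 1)
    w = np.exp(np.log(fold_range) / n_units * i)
    target = total_fibers * w / w.sum()
    counts = np.floor(target).astype(int)
    short = total_fibers - counts.sum()
    order = np.argsort(-(target - counts), kind="stable")
    counts[order[:short]] += 1
    if counts.min() < 1:
        raise ValueError("fold range too steep: some units receive no fibers")
    return counts


def conduction_velocity(diameter_um) -> float | np.ndarray:
    """Fiber conduction velocity (m/s), linear in fiber diameter."""
    d = np.asarray(diameter_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("fiber diameter must be positive")
    v = CV_V0 + CV_SLOPE * (d - CV_D0)
    return v if v.ndim else float(v)


def place_territories(
    counts: np.ndarray,
    geometry: MuscleGeometry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Place unit territories and fibers inside the muscle cross-section.

    Territory radius keeps fiber density at ``fiber_density_per_mm2``; centers
    are uniform over the disc of positions at which the whole territory fits
    inside the muscle.  Returns (centers (n,2), radii (n,), per-unit fiber
    position arrays (count_i, 2)).
    """
    counts = np.asarray(counts)
    R = geometry.muscle_radius_mm
    radii = np.sqrt(counts / (geometry.fiber_density_per_mm2 * math.pi))
    if np.any(radii > R):
        warnings.warn("territory larger than muscle cross-section; radius clipped")
        radii = np.minimum(radii, R)
    centers = np.empty((counts.size, 2))
    fibers = []
    for k, (cnt, r) in enumerate(zip(counts, radii)):
        c_max = max(R - r, 0.0)
        rho = c_max * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        centers[k] = (rho * math.cos(th), rho * math.sin(th))
        frho = r * np.sqrt(rng.uniform(size=cnt))
        fth = rng.uniform(0, 2 * math.pi, size=cnt)
        pos = centers[k] + np.column_stack([frho * np.cos(fth), frho * np.sin(fth)])
        fibers.append(pos)
    return centers, radii, fibers


def _tripole_waveforms(
    xy: np.ndarray,
    velocity: np.ndarray,
    z_iz: np.ndarray,
    z_left: np.ndarray,
    z_right: np.ndarray,
    electrode: tuple[float, float, float],
    fs: float,
    n_samples: int,
) -> np.ndarray:
    """Vectorised monopolar potentials for a batch of fibers.

    Returns an array (n_fibers, n_samples).  Velocities in m/s equal mm/ms, so
    positions stay in mm with time in ms.
    """
    ex, ey, ez = electrode
    t_ms = np.arange(n_samples) / fs * 1e3
    v = np.asarray(velocity, dtype=float)[:, None]          # (F, 1)
    radial2 = (xy[:, 0] - ex) ** 2 + (xy[:, 1] - ey) ** 2   # (F,)
    if np.any(radial2 <= 0):
        raise ValueError("electrode lies on a fiber axis (inside the source region)")
    out = np.zeros((xy.shape[0], n_samples))
    travel = v * t_ms[None, :]                              # (F, L)
    for direction in (+1.0, -1.0):
        z_lead = z_iz[:, None] + direction * travel
        end = z_right[:, None] if direction > 0 else z_left[:, None]
        # all three pole charges ramp together as the lead pole nears the
        # tendon: net source charge stays zero throughout extinction
        w = np.clip(direction * (end - z_lead) / EXTINCTION_RAMP_MM, 0.0, 1.0)
        for charge, off in zip(TRIPOLE_CHARGES, TRIPOLE_OFFSETS_MM):
            z = z_lead - direction * off
            dist = np.sqrt(radial2[:, None] + (z - ez) ** 2)
            out += charge * w / (4.0 * math.pi * dist)
    return out


def _waveform_samples(velocity, z_iz, z_left, z_right, fs) -> int:
    """Samples until the slowest pole of either tripole is extinguished."""
    span = np.maximum(
        np.asarray(z_right) - np.asarray(z_iz),
        np.asarray(z_iz) - np.asarray(z_left),
    ) + TRIPOLE_OFFSETS_MM[-1]
    dur_ms = np.max(span / np.asarray(velocity))
    return int(math.ceil(dur_ms * 1e-3 * fs)) + 1


def fiber_action_potential(
    fiber: Fiber,
    electrode: tuple[float, float, float],
    fs: float,
    n_samples: int | None = None,
) -> np.ndarray:
    """Surface potential waveform of a single fiber discharge at t = 0."""
    if fs < 2000:
        raise ValueError("fs must be >= 2 kHz")
    if n_samples is None:
        n_samples = _waveform_samples(
            fiber.velocity_m_s, fiber.z_iz, fiber.z_left, fiber.z_right, fs
        )
    return _tripole_waveforms(
        np.array([[fiber.x, fiber.y]]),
        np.array([fiber.velocity_m_s]),
        np.array([fiber.z_iz]),
        np.array([fiber.z_left]),
        np.array([fiber.z_right]),
        electrode,
        fs,
        n_samples,
    )[0]


def muap_template(
    fibers: list[Fiber],
    electrode: tuple[float, float, float],
    fs: float,
    n_samples: int | None = None,
) -> np.ndarray:
    """MUAP template of one unit: sum of its fibers' action potentials."""
    if not fibers:
        raise ValueError("unit must have at least one fiber")
    xy = np.array([[f.x, f.y] for f in fibers])
    v = np.array([f.velocity_m_s for f in fibers])
    z_iz = np.array([f.z_iz for f in fibers])
    z_l = np.array([f.z_left for f in fibers])
    z_r = np.array([f.z_right for f in fibers])
    if n_samples is None:
        n_samples = _waveform_samples(v, z_iz, z_l, z_r, fs)
    return _tripole_waveforms(xy, v, z_iz, z_l, z_r, electrode, fs, n_samples).sum(axis=0)


@dataclass
class MuscleModel:
    """Realised fiber population and per-unit MUAP templates for one pool."""

    geometry: MuscleGeometry
    counts: np.ndarray
    territory_centers: np.ndarray
    territory_radii: np.ndarray
    templates: list[np.ndarray] = field(repr=False)

    @property
    def fs(self) -> float:
        return self.geometry.fs


def build_muscle(
    counts: np.ndarray,
    geometry: MuscleGeometry,
    rng: np.random.Generator,
) -> MuscleModel:
    """Sample the fiber population and precompute every unit's MUAP template.

    ``counts`` is the per-unit innervation number of the *intact* pool (unit
    loss only deselects templates downstream).  Fiber diameters are Gaussian
    (one shared mean for all units, truncated at 3 SD) and conduction velocity
    follows the diameter map.
    """
    counts = np.asarray(counts)
    centers, radii, positions = place_territories(counts, geometry, rng)
    L = 0
    per_unit = []
    for pos in positions:
        cnt = pos.shape[0]
        lo = geometry.diameter_mean_um - 3 * geometry.diameter_sd_um
        hi = geometry.diameter_mean_um + 3 * geometry.diameter_sd_um
        d = rng.normal(geometry.diameter_mean_um, geometry.diameter_sd_um, size=cnt)
        while np.any((d < lo) | (d > hi)):
            bad = (d < lo) | (d > hi)
            d[bad] = rng.normal(geometry.diameter_mean_um, geometry.diameter_sd_um, size=bad.sum())
        v = conduction_velocity(d)
        z_iz = rng.uniform(-geometry.iz_scatter_mm, geometry.iz_scatter_mm, size=cnt)
        z_l = np.full(cnt, -geometry.fiber_semilength_mm)
        z_r = np.full(cnt, geometry.fiber_semilength_mm)
        per_unit.append((pos, v, z_iz, z_l, z_r))
        L = max(L, _waveform_samples(v, z_iz, z_l, z_r, geometry.fs))
    templates = [
        _tripole_waveforms(pos, v, z_iz, z_l, z_r, geometry.electrode, geometry.fs, L).sum(axis=0)
        for pos, v, z_iz, z_l, z_r in per_unit
    ]
    return MuscleModel(geometry, counts, centers, radii, templates)


def compose_emg(
    spike_trains: list[np.ndarray],
    templates: list[np.ndarray],
    fs: float,
    t_end: float,
) -> np.ndarray:
    """Surface EMG: superpose each unit's MUAP template at its discharge times.

    Discharges are aligned to the nearest EMG sample; templates extending past
    ``t_end`` are truncated, and discharges beyond ``t_end`` are dropped with
    a warning.
    """
    if len(spike_trains) != len(templates):
        raise ValueError("one template per spike train required")
    n = int(round(t_end * fs)) + 1
    x = np.zeros(n)
    for train, tmpl in zip(spike_trains, templates):
        train = np.asarray(train)
        if train.size == 0:
            continue
        if np.any(train > t_end):
            warnings.warn("discharges beyond t_end clipped from EMG")
            train = train[train <= t_end]
        idx = np.round(train * fs).astype(int)
        L = tmpl.size
        for k in idx:
            hi = min(k + L, n)
            x[k:hi] += tmpl[: hi - k]
    return x
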