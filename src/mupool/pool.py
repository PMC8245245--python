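"""Motor neuron pool: recruitment thresholds, rate coding, and stochastic discharge.

The pool follows the classic exponential size-principle organisation: recruitment
thresholds, twitch forces and innervation numbers all grow exponentially with the
unit index, so most units are small, low-threshold ones and a few are large,
high-threshold ones.  Firing rate rises linearly with excitatory drive above the
recruitment threshold until the unit's peak firing rate (PFR) is reached.  Two
PFR assignments are supported:

* ``onion_skin`` — earlier-recruited (small) units sustain the higher peak
  rates; PFR decreases linearly with recruitment threshold.
* ``reverse_onion_skin`` — the mirrored assignment: the largest units reach
  the highest peak rates.

Discharge trains are renewal processes with Gaussian interspike intervals
(mean 1/rate, SD = isi_cv * mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .force import contraction_time, peak_twitch
from .emg import allocate_innervation

__all__ = [
    "PoolConfig",
    "MotorUnit",
    "recruitment_threshold",
    "recruitment_thresholds",
    "peak_firing_rate",
    "firing_rate",
    "sample_spike_train",
    "build_pool",
]

PFR_SCHEMES = ("onion_skin", "reverse_onion_skin")


@dataclass(frozen=True)
class PoolConfig:
    """Scalar parameters defining a motor neuron pool and its firing strategy.

    Attributes
    ----------
    n_units : number of motor units in the intact pool.
    rr : recruitment range — threshold of the last unit, in % of maximum
        excitation (the first unit's threshold is ``rr**(1/n_units)``).
    mfr : minimum firing rate at recruitment, Hz.
    gain : firing-rate gain, Hz per % excitation above threshold; identical
        for all units.
    pfr_scheme : ``onion_skin`` or ``reverse_onion_skin``.
    pfr_lo, pfr_hi : endpoints of the linear PFR assignment, Hz.
    isi_cv : coefficient of variation of the Gaussian interspike interval.
    rp : fold range of peak twitch force across the pool.
    rt : fold range of twitch contraction time across the pool.
    t_l : longest contraction time (smallest unit), ms.
    total_fibers : muscle fibers distributed over the pool (100-fold
        exponential range, same shape as twitch force).
    dt_force : force-trace sampling interval, ms.
    """

    n_units: int = 120
    rr: float = 40.0
    mfr: float = 8.0
    gain: float = 1.0
    pfr_scheme: str = "onion_skin"
    pfr_lo: float = 25.0
    pfr_hi: float = 35.0
    isi_cv: float = 0.20
    rp: float = 100.0
    rt: float = 3.0
    t_l: float = 90.0
    total_fibers: int = 70_000
    dt_force: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError(f"n_units must be >= 1, got {self.n_units}")
        if not 0 < self.rr <= 100:
            raise ValueError(f"rr must be in (0, 100], got {self.rr}")
        if self.mfr <= 0:
            raise ValueError(f"mfr must be > 0, got {self.mfr}")
        if self.pfr_scheme not in PFR_SCHEMES:
            raise ValueError(f"pfr_scheme must be one of {PFR_SCHEMES}, got {self.pfr_scheme!r}")
        if not self.pfr_hi >= self.pfr_lo:
            raise ValueError("pfr_hi must be >= pfr_lo")
        if self.pfr_lo <= self.mfr:
            raise ValueError("pfr_lo must exceed mfr (units must be able to raise their rate)")
        if self.isi_cv < 0:
            raise ValueError("isi_cv must be >= 0")
        if self.rp <= 1 or self.rt <= 1:
            raise ValueError("rp and rt must be > 1")
        if self.t_l <= 0:
            raise ValueError("t_l must be > 0")
        if self.total_fibers < self.n_units:
            raise ValueError("total_fibers must be >= n_units")
        if self.dt_force <= 0:
            raise ValueError("dt_force must be > 0")

    def with_scheme(self, scheme: str) -> "PoolConfig":
        return replace(self, pfr_scheme=scheme)


@dataclass(frozen=True)
class MotorUnit:
    """Derived properties of one motor unit (1-based index ``i``)."""

    index: int
    rte: float          # recruitment threshold, % max excitation
    pfr: float          # peak firing rate, Hz
    peak_twitch: float  # P, arbitrary units
    contraction_time_ms: float  # T, ms
    n_fibers: int


def recruitment_threshold(i: int, rr: float, n: int) -> float:
    """Recruitment threshold of unit ``i`` (% max excitation).

    ``RTE_i = exp(ln(rr)/n * i)``: thresholds rise exponentially so most of
    the pool is recruited at low drive; the last unit's threshold equals
    ``rr`` exactly.
    """
    if rr <= 0:
        raise ValueError(f"rr must be > 0, got {rr}")
    if not 1 <= i <= n:
        raise IndexError(f"unit index {i} outside 1..{n}")
    return math.exp(math.log(rr) / n * i)


def recruitment_thresholds(rr: float, n: int) -> np.ndarray:
    """Vector of all ``n`` recruitment thresholds."""
    if rr <= 0:
        raise ValueError(f"rr must be > 0, got {rr}")
    return np.exp(np.log(rr) / n * np.arange(1, n + 1))


def peak_firing_rate(
    rte: float,
    scheme: str,
    pfr_lo: float,
    pfr_hi: float,
    rr: float,
) -> float:
    """Peak firing rate assigned to a unit from its recruitment threshold.

    Linear in ``rte/rr``: under ``onion_skin`` the PFR falls from ``pfr_hi``
    (threshold -> 0) to ``pfr_lo`` (threshold = rr); ``reverse_onion_skin``
    is the mirror image.
    """
    if scheme not in PFR_SCHEMES:
        raise ValueError(f"unknown pfr scheme {scheme!r}")
    frac = rte / rr
    if scheme == "onion_skin":
        return pfr_hi - (pfr_hi - pfr_lo) * frac
    return pfr_lo + (pfr_hi - pfr_lo) * frac


def firing_rate(excitation: float, unit: MotorUnit, cfg: PoolConfig) -> float:
    """Instantaneous firing rate (Hz) of ``unit`` at drive ``excitation`` (%).

    Zero below the recruitment threshold; above it the rate rises linearly
    from ``mfr`` with slope ``gain`` and is clamped at the unit's PFR.
    """
    if excitation < unit.rte:
        return 0.0
    return min(cfg.gain * (excitation - unit.rte) + cfg.mfr, unit.pfr)


def sample_spike_train(
    rate: Callable[[float], float],
    isi_cv: float,
    t_end: float,
    rng: np.random.Generator,
    t_start: float = 0.0,
) -> np.ndarray:
    """Sample one discharge train from a time-varying rate profile.

    The first discharge occurs at ``t_start`` (the instant the unit becomes
    recruited).  Each subsequent interspike interval is drawn from a Gaussian
    with mean ``1/rate(t_prev)`` and SD ``isi_cv`` times that mean — a renewal
    approximation in which the rate is frozen at the previous discharge.
    Negative draws are resampled (vanishingly rare at CV 0.2).

    Returns an array of discharge times in ``[t_start, t_end]``; empty if the
    rate at ``t_start`` is not positive.
    """
    if isi_cv < 0:
        raise ValueError("isi_cv must be >= 0")
    times: list[float] = []
    t = float(t_start)
    while t <= t_end:
        fr = rate(t)
        if fr <= 0:
            break
        times.append(t)
        mean_isi = 1.0 / fr
        if isi_cv == 0:
            isi = mean_isi
        else:
            isi = rng.normal(mean_isi, isi_cv * mean_isi)
            while isi <= 0:
                isi = rng.normal(mean_isi, isi_cv * mean_isi)
        t += isi
    return np.asarray(times, dtype=float)


def build_pool(cfg: PoolConfig) -> list[MotorUnit]:
    """Construct the full pool of motor units from a configuration.

    Per-unit recruitment threshold, peak firing rate, twitch parameters and
    innervation number are all deterministic functions of the unit index;
    randomness enters only at discharge sampling and fiber placement.
    """
    n = cfg.n_units
    rtes = recruitment_thresholds(cfg.rr, n)
    counts = allocate_innervation(n, cfg.total_fibers, cfg.rp)
    units = []
    for i in range(1, n + 1):
        p = peak_twitch(i, cfg.rp, n)
        units.append(
            MotorUnit(
                index=i,
                rte=float(rtes[i - 1]),
                pfr=peak_firing_rate(float(rtes[i - 1]), cfg.pfr_scheme, cfg.pfr_lo, cfg.pfr_hi, cfg.rr),
                peak_twitch=p,
                contraction_time_ms=contraction_time(p, cfg.t_l, cfg.rt, cfg.rp),
                n_fibers=int(counts[i - 1]),
            )
        )
    _validate_pool(units, cfg)
    return units


def _validate_pool(units: Sequence[MotorUnit], cfg: PoolConfig) -> None:
    for u in units:
        if u.pfr <= cfg.mfr:
            raise ValueError(f"unit {u.index}: pfr {u.pfr} must exceed mfr {cfg.mfr}")
    if len(units) > 1:
        rte = np.array([u.rte for u in units])
        p = np.array([u.peak_twitch for u in units])
        t = np.array([u.contraction_time_ms for u in units])
        nf = np.array([u.n_fibers for u in units])
        if not (np.all(np.diff(rte) > 0) and np.all(np.diff(p) > 0)):
            raise ValueError("recruitment thresholds and twitch forces must increase with index")
        if not np.all(np.diff(t) < 0):
            raise ValueError("contraction times must decrease with index")
        if not np.all(np.diff(nf) >= 0):
            raise ValueError("fiber counts must be nondecreasing with index")
    total = sum(u.n_fibers for u in units)
    if total != cfg.total_fibers:
        raise ValueError(f"fiber counts sum to {total}, expected {cfg.total_fibers}")
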