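"""Twitch force generation and summation.

Each discharge of a motor unit produces a second-order critically damped
twitch ``f(t) = g * P * (t/T) * exp(1 - t/T)`` with peak force ``P`` reached at
the contraction time ``T``.  When discharges arrive faster than the twitch can
decay the twitches fuse; the per-discharge gain ``g`` captures the resulting
nonlinear force summation as a function of ``T/ISI`` (contraction time over
the interspike interval preceding the discharge): unity in the unfused regime
(``T/ISI <= 0.4``), rising to a maximum near ``T/ISI = 1`` and falling again
as the unit saturates.  Whole-muscle force is the linear sum of unit forces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwitchParams",
    "peak_twitch",
    "contraction_time",
    "twitch_response",
    "fusion_gain",
    "discharge_gains",
    "unit_force",
    "total_force",
]

_FUSION_KNEE = 0.4
# support of one twitch, in units of T: (u)exp(1-u) < 4e-16 beyond u = 45
_TWITCH_SUPPORT = 45.0


@dataclass(frozen=True)
class TwitchParams:
    """Peak twitch force ``P`` (au) and contraction time ``T``.

    ``T`` must be expressed in the same time units as the spike times and
    sampling grid it is used with (seconds throughout the trial pipeline).
    """

    P: float
    T: float

    def __post_init__(self) -> None:
        if self.P <= 0 or self.T <= 0:
            raise ValueError("P and T must be positive")


def peak_twitch(i: int, rp: float, n: int) -> float:
    """Peak twitch force of unit ``i``: ``P_i = exp(ln(rp)/n * i)`` (au).

    Exponential across the pool so that unit ``n`` is ``rp``-fold stronger
    than ``exp(ln(rp)/n)`` (the smallest unit); with ``rp = 100`` half the
    pool produces less than 10% of the largest unit's twitch.
    """
    if rp <= 0:
        raise ValueError(f"rp must be > 0, got {rp}")
    if not 1 <= i <= n:
        raise IndexError(f"unit index {i} outside 1..{n}")
    return math.exp(math.log(rp) / n * i)


def contraction_time(p: float, t_l: float, rt: float, rp: float) -> float:
    """Contraction time paired with peak twitch ``p``: ``T = t_l * (1/p)**(ln rt / ln rp)``.

    Inverse power law in ``p`` so contraction time spans an ``rt``-fold range
    (longest ``t_l`` for the weakest unit, ``t_l/rt`` for ``p = rp``).
    Units follow ``t_l`` (ms by convention).
    """
    if p <= 0:
        raise ValueError(f"peak twitch must be > 0, got {p}")
    if t_l <= 0 or rt <= 1 or rp <= 1:
        raise ValueError("require t_l > 0, rt > 1, rp > 1")
    return t_l * (1.0 / p) ** (math.log(rt) / math.log(rp))


def twitch_response(t, g: float, p: float, T: float):
    """Single twitch ``g*p*(t/T)*exp(1 - t/T)`` at time ``t`` after discharge.

    Zero at ``t = 0``, peak ``g*p`` at ``t = T``.  Accepts scalar or array ``t``
    (negative times return 0).
    """
    t = np.asarray(t, dtype=float)
    u = np.clip(t, 0.0, None) / T
    out = g * p * u * np.exp(1.0 - u)
    return out if out.ndim else float(out)


def _s(x):
    return (1.0 - np.exp(-2.0 * x**3)) / x


def fusion_gain(T: float, isi: float) -> float:
    """Nonlinear force gain for a discharge preceded by interval ``isi``.

    ``T`` and ``isi`` must share units.  With ``x = T/isi``: gain is 1 for
    ``x <= 0.4`` (twitches far enough apart to sum linearly) and
    ``S(x)/S(0.4)`` with ``S(x) = (1 - exp(-2 x^3))/x`` beyond — continuous at
    the knee, maximal near ``x = 1`` where the interval matches the
    contraction time, then declining as the tetanus saturates.
    """
    if T <= 0 or isi <= 0:
        raise ValueError("T and isi must be positive")
    x = T / isi
    if x <= _FUSION_KNEE:
        return 1.0
    return float(_s(x) / _s(_FUSION_KNEE))


def discharge_gains(spike_times: np.ndarray, T: float) -> np.ndarray:
    """Gain for every discharge of a train (first discharge: 1, a lone twitch)."""
    spike_times = np.asarray(spike_times, dtype=float)
    gains = np.ones_like(spike_times)
    if spike_times.size > 1:
        isi = np.diff(spike_times)
        if np.any(isi <= 0):
            raise ValueError("spike times must be strictly increasing")
        x = T / isi
        hot = x > _FUSION_KNEE
        gains[1:][hot] = _s(x[hot]) / _s(_FUSION_KNEE)
    return gains


def unit_force(
    spike_times: np.ndarray,
    twitch: TwitchParams,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Force trace of one motor unit: superposed gain-scaled twitches.

    Each discharge contributes ``g_j * P * (u) exp(1-u)`` with
    ``u = (t - t_j)/T``; ``g_j`` is the fusion gain of the interval preceding
    discharge ``j`` (1 for the first).  ``t_grid`` must be uniformly spaced and
    start at 0; spike times are kept continuous (no binning).

    The superposition is evaluated with a per-unit geometric recurrence
    (``exp(-(k dt - t_j)/T)`` factorises over the grid), which is algebraically
    identical to the term-by-term sum.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.zeros_like(t_grid)
    if spike_times.size == 0:
        return out
    dt = t_grid[1] - t_grid[0]
    if not np.allclose(np.diff(t_grid), dt):
        raise ValueError("t_grid must be uniformly spaced")
    if abs(t_grid[0]) > 1e-12:
        raise ValueError("t_grid must start at 0")

    P, T = twitch.P, twitch.T
    gains = discharge_gains(spike_times, T)
    n = t_grid.size
    w = min(n, int(math.ceil(_TWITCH_SUPPORT * T / dt)) + 1)
    j = np.arange(w, dtype=float)
    decay = np.exp(-dt / T) ** j          # r^j
    ramp = j * (dt / T) * decay           # j*(dt/T)*r^j

    for t0, g in zip(spike_times, gains):
        m = int(math.floor(t0 / dt + 1e-12))
        phi = t0 / dt - m                 # fractional grid offset in [0, 1)
        k0 = m + 1 if phi > 1e-12 else m  # first sample at/after the spike
        if k0 >= n:
            continue
        off = k0 - m                      # grid steps from m to first sample
        span = min(w - off, n - k0)
        if span <= 0:
            continue
        # sample k = m + j' carries u = (j' - phi)*dt/T, so
        # f_k = g*P*e * exp(phi*dt/T) * [j'*(dt/T) - phi*(dt/T)] * r^j'
        c = g * P * math.e * math.exp(phi * dt / T)
        seg = slice(off, off + span)
        out[k0:k0 + span] += c * (ramp[seg] - phi * (dt / T) * decay[seg])
    return out


def total_force(unit_traces: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Whole-muscle force: elementwise (linear) sum of per-unit traces."""
    traces = [np.asarray(tr, dtype=float) for tr in unit_traces]
    if not traces:
        raise ValueError("no unit traces to sum")
    n = traces[0].size
    if any(tr.size != n for tr in traces):
        raise ValueError("unit traces must share one sampling grid")
    return np.sum(traces, axis=0)
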