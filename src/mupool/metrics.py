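"""Outcome measures: steady-state windows, force variability, EMG amplitude, EMG-force relation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "steady_window",
    "force_cov",
    "emg_arv",
    "EMGForceCurve",
    "emg_force_curve",
    "percent_change",
]


def steady_window(t: np.ndarray, y: np.ndarray, t_start: float = 2.0) -> np.ndarray:
    """Samples of ``y`` at ``t >= t_start`` (the ramp transient is discarded)."""
    t = np.asarray(t)
    y = np.asarray(y)
    if t.shape != y.shape:
        raise ValueError("t and y must have the same shape")
    if t[-1] < t_start:
        raise ValueError(f"trace ends at {t[-1]} s, before the steady window at {t_start} s")
    return y[t >= t_start]


def force_cov(force: np.ndarray) -> float:
    """Coefficient of variation of a force window, % (population SD / mean)."""
    force = np.asarray(force, dtype=float)
    if force.size == 0:
        raise ValueError("empty force window")
    m = force.mean()
    if m <= 0:
        raise ValueError("force COV undefined for a nonpositive-mean window")
    return float(100.0 * force.std() / m)


def emg_arv(emg: np.ndarray) -> float:
    """Averaged rectified value of an EMG window (mean absolute amplitude)."""
    emg = np.asarray(emg, dtype=float)
    if emg.size == 0:
        raise ValueError("empty EMG window")
    return float(np.mean(np.abs(emg)))


@dataclass(frozen=True)
class EMGForceCurve:
    """Normalized EMG-force relation across excitation levels with its linear fit.

    Force and EMG amplitude are each normalized to their own maximum within
    the condition, so both coordinates end in (0, 1].  ``residuals`` are the
    EMG deviations from the ordinary least-squares line (positive = EMG above
    the line).
    """

    levels: np.ndarray
    force_norm: np.ndarray
    emg_norm: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray


def emg_force_curve(levels, force_means, emg_arvs) -> EMGForceCurve:
    """Normalize force and EMG to their condition maxima and fit a line.

    A linear relation (high R-squared) indicates that EMG amplitude and force
    grow in proportion across the excitation range; EMG systematically above
    the fitted line at mid levels signals the nonlinear regime in which EMG
    rises faster than force.
    """
    levels = np.asarray(levels, dtype=float)
    f = np.asarray(force_means, dtype=float)
    e = np.asarray(emg_arvs, dtype=float)
    if not (levels.size == f.size == e.size) or levels.size < 3:
        raise ValueError("need matching force/EMG values for at least 3 levels")
    if np.max(f) <= 0 or np.max(e) <= 0:
        raise ValueError("maxima must be positive for normalization")
    fn = f / f.max()
    en = e / e.max()
    fit = stats.linregress(fn, en)
    resid = en - (fit.slope * fn + fit.intercept)
    return EMGForceCurve(
        levels=levels,
        force_norm=fn,
        emg_norm=en,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residuals=resid,
    )


def percent_change(reference: float, comparison: float) -> float:
    """Signed percent change from ``reference`` to ``comparison`` (negative = reduction)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (comparison - reference) / reference
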