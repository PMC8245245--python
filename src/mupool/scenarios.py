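"""Experiment scenarios: motor unit loss patterns, excitation protocol, trials and grids.

A trial drives one (possibly depleted) pool with a trapezoidal excitation
profile — a 2 s linear ramp to the target level followed by a 5 s hold — and
measures steady-state force (mean and coefficient of variation) and, when EMG
synthesis is enabled, the averaged rectified EMG value.  The full experiment is
a factorial grid: firing strategy x loss scenario x excitation level x
repetition, each cell with an independently derived random substream.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pool import PoolConfig, MotorUnit, build_pool, firing_rate, sample_spike_train
from .force import TwitchParams, discharge_gains, unit_force, total_force
from .emg import MuscleGeometry, MuscleModel, build_muscle, compose_emg
from . import metrics

__all__ = [
    "LossScenario",
    "ExcitationProfile",
    "TrialResult",
    "LOSS_PATTERNS",
    "DEFAULT_LEVELS",
    "apply_loss",
    "excitation",
    "trial_seed",
    "run_trial",
    "run_grid",
    "condition_means",
]

LOSS_PATTERNS = ("none", "largest", "smallest", "unrestricted")
DEFAULT_LEVELS = tuple(range(10, 101, 10))
DEFAULT_FRACTIONS = (0.2, 0.4, 0.6)


@dataclass(frozen=True)
class LossScenario:
    """A motor unit loss pattern and its severity.

    ``largest`` removes the highest-threshold (largest-twitch) units,
    ``smallest`` the lowest-threshold units, and ``unrestricted`` a uniformly
    random subset; ``none`` keeps the intact pool.  Surviving units keep their
    original properties (no reinnervation).
    """

    pattern: str = "none"
    fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern not in LOSS_PATTERNS:
            raise ValueError(f"pattern must be one of {LOSS_PATTERNS}, got {self.pattern!r}")
        if not 0 <= self.fraction < 1:
            raise ValueError(f"fraction must be in [0, 1), got {self.fraction}")
        if self.pattern == "none" and self.fraction != 0:
            raise ValueError("pattern 'none' requires fraction 0")


@dataclass(frozen=True)
class ExcitationProfile:
    """Trapezoidal excitatory drive: linear ramp then constant hold."""

    level: float
    ramp_s: float = 2.0
    hold_s: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.level <= 100:
            raise ValueError(f"level must be in (0, 100], got {self.level}")
        if self.ramp_s < 0 or self.hold_s <= 0:
            raise ValueError("ramp_s must be >= 0 and hold_s > 0")

    @property
    def t_end(self) -> float:
        return self.ramp_s + self.hold_s

    def __call__(self, t: float) -> float:
        return excitation(self.level, t, self.ramp_s, self.hold_s)

    def recruit_time(self, rte: float) -> float | None:
        """First instant the drive reaches ``rte``; None if never recruited."""
        if rte > self.level:
            return None
        if self.ramp_s == 0:
            return 0.0
        return self.ramp_s * rte / self.level


def excitation(level: float, t, ramp_s: float = 2.0, hold_s: float = 5.0):
    """Excitatory drive (% max excitation) at time ``t`` of the trapezoid."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > ramp_s + hold_s):
        raise ValueError(f"t outside the trial window [0, {ramp_s + hold_s}]")
    if ramp_s == 0:
        out = np.full_like(t_arr, float(level))
    else:
        out = np.where(t_arr < ramp_s, level * t_arr / ramp_s, float(level))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TrialResult:
    """Steady-state outcome of one simulated contraction."""

    strategy: str
    pattern: str
    fraction: float
    level: float
    rep: int
    seed: int
    n_active_units: int
    force_mean: float
    force_cov_pct: float
    emg_arv: float | None = None


def apply_loss(
    units: Sequence[MotorUnit],
    scenario: LossScenario,
    rng: np.random.Generator | None = None,
) -> list[MotorUnit]:
    """Return the surviving units under a loss scenario.

    The number removed is ``round(fraction * n)``.  ``unrestricted`` draws the
    removed subset uniformly with ``rng`` (required for that pattern).
    """
    n = len(units)
    k = int(round(scenario.fraction * n))
    if scenario.pattern == "none" or k == 0:
        return list(units)
    if k >= n:
        raise ValueError("loss would remove the entire pool")
    if scenario.pattern == "largest":
        return list(units[: n - k])
    if scenario.pattern == "smallest":
        return list(units[k:])
    if rng is None:
        raise ValueError("unrestricted loss requires an rng")
    removed = set(rng.choice(n, size=k, replace=False).tolist())
    return [u for j, u in enumerate(units) if j not in removed]


def trial_seed(
    master_seed: int,
    strategy: str,
    pattern: str,
    fraction: float,
    level: float,
    rep: int,
) -> int:
    """Deterministic per-trial seed derived from the condition coordinates."""
    key = (
        int(master_seed) & 0x7FFFFFFF,
        1 + ("onion_skin", "reverse_onion_skin").index(strategy),
        1 + LOSS_PATTERNS.index(pattern),
        int(round(fraction * 100)),
        int(round(level)),
        int(rep),
    )
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _simulate_spike_trains(
    units: Sequence[MotorUnit],
    cfg: PoolConfig,
    profile: ExcitationProfile,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    trains = []
    for u in units:
        t0 = profile.recruit_time(u.rte)
        if t0 is None:
            trains.append(np.empty(0))
            continue
        trains.append(
            sample_spike_train(
                lambda t, u=u: firing_rate(profile(t), u, cfg),
                cfg.isi_cv,
                profile.t_end,
                rng,
                t_start=t0,
            )
        )
    return trains


def synthesize_force(
    units: Sequence[MotorUnit],
    trains: Sequence[np.ndarray],
    cfg: PoolConfig,
    t_end: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Force trace (t_grid, force) for a set of units and their spike trains."""
    dt = cfg.dt_force * 1e-3
    t_grid = np.arange(0.0, t_end + dt / 2, dt)
    traces = [
        unit_force(tr, TwitchParams(u.peak_twitch, u.contraction_time_ms * 1e-3), t_grid)
        for u, tr in zip(units, trains)
    ]
    return t_grid, total_force(traces) if traces else np.zeros_like(t_grid)


def run_trial(
    cfg: PoolConfig,
    scenario: LossScenario,
    level: float,
    seed: int,
    with_emg: bool = False,
    muscle: MuscleModel | None = None,
    ramp_s: float = 2.0,
    hold_s: float = 5.0,
    return_traces: bool = False,
    pool: Sequence[MotorUnit] | None = None,
    rep: int = 0,
    loss_seed: int | None = None,
):
    """Simulate one contraction and return its steady-state ``TrialResult``.

    Fully reproducible from ``(cfg, scenario, level, seed)`` (plus
    ``loss_seed`` if given).  ``loss_seed`` draws the unrestricted-loss subset
    from its own stream, so one lesioned pool can be held fixed across
    excitation levels while discharge noise stays per-trial.  ``pool`` may be
    passed to reuse an already built intact pool; ``muscle`` (a prebuilt fiber
    model for the intact pool) is required when ``with_emg`` is set.  With
    ``return_traces`` the (t_grid, force, emg) arrays are returned alongside.
    """
    if with_emg and muscle is None:
        raise ValueError("with_emg requires a prebuilt MuscleModel")
    rng = np.random.default_rng(seed)
    units = list(pool) if pool is not None else build_pool(cfg)
    loss_rng = rng if loss_seed is None else np.random.default_rng(loss_seed)
    survivors = apply_loss(units, scenario, loss_rng)
    profile = ExcitationProfile(level, ramp_s, hold_s)
    trains = _simulate_spike_trains(survivors, cfg, profile, rng)

    t_grid, force = synthesize_force(survivors, trains, cfg, profile.t_end)
    steady_f = metrics.steady_window(t_grid, force, t_start=ramp_s)
    f_mean = float(np.mean(steady_f))
    f_cov = metrics.force_cov(steady_f)

    arv = None
    emg = None
    if with_emg:
        templates = [muscle.templates[u.index - 1] for u in survivors]
        emg = compose_emg(trains, templates, muscle.fs, profile.t_end)
        t_emg = np.arange(emg.size) / muscle.fs
        arv = metrics.emg_arv(metrics.steady_window(t_emg, emg, t_start=ramp_s))

    result = TrialResult(
        strategy=cfg.pfr_scheme,
        pattern=scenario.pattern,
        fraction=scenario.fraction,
        level=level,
        rep=rep,
        seed=seed,
        n_active_units=len(survivors),
        force_mean=f_mean,
        force_cov_pct=f_cov,
        emg_arv=arv,
    )
    if return_traces:
        return result, (t_grid, force, emg)
    return result


def run_grid(
    cfg: PoolConfig,
    master_seed: int,
    strategies: Iterable[str] = ("onion_skin", "reverse_onion_skin"),
    scenarios: Iterable[LossScenario] | None = None,
    levels: Iterable[float] = DEFAULT_LEVELS,
    n_reps: int = 10,
    with_emg: bool = False,
    geometry: MuscleGeometry | None = None,
) -> pd.DataFrame:
    """Run the factorial condition grid and return one tidy row per trial.

    Every cell derives its own seed from ``master_seed`` and the condition
    coordinates, so any subset of the grid reproduces the identical trials.
    For ``unrestricted`` loss a fresh random subset is drawn per repetition
    but held fixed across excitation levels within that repetition (one
    lesioned pool, measured over the whole protocol).  A failed cell is
    recorded with NaN metrics rather than aborting the grid.
    """
    if scenarios is None:
        scenarios = [LossScenario()] + [
            LossScenario(p, f) for p in ("largest", "smallest", "unrestricted")
            for f in DEFAULT_FRACTIONS
        ]
    rows = []
    for strategy in strategies:
        scfg = cfg.with_scheme(strategy)
        pool = build_pool(scfg)
        muscle = None
        if with_emg:
            geo = geometry if geometry is not None else MuscleGeometry()
            muscle_rng = np.random.default_rng(
                trial_seed(master_seed, strategy, "none", 0.0, 100.0, 10_000)
            )
            muscle = build_muscle(np.array([u.n_fibers for u in pool]), geo, muscle_rng)
        for scen in scenarios:
            for level in levels:
                for rep in range(n_reps):
                    seed = trial_seed(master_seed, strategy, scen.pattern, scen.fraction, level, rep)
                    # level-independent stream: the lesion is a property of
                    # the (repetition's) pool, not of the excitation level
                    loss_seed = trial_seed(master_seed, strategy, scen.pattern, scen.fraction, 0.0, rep)
                    try:
                        res = run_trial(
                            scfg, scen, level, seed,
                            with_emg=with_emg, muscle=muscle, pool=pool, rep=rep,
                            loss_seed=loss_seed,
                        )
                        rows.append(asdict(res))
                    except Exception as exc:  # pragma: no cover - per-cell fault isolation
                        rows.append({
                            "strategy": strategy, "pattern": scen.pattern,
                            "fraction": scen.fraction, "level": level, "rep": rep,
                            "seed": seed, "n_active_units": np.nan,
                            "force_mean": np.nan, "force_cov_pct": np.nan,
                            "emg_arv": np.nan,
                        })
    return pd.DataFrame(rows)


def condition_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Average the repetitions of every condition cell."""
    keys = ["strategy", "pattern", "fraction", "level"]
    cols = ["force_mean", "force_cov_pct"]
    if trials["emg_arv"].notna().any():
        cols.append("emg_arv")
    return trials.groupby(keys, as_index=False)[cols].mean()
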