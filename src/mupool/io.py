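"""Configuration files, run manifests and result export.

Configs are YAML (JSON is a subset) with three optional blocks — ``pool``,
``geometry`` and ``grid`` — whose keys mirror :class:`~mupool.PoolConfig`,
:class:`~mupool.MuscleGeometry` and the grid arguments of
:func:`~mupool.run_grid`.  Missing keys take the model defaults; unknown keys
are rejected.  A run manifest (JSON) echoes the resolved configuration and the
master seed so any grid cell can be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .pool import PoolConfig, build_pool
from .emg import MuscleGeometry
from .scenarios import DEFAULT_LEVELS, DEFAULT_FRACTIONS, LossScenario

__all__ = [
    "GridSpec",
    "RunManifest",
    "load_config",
    "save_config",
    "grid_scenarios",
    "make_fixture_pool",
    "write_results",
]


@dataclass(frozen=True)
class GridSpec:
    """Shape of the condition grid: strategies, loss patterns/fractions, levels, reps."""

    strategies: tuple[str, ...] = ("onion_skin", "reverse_onion_skin")
    patterns: tuple[str, ...] = ("largest", "smallest", "unrestricted")
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    levels: tuple[float, ...] = tuple(DEFAULT_LEVELS)
    n_reps: int = 10
    with_emg: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def _build(cls, block: dict[str, Any], name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name!r} block: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in block.items()
    }
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid {name!r} configuration: {exc}") from exc


def load_config(path: str | Path) -> tuple[PoolConfig, MuscleGeometry, GridSpec]:
    """Load and validate a config file; absent blocks resolve to full defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - {"pool", "geometry", "grid"}
    if unknown:
        raise ValueError(f"unknown top-level config blocks: {sorted(unknown)}")
    pool = _build(PoolConfig, raw.get("pool", {}) or {}, "pool")
    geometry = _build(MuscleGeometry, raw.get("geometry", {}) or {}, "geometry")
    grid = _build(GridSpec, raw.get("grid", {}) or {}, "grid")
    return pool, geometry, grid


def save_config(
    path: str | Path,
    pool: PoolConfig,
    geometry: MuscleGeometry | None = None,
    grid: GridSpec | None = None,
) -> None:
    """Write a config file that round-trips through :func:`load_config`."""
    doc: dict[str, Any] = {"pool": dataclasses.asdict(pool)}
    if geometry is not None:
        doc["geometry"] = dataclasses.asdict(geometry)
    if grid is not None:
        doc["grid"] = dataclasses.asdict(grid)
    Path(path).write_text(yaml.safe_dump(_jsonable(doc), sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def grid_scenarios(grid: GridSpec) -> list[LossScenario]:
    """The loss scenarios of a grid: the intact pool plus every pattern x fraction."""
    return [LossScenario()] + [
        LossScenario(p, f) for p in grid.patterns for f in grid.fractions
    ]


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a grid run."""

    pool: dict
    geometry: dict | None
    grid: dict
    master_seed: int
    package_version: str = field(default="")

    @classmethod
    def create(cls, pool: PoolConfig, grid: GridSpec, geometry: MuscleGeometry | None = None):
        from . import __version__

        return cls(
            pool=dataclasses.asdict(pool),
            geometry=dataclasses.asdict(geometry) if geometry is not None else None,
            grid=dataclasses.asdict(grid),
            master_seed=grid.master_seed,
            package_version=__version__,
        )


def make_fixture_pool(n_units: int = 12, total_fibers: int = 700, **overrides):
    """A scaled-down pool for fast tests: same generative rules at reduced n.

    Returns ``(cfg, units)``.  All exponential shape parameters (recruitment
    range, twitch range, contraction-time range) keep their defaults unless
    overridden, so closed-form endpoint identities hold at any size.
    """
    if n_units < 2:
        raise ValueError("fixture pool needs at least 2 units")
    cfg = PoolConfig(n_units=n_units, total_fibers=total_fibers, **overrides)
    return cfg, build_pool(cfg)


def write_results(
    trials: pd.DataFrame,
    means: pd.DataFrame,
    manifest: RunManifest,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write trial and condition-mean CSVs plus the manifest JSON.

    Deterministic formatting: rewriting the same inputs produces identical
    bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": outdir / "trials.csv",
        "means": outdir / "condition_means.csv",
        "manifest": outdir / "manifest.json",
    }
    trials.to_csv(paths["trials"], index=False, float_format="%.10g")
    means.to_csv(paths["means"], index=False, float_format="%.10g")
    paths["manifest"].write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True) + "\n"
    )
    return paths
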