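"""Configuration files, trajectory serialization and run manifests.

Configs are YAML or JSON mappings that mirror :class:`ScenarioConfig`
field-for-field.  Parsing is fail-closed: unknown keys, type mismatches and
invariant violations abort with an error naming the offending field before
any simulation starts.

Trajectories are written as plain CSV (step, pop_size, environment, one
repertoire column per guild, total) with the event log in a sidecar CSV.
Every run is paired with a JSON manifest — fully resolved config, seed and
software version — sufficient to reproduce its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import N_CLASSES, VariantConfig
from .params import ModelParams
from .scenario import (
    BottleneckEvent,
    CollapseConfig,
    DemographyConfig,
    EnvironmentConfig,
    Event,
    ScenarioConfig,
    Trajectory,
)

__all__ = [
    "ConfigError",
    "config_from_dict",
    "config_to_dict",
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "RunManifest",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def _build(cls, d: dict, where: str, casts: dict[str, Any] | None = None):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(d, fields, where)
    kwargs = dict(d)
    if casts:
        for key, cast in casts.items():
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = cast(kwargs[key])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where}: {exc}") from exc


def config_from_dict(d: dict) -> ScenarioConfig:
    """Build a validated ScenarioConfig from a plain mapping (fail-closed)."""
    if not isinstance(d, dict):
        raise ConfigError("config must be a mapping")
    top = {f.name for f in dataclasses.fields(ScenarioConfig)}
    _check_keys(d, top, "config")
    kwargs: dict[str, Any] = {k: v for k, v in d.items()}
    if "params" in kwargs and kwargs["params"] is not None:
        kwargs["params"] = _build(ModelParams, kwargs["params"], "params")
    if "variant" in kwargs and kwargs["variant"] is not None:
        kwargs["variant"] = _build(VariantConfig, kwargs["variant"], "variant")
    if kwargs.get("demography") is not None:
        kwargs["demography"] = _build(
            DemographyConfig,
            kwargs["demography"],
            "demography",
            casts={"bounds": lambda b: tuple(int(x) for x in b)},
        )
    if kwargs.get("environment") is not None:
        kwargs["environment"] = _build(
            EnvironmentConfig, kwargs["environment"], "environment"
        )
    if kwargs.get("collapse") is not None:
        kwargs["collapse"] = _build(CollapseConfig, kwargs["collapse"], "collapse")
    if "bottlenecks" in kwargs and kwargs["bottlenecks"] is not None:
        kwargs["bottlenecks"] = tuple(
            _build(BottleneckEvent, b, f"bottlenecks[{i}]")
            for i, b in enumerate(kwargs["bottlenecks"])
        )
    try:
        return ScenarioConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: ScenarioConfig) -> dict:
    """Fully resolved (defaults expanded) plain-dict form of a config."""
    d = dataclasses.asdict(config)
    d["bottlenecks"] = [dataclasses.asdict(b) for b in config.bottlenecks]
    if config.demography is not None:
        d["demography"]["bounds"] = list(config.demography.bounds)
    return d


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a YAML or JSON scenario config; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    return config_from_dict(raw)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def _events_path(path: Path) -> Path:
    return path.with_name(path.stem + "_events.csv")


def write_trajectory(
    trajectory: Trajectory, path: str | Path, events_path: str | Path | None = None
) -> None:
    """Write a trajectory CSV plus an event-log sidecar CSV.

    Columns: step, pop_size, environment, guild_<i>_repertoire..., total_repertoire.
    """
    path = Path(path)
    g = trajectory.n_guilds
    reps = trajectory.guild_repertoires
    cols: dict[str, np.ndarray] = {
        "step": trajectory.steps,
        "pop_size": trajectory.pop_size,
        "environment": trajectory.env.astype(np.int64),
    }
    for i in range(g):
        cols[f"guild_{i}_repertoire"] = reps[:, i]
    cols["total_repertoire"] = trajectory.total_repertoire
    pd.DataFrame(cols).to_csv(path, index=False)
    ev = pd.DataFrame(
        [(e.step, e.kind, e.detail) for e in trajectory.events],
        columns=["step", "event_type", "detail"],
    )
    ev.to_csv(events_path if events_path is not None else _events_path(path), index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV back into a Trajectory.

    Per-class tool counts are not stored in the CSV; each guild's repertoire
    is restored into the universal class, which leaves every repertoire
    total (and hence all summary statistics) intact.
    """
    df = pd.read_csv(path)
    guild_cols = [c for c in df.columns if c.startswith("guild_")]
    g = len(guild_cols)
    n = len(df)
    counts = np.zeros((n, g, N_CLASSES), dtype=np.int64)
    for i, c in enumerate(guild_cols):
        counts[:, i, 0] = df[c].to_numpy()
    sizes = np.zeros((n, g), dtype=np.int64)
    if g > 0 and n > 0:
        # Per-guild sizes are not serialized; spread the total evenly so the
        # population-size column round-trips.
        pop = df["pop_size"].to_numpy(dtype=np.int64)
        sizes[:] = (pop // g)[:, None]
        sizes[:, 0] += pop - (pop // g) * g
    ev_path = _events_path(Path(path))
    events: list[Event] = []
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        events = [
            Event(int(r.step), str(r.event_type), str(r.detail))
            for r in ev.itertuples()
        ]
    return Trajectory(
        steps=df["step"].to_numpy(dtype=np.int64),
        sizes=sizes,
        env=df["environment"].to_numpy(dtype=np.int8),
        counts=counts,
        events=events,
        config=None,
    )


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run: config echo, seed, version, outputs."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict | None = None
    notes: dict | None = None

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "outputs": self.outputs or {},
            "notes": self.notes or {},
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
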