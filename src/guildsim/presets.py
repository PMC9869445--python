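"""Preset scenarios reproducing the published simulation setups.

Each preset bundles one or two scenario configurations (a non-specialized
population and/or a 10-guild population) together with the measurement
windows used to report steady-state statistics and retention fractions:

* ``fig4_n10`` / ``fig4_n100`` / ``fig4_n1000`` — a single guild of 10, 100
  or 1000 individuals run for 500,000 steps; steady state is measured over
  steps [200,000, 500,000).
* ``fig5`` — populations of 800 (1 vs 10 guilds) held constant for 500,000
  steps, after which total size fluctuates by ±200 between 600 and 1000
  with probability 1e-5 per step; runs last 1,500,000 steps.
* ``fig6`` — populations of 1000 (1 vs 10 guilds); the environment is stable
  until step 200,000 and then switches between two states with probability
  1e-4 per step (90% of tools are environment-specific; mismatched tools
  are lost 10x faster).
* ``fig7a`` — populations of 1000 (1 vs 10 guilds) bottlenecked to 200
  individuals at step 1,000,000.
* ``fig7b`` — a non-specialized population of 300 and a 10-guild population
  of 2500, both bottlenecked to 200 at step 1,000,000.

Per-label random streams are derived deterministically from the preset seed,
so two invocations with the same seed produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import RunManifest, config_to_dict, write_trajectory
from .scenario import (
    BottleneckEvent,
    DemographyConfig,
    EnvironmentConfig,
    ScenarioConfig,
    run_scenario,
)
from .stats import retention, window_stats

__all__ = ["PRESETS", "preset_names", "run_preset"]

_STEADY = (200_000, 500_000)


@dataclass(frozen=True)
class Preset:
    name: str
    configs: dict[str, ScenarioConfig]
    windows: dict[str, tuple[int, int]] = field(default_factory=dict)
    retention_windows: tuple[tuple[int, int], tuple[int, int]] | None = None


def _fig4(n: int, record_every: int) -> Preset:
    return Preset(
        name=f"fig4_n{n}",
        configs={
            "g1": ScenarioConfig(
                n_total=n, g=1, n_steps=500_000, record_every=record_every
            )
        },
        windows={"steady": _STEADY},
    )


def _fig5() -> Preset:
    demo = DemographyConfig(
        change_prob=0.00001, delta=200, bounds=(600, 1000), start_step=500_000
    )
    mk = lambda g: ScenarioConfig(
        n_total=800, g=g, n_steps=1_500_000, demography=demo, record_every=100
    )
    return Preset(
        name="fig5",
        configs={"g1": mk(1), "g10": mk(10)},
        windows={"stable": _STEADY, "fluctuating": (500_000, 1_500_000)},
    )


def _fig6() -> Preset:
    envcfg = EnvironmentConfig(switch_prob=0.0001, start_step=200_000)
    mk = lambda g: ScenarioConfig(
        n_total=1000, g=g, n_steps=1_000_000, environment=envcfg, record_every=100
    )
    return Preset(
        name="fig6",
        configs={"g1": mk(1), "g10": mk(10)},
        windows={"stable": (100_000, 200_000), "switching": (500_000, 1_000_000)},
    )


def _fig7(name: str, n_by_label: dict[str, tuple[int, int]]) -> Preset:
    configs = {
        label: ScenarioConfig(
            n_total=n,
            g=g,
            n_steps=2_000_000,
            bottlenecks=(BottleneckEvent(step=1_000_000, new_total_size=200),),
            record_every=100,
        )
        for label, (n, g) in n_by_label.items()
    }
    # Post-bottleneck window starts after a 200,000-step re-equilibration lag.
    return Preset(
        name=name,
        configs=configs,
        windows={"pre": (500_000, 1_000_000), "post": (1_200_000, 1_500_000)},
        retention_windows=((500_000, 1_000_000), (1_200_000, 1_500_000)),
    )


PRESETS: dict[str, Preset] = {
    p.name: p
    for p in [
        _fig4(10, record_every=1),
        _fig4(100, record_every=10),
        _fig4(1000, record_every=100),
        _fig5(),
        _fig6(),
        _fig7("fig7a", {"g1": (1000, 1), "g10": (1000, 10)}),
        _fig7("fig7b", {"g1": (300, 1), "g10": (2500, 10)}),
    ]
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def _label_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % 2**31)


def run_preset(
    name: str, seed: int, out_dir: str | Path, quiet: bool = True
) -> dict:
    """Run every population of a preset; write trajectories, stats and manifest.

    Returns the stats report (also written to ``<name>_stats.json``).
    """
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        )
    preset = PRESETS[name]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"preset": name, "seed": seed, "labels": {}}
    outputs: dict = {}
    resolved: dict = {}
    for idx, (label, config) in enumerate(sorted(preset.configs.items())):
        cfg = config.with_seed(_label_seed(seed, idx))
        if not quiet:
            print(f"[{name}:{label}] running {cfg.n_steps} steps (seed {cfg.seed})")
        traj = run_scenario(cfg)
        tpath = out_dir / f"{name}_{label}_trajectory.csv"
        write_trajectory(traj, tpath)
        entry: dict = {"seed": cfg.seed, "windows": {}}
        for wname, window in preset.windows.items():
            entry["windows"][wname] = window_stats(traj, window).to_dict()
        if preset.retention_windows is not None:
            pre, post = preset.retention_windows
            entry["retention"] = retention(traj, pre, post)
        entry["n_events"] = len(traj.events)
        report["labels"][label] = entry
        outputs[label] = {
            "trajectory": str(tpath),
            "events": str(tpath.with_name(tpath.stem + "_events.csv")),
        }
        resolved[label] = config_to_dict(cfg)
    import json

    stats_path = out_dir / f"{name}_stats.json"
    stats_path.write_text(json.dumps(report, indent=2) + "\n")
    outputs["stats"] = str(stats_path)
    manifest = RunManifest(config=resolved, seed=seed, outputs=outputs)
    manifest.write(out_dir / f"{name}_manifest.json")
    return report
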