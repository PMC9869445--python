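"""Shared fixtures: long steady-state runs reused across test modules.

All heavy simulations are session-scoped so each is run at most once per
test session.  Seeds are fixed constants so the suite is deterministic.
"""

from __future__ import annotations

import pytest

from guildsim import (
    BottleneckEvent,
    ScenarioConfig,
    run_guild,
    run_scenario,
)

STEADY_WINDOW = (200_000, 500_000)


@pytest.fixture(scope="session")
def guild10_series():
    """Guild of 10, defaults, 500k steps, per-step recording."""
    return run_guild(10, n_steps=500_000, record_every=1, seed=10)


@pytest.fixture(scope="session")
def guild100_series():
    """Guild of 100, defaults, 500k steps, per-step recording."""
    return run_guild(100, n_steps=500_000, record_every=1, seed=100)


@pytest.fixture(scope="session")
def stable_g10_trajectory():
    """10 guilds of 100 (population 1000), stable environment, 500k steps."""
    return run_scenario(
        ScenarioConfig(n_total=1000, g=10, n_steps=500_000, seed=12, record_every=100)
    )


def _bottleneck_run(n_total: int, g: int, seed: int):
    return run_scenario(
        ScenarioConfig(
            n_total=n_total,
            g=g,
            n_steps=1_000_000,
            seed=seed,
            bottlenecks=(BottleneckEvent(step=500_000, new_total_size=200),),
            record_every=100,
        )
    )


@pytest.fixture(scope="session")
def bottleneck_g1_1000():
    return _bottleneck_run(1000, 1, seed=9)


@pytest.fixture(scope="session")
def bottleneck_g10_1000():
    return _bottleneck_run(1000, 10, seed=19)


@pytest.fixture(scope="session")
def bottleneck_g1_300():
    return _bottleneck_run(300, 1, seed=29)
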