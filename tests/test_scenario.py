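"""Scenario engine: events, conservation, independence, collapse."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from guildsim import (
    BottleneckEvent,
    CollapseConfig,
    DemographyConfig,
    EnvironmentConfig,
    ModelParams,
    ScenarioConfig,
    apply_bottleneck,
    apply_demographic_change,
    run_guild,
    run_scenario,
)
from guildsim.scenario import _apply_collapses, _split_equally


class FakeRng:
    """Deterministic stand-in feeding preset uniforms to event appliers."""

    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


class TestConfigValidation:
    def test_requires_one_member_per_guild(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_total=5, g=10)

    def test_bottleneck_must_keep_guilds_populated(self):
        with pytest.raises(ValueError):
            ScenarioConfig(
                n_total=100,
                g=10,
                bottlenecks=(BottleneckEvent(step=10, new_total_size=5),),
            )

    def test_seed_required_to_run(self):
        with pytest.raises(ValueError):
            run_scenario(ScenarioConfig(n_total=10, g=1, n_steps=10))


class TestDemography:
    def test_rejected_at_lower_bound(self):
        sizes = np.array([600], dtype=np.int64)
        demo = DemographyConfig(change_prob=1.0, delta=200, bounds=(600, 1000))
        # first uniform triggers the event, second (>= 0.5) picks "decrease"
        assert not apply_demographic_change(sizes, demo, FakeRng([0.0, 0.9]))
        assert sizes[0] == 600

    def test_equal_split_across_ten_guilds(self):
        sizes = np.full(10, 80, dtype=np.int64)
        demo = DemographyConfig(change_prob=1.0, delta=200, bounds=(600, 1000))
        assert apply_demographic_change(sizes, demo, FakeRng([0.0, 0.1]))  # increase
        assert (sizes == 100).all()

    def test_remainder_round_robin(self):
        sizes = np.full(3, 300, dtype=np.int64)
        demo = DemographyConfig(change_prob=1.0, delta=200, bounds=(600, 2000))
        assert apply_demographic_change(sizes, demo, FakeRng([0.0, 0.1]))
        assert sizes.tolist() == [367, 367, 366]
        assert sizes.sum() == 1100

    def test_disabled_when_probability_zero(self):
        sizes = np.array([800], dtype=np.int64)
        demo = DemographyConfig(change_prob=0.0)
        for u in (0.0, 0.5, 0.99):
            assert not apply_demographic_change(sizes, demo, FakeRng([u, u]))
        assert sizes[0] == 800


class TestBottleneck:
    def test_equal_representation(self):
        sizes = np.full(10, 100, dtype=np.int64)
        apply_bottleneck(sizes, 200)
        assert (sizes == 20).all()

    def test_single_guild(self):
        sizes = np.array([300], dtype=np.int64)
        apply_bottleneck(sizes, 200)
        assert sizes[0] == 200

    def test_noop_at_current_size(self):
        sizes = np.full(4, 25, dtype=np.int64)
        apply_bottleneck(sizes, 100)
        assert (sizes == 25).all()

    def test_rejects_fewer_members_than_guilds(self):
        with pytest.raises(ValueError):
            apply_bottleneck(np.full(10, 10, dtype=np.int64), 5)


class TestCollapse:
    def test_threshold_one_never_collapses(self):
        cfg = ScenarioConfig(
            n_total=40,
            g=4,
            n_steps=30_000,
            seed=1,
            collapse=CollapseConfig(loss_fraction_threshold=1.0, window_steps=500),
            record_every=100,
        )
        traj = run_scenario(cfg)
        assert not any(e.kind == "collapse" for e in traj.events)
        assert (traj.sizes[-1] == 10).all()

    def test_redistribution_conserves_population(self):
        sizes = np.array([10, 11, 12, 13], dtype=np.int64)
        counts = np.array([[5, 0, 0]] * 4, dtype=np.int64)
        alive = np.ones(4, dtype=bool)
        gone = _apply_collapses(
            np.array([True, False, True, False]), sizes, counts, alive
        )
        assert sorted(gone) == [0, 2]
        assert sizes.sum() == 46
        assert sizes[0] == 0 and sizes[2] == 0
        assert counts[0].sum() == 0 and counts[2].sum() == 0
        assert alive.tolist() == [False, True, False, True]

    def test_total_collapse_spares_largest_repertoire(self):
        sizes = np.array([10, 10, 10], dtype=np.int64)
        counts = np.array([[3, 0, 0], [9, 0, 0], [9, 0, 0]], dtype=np.int64)
        alive = np.ones(3, dtype=bool)
        gone = _apply_collapses(np.array([True, True, True]), sizes, counts, alive)
        # guild 1 has the (tied) largest repertoire and the lowest index
        assert sorted(gone) == [0, 2]
        assert alive.tolist() == [False, True, False]
        assert sizes.tolist() == [0, 30, 0]

    def test_small_guilds_consolidate_over_time(self):
        """10 guilds of 10 with a 50% crash threshold: collapses thin the
        guild count while conserving the population."""
        cfg = ScenarioConfig(
            n_total=100,
            g=10,
            n_steps=150_000,
            seed=7,
            collapse=CollapseConfig(loss_fraction_threshold=0.5, window_steps=1000),
            record_every=100,
        )
        traj = run_scenario(cfg)
        n_alive = int((traj.sizes[-1] > 0).sum())
        assert 1 <= n_alive < 10
        assert traj.pop_size[-1] == 100
        assert any(e.kind == "collapse" for e in traj.events)


class TestEngine:
    def test_single_guild_scenario_equals_run_guild(self):
        cfg = ScenarioConfig(n_total=50, g=1, n_steps=20_000, seed=3, record_every=1)
        traj = run_scenario(cfg)
        series = run_guild(50, n_steps=20_000, record_every=1, seed=3)
        np.testing.assert_array_equal(traj.total_repertoire, series)

    def test_reproducible_byte_for_byte(self):
        cfg = ScenarioConfig(
            n_total=60,
            g=3,
            n_steps=20_000,
            seed=11,
            demography=DemographyConfig(change_prob=0.001, delta=6, bounds=(30, 90)),
            environment=EnvironmentConfig(switch_prob=0.001),
            record_every=10,
        )
        a, b = run_scenario(cfg), run_scenario(cfg)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.sizes, b.sizes)
        np.testing.assert_array_equal(a.env, b.env)
        assert a.events == b.events

    def test_population_conserved_between_events(self):
        cfg = ScenarioConfig(
            n_total=800,
            g=4,
            n_steps=30_000,
            seed=13,
            demography=DemographyConfig(change_prob=0.002, delta=40, bounds=(600, 1000)),
            record_every=10,
        )
        traj = run_scenario(cfg)
        pop = traj.pop_size
        change_steps = {e.step for e in traj.events if e.kind == "demography"}
        assert change_steps  # the event fired at this probability
        jumps = np.flatnonzero(np.diff(pop) != 0) + 1
        for idx in jumps:
            lo, hi = traj.steps[idx - 1], traj.steps[idx]
            assert any(lo < s <= hi for s in change_steps)
        assert pop.min() >= 600 and pop.max() <= 1000

    def test_totals_are_sums_over_guilds_and_classes(self, stable_g10_trajectory):
        traj = stable_g10_trajectory
        np.testing.assert_array_equal(
            traj.total_repertoire, traj.guild_repertoires.sum(axis=1)
        )
        np.testing.assert_array_equal(traj.pop_size, traj.sizes.sum(axis=1))

    def test_guilds_behave_like_independent_runs(self):
        """Per-guild steady-state means from 4-guild runs are distributionally
        indistinguishable from independent single-guild runs (guild size 10)."""
        pooled = []
        for i in range(8):
            cfg = ScenarioConfig(
                n_total=40, g=4, n_steps=100_000, seed=500 + i, record_every=10
            )
            reps = run_scenario(cfg).guild_repertoires
            pooled.extend(reps[2000:].mean(axis=0))  # steps >= 20,000
        singles = [
            run_guild(10, n_steps=100_000, record_every=10, seed=700 + i)[2000:].mean()
            for i in range(32)
        ]
        stat, p_value = mannwhitneyu(pooled, singles, alternative="two-sided")
        assert p_value > 0.01

    def test_environment_tagging_tracks_current_environment(self):
        cfg = ScenarioConfig(
            n_total=400,
            g=1,
            n_steps=20_000,
            seed=21,
            environment=EnvironmentConfig(switch_prob=0.0),
            record_every=100,
        )
        traj = run_scenario(cfg)
        by_class = traj.counts[-1, 0]
        assert by_class[2] == 0  # environment 1 never visited
        assert by_class[1] > 0  # specific tools accumulate in environment 0
        frac = by_class[1] / (by_class[0] + by_class[1])
        assert 0.8 < frac < 0.97  # ~90% of inventions are environment-specific

    def test_switching_environment_prunes_mismatched_tools(self):
        base = ScenarioConfig(
            n_total=200,
            g=1,
            n_steps=150_000,
            seed=23,
            environment=EnvironmentConfig(switch_prob=0.0005),
            record_every=10,
        )
        switching = run_scenario(base)
        stable = run_scenario(
            dataclasses.replace(
                base, environment=EnvironmentConfig(switch_prob=0.0), seed=24
            )
        )
        assert switching.total_repertoire[5000:].mean() < stable.total_repertoire[
            5000:
        ].mean()
        assert any(e.kind == "env_switch" for e in switching.events)


def test_split_equally_round_robin():
    assert _split_equally(10, 3).tolist() == [4, 3, 3]
    assert _split_equally(200, 10).tolist() == [20] * 10
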