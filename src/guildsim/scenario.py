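"""Population-level orchestration of guild dynamics.

A scenario runs g equal-sized, culturally independent guilds forward in
time and layers scheduled events on top of the per-guild innovation-loss
process:

* demographic fluctuation — with a small per-step probability the total
  population grows or shrinks by a fixed delta (split equally across
  guilds), bounded to a size interval;
* environmental switching — the shared environment flips between two
  states with a small per-step probability; environment-specific tools
  suffer a 10-fold loss multiplier while mismatched;
* bottlenecks — at scheduled steps every guild is resized so the total
  hits a new (smaller) population size; repertoires are left intact and
  subsequent loss dynamics at the smaller N do the damage;
* guild collapse — a guild that loses more than a threshold fraction of
  its repertoire relative to its maximum within a trailing window is
  dissolved: its tools are lost and its members divided among the
  surviving guilds.

Within a step events apply in a fixed order (demography, environment,
bottleneck, guild updates, collapse check) so runs are reproducible
byte-for-byte from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import N_CLASSES, VariantConfig, _ln_c
from .params import ModelParams

__all__ = [
    "DemographyConfig",
    "EnvironmentConfig",
    "BottleneckEvent",
    "CollapseConfig",
    "ScenarioConfig",
    "Event",
    "Trajectory",
    "apply_demographic_change",
    "apply_bottleneck",
    "run_scenario",
]


@dataclass(frozen=True)
class DemographyConfig:
    """Stochastic fluctuation of total population size."""

    change_prob: float = 0.00001
    delta: int = 200
    bounds: tuple[int, int] = (600, 1000)
    start_step: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.change_prob <= 1.0:
            raise ValueError(f"change_prob must be in [0, 1], got {self.change_prob}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        lo, hi = self.bounds
        if not (0 < lo <= hi):
            raise ValueError(f"bounds must satisfy 0 < low <= high, got {self.bounds}")
        if self.start_step < 0:
            raise ValueError("start_step must be >= 0")


@dataclass(frozen=True)
class EnvironmentConfig:
    """Switching between two environments; enables environment-specific tools."""

    switch_prob: float = 0.0001
    start_step: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError(f"switch_prob must be in [0, 1], got {self.switch_prob}")
        if self.start_step < 0:
            raise ValueError("start_step must be >= 0")


@dataclass(frozen=True)
class BottleneckEvent:
    """Instantaneous contraction of the whole population at a given step."""

    step: int
    new_total_size: int

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("bottleneck step must be >= 1")
        if self.new_total_size < 1:
            raise ValueError("bottleneck size must be >= 1")


@dataclass(frozen=True)
class CollapseConfig:
    """Guild-collapse rule: dissolve guilds after steep repertoire crashes."""

    loss_fraction_threshold: float
    window_steps: int
    enabled_after_step: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_fraction_threshold <= 1.0:
            raise ValueError(
                "loss_fraction_threshold must be in [0, 1], got "
                f"{self.loss_fraction_threshold}"
            )
        if self.window_steps < 1:
            raise ValueError("window_steps must be >= 1")
        if self.enabled_after_step < 0:
            raise ValueError("enabled_after_step must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    n_total: int = 100
    g: int = 1
    n_steps: int = 500_000
    params: ModelParams = field(default_factory=ModelParams)
    variant: VariantConfig = field(default_factory=VariantConfig)
    seed: int | None = None
    demography: DemographyConfig | None = None
    environment: EnvironmentConfig | None = None
    bottlenecks: tuple[BottleneckEvent, ...] = ()
    collapse: CollapseConfig | None = None
    record_every: int = 100

    def __post_init__(self) -> None:
        if self.g < 1:
            raise ValueError(f"guild count must be >= 1, got {self.g}")
        if self.n_total < self.g:
            raise ValueError(
                f"n_total ({self.n_total}) must be >= guild count ({self.g}): "
                "every guild needs at least one member"
            )
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        object.__setattr__(self, "bottlenecks", tuple(self.bottlenecks))
        steps = [b.step for b in self.bottlenecks]
        if len(set(steps)) != len(steps):
            raise ValueError("bottleneck steps must be distinct")
        for b in self.bottlenecks:
            if b.new_total_size < self.g:
                raise ValueError(
                    f"bottleneck size {b.new_total_size} < guild count {self.g}: "
                    "every guild must retain at least one individual"
                )

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class Event:
    step: int
    kind: str  # demography | env_switch | bottleneck | collapse | guild_died
    detail: str


@dataclass
class Trajectory:
    """Recorded state of a scenario run.

    Arrays are indexed by record number; entry i is the state after
    ``steps[i]`` time steps (entry 0 is the initial state).  ``counts`` has
    shape (n_records, g, 3): per-guild tool counts per class.
    """

    steps: np.ndarray
    sizes: np.ndarray  # (n_records, g) per-guild sizes
    env: np.ndarray  # (n_records,) environment id
    counts: np.ndarray  # (n_records, g, 3)
    events: list[Event]
    config: ScenarioConfig | None = None

    @property
    def n_guilds(self) -> int:
        return self.sizes.shape[1]

    @property
    def pop_size(self) -> np.ndarray:
        return self.sizes.sum(axis=1)

    @property
    def guild_repertoires(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    @property
    def total_repertoire(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))


def _split_equally(total: int, k: int) -> np.ndarray:
    """k parts of total, as equal as possible; remainder round-robin by index."""
    q, r = divmod(total, k)
    out = np.full(k, q, dtype=np.int64)
    out[:r] += 1
    return out


def apply_demographic_change(
    sizes: np.ndarray,
    demography: DemographyConfig,
    rng: np.random.Generator,
    alive: np.ndarray | None = None,
) -> bool:
    """Possibly grow or shrink the population by delta; True if it changed.

    With probability ``change_prob`` a direction is drawn equiprobably; the
    move is rejected (sizes unchanged) if it would leave the bounds or drop
    any living guild below one member.  The delta is split equally across
    living guilds, remainder assigned round-robin by guild index.
    """
    if rng.random() >= demography.change_prob:
        return False
    delta = demography.delta if rng.random() < 0.5 else -demography.delta
    if alive is None:
        alive = sizes > 0
    idx = np.flatnonzero(alive)
    new_total = int(sizes[idx].sum()) + delta
    lo, hi = demography.bounds
    if not lo <= new_total <= hi:
        return False
    share = _split_equally(abs(delta), len(idx))
    change = share if delta > 0 else -share
    if (sizes[idx] + change < 1).any():
        return False
    sizes[idx] += change
    return True


def apply_bottleneck(
    sizes: np.ndarray, new_total_size: int, alive: np.ndarray | None = None
) -> None:
    """Resize every living guild so the total equals ``new_total_size``.

    Guilds are assumed equally represented in the bottlenecked population:
    each is resized to new_total/g (remainder round-robin).  Repertoires are
    not touched; intensified loss at the smaller sizes follows on its own.
    """
    if alive is None:
        alive = sizes > 0
    idx = np.flatnonzero(alive)
    if new_total_size < len(idx):
        raise ValueError(
            f"bottleneck size {new_total_size} < number of living guilds {len(idx)}"
        )
    sizes[idx] = _split_equally(new_total_size, len(idx))


def _apply_collapses(
    collapsing: np.ndarray,
    sizes: np.ndarray,
    counts: np.ndarray,
    alive: np.ndarray,
) -> list[int]:
    """Dissolve the given guilds, conserving total population size.

    If every living guild would collapse at once, the one with the largest
    repertoire (lowest index on ties) survives.  Members of collapsed guilds
    are divided equally among survivors (remainder round-robin by index);
    their tools are lost.
    """
    coll = np.flatnonzero(collapsing & alive)
    if len(coll) == 0:
        return []
    survivors = np.flatnonzero(alive & ~collapsing)
    if len(survivors) == 0:
        reps = counts.sum(axis=1)
        keep = coll[np.argmax(reps[coll])]  # argmax takes lowest index on ties
        coll = coll[coll != keep]
        survivors = np.array([keep])
        if len(coll) == 0:
            return []
    freed = int(sizes[coll].sum())
    sizes[coll] = 0
    counts[coll] = 0
    alive[coll] = False
    sizes[survivors] += _split_equally(freed, len(survivors))
    return [int(j) for j in coll]


_CHUNK = 4096  # establishment counts pre-drawn this many steps at a time


def run_scenario(config: ScenarioConfig) -> Trajectory:
    """Run a full scenario; deterministic given ``config.seed``.

    The inner loop samples the model exactly but in aggregated form: per
    step each guild draws its number of newly established tools directly
    from Binomial(N, p_inv * q) with ``q = beta * (1 - exp(-1/beta))``, the
    exact marginal establishment probability of an invention attempt whose
    selection coefficient is Exponential(beta) clamped to 1, and losses as
    one Binomial(count, loss probability) per tool class.  Establishment
    counts do not depend on the repertoire, so they are pre-drawn in chunks
    (re-drawn whenever guild sizes change); loss draws are state-dependent
    and made step by step.
    """
    if config.seed is None:
        raise ValueError("ScenarioConfig.seed must be set to run a scenario")
    params, variant = config.params, config.variant
    g = config.g
    rng = np.random.default_rng(config.seed)
    rbinom = rng.binomial
    runif = rng.random
    exp = math.exp

    sizes = _split_equally(config.n_total, g)
    counts = [[0, 0, 0] for _ in range(g)]
    alive = np.ones(g, dtype=bool)
    env = 0
    env_on = config.environment is not None
    lnc = _ln_c(params, variant)
    t_max = variant.t_max
    p_loss = params.p_loss
    frac = params.env_specific_fraction
    mult = params.env_loss_multiplier
    # Exact marginal establishment probability per individual per step.
    pq = params.p_inv * params.beta * (1.0 - exp(-1.0 / params.beta))
    events: list[Event] = []
    flagged_dead: set[int] = set()

    base = [0.0] * g  # per-guild p_loss / N, inf for empty guilds

    def refresh_base() -> None:
        for j in range(g):
            n = int(sizes[j])
            base[j] = (p_loss / n) if n > 0 else math.inf

    est_rows: list[list[int]] = []
    est_tot: list[int] = []
    bi = 0

    def draw_chunk() -> None:
        nonlocal est_rows, est_tot, bi
        buf = rng.binomial(sizes, pq, size=(_CHUNK, g))
        est_rows = buf.tolist()
        est_tot = buf.sum(axis=1).tolist()
        bi = 0

    refresh_base()
    draw_chunk()

    bneck = {b.step: b.new_total_size for b in config.bottlenecks}
    demo = config.demography
    envcfg = config.environment
    coll = config.collapse
    if coll is not None:
        hist = np.zeros((coll.window_steps, g), dtype=np.int64)
        hist_n = 0

    record_every = config.record_every
    n_rec = config.n_steps // record_every + 1
    rec_steps = np.zeros(n_rec, dtype=np.int64)
    rec_sizes = np.zeros((n_rec, g), dtype=np.int64)
    rec_env = np.zeros(n_rec, dtype=np.int8)
    rec_counts = np.zeros((n_rec, g, N_CLASSES), dtype=np.int64)
    rec_sizes[0] = sizes
    k = 1

    have_events = demo is not None or envcfg is not None or bool(bneck)

    for step in range(1, config.n_steps + 1):
        if have_events:
            changed = False
            if demo is not None and step >= demo.start_step:
                before = int(sizes.sum())
                if apply_demographic_change(sizes, demo, rng, alive):
                    events.append(
                        Event(step, "demography", f"{before}->{int(sizes.sum())}")
                    )
                    changed = True
            if envcfg is not None and step >= envcfg.start_step:
                if runif() < envcfg.switch_prob:
                    env = 1 - env
                    events.append(Event(step, "env_switch", f"env={env}"))
            if step in bneck:
                before = int(sizes.sum())
                apply_bottleneck(sizes, bneck[step], alive)
                events.append(Event(step, "bottleneck", f"{before}->{bneck[step]}"))
                changed = True
            if changed:
                refresh_base()
                draw_chunk()

        row = est_rows[bi]
        etot = est_tot[bi]
        bi += 1
        if bi == _CHUNK:
            draw_chunk()

        if env_on:
            spec_cls = 1 + env
            other_cls = 2 - env
            for j in range(g):
                cj = counts[j]
                tj = cj[0] + cj[1] + cj[2]
                if tj:
                    b = base[j] * exp(tj * lnc) if tj * lnc < 700 else math.inf
                    if b >= 1.0:
                        if cj[0] or cj[1] or cj[2]:
                            cj[0] = cj[1] = cj[2] = 0
                            if int(sizes[j]) == 0 and j not in flagged_dead:
                                flagged_dead.add(j)
                                events.append(
                                    Event(step, "guild_died", f"guild {j} (size 0) lost all tools")
                                )
                    else:
                        if cj[0]:
                            cj[0] -= rbinom(cj[0], b)
                        if cj[spec_cls]:
                            cj[spec_cls] -= rbinom(cj[spec_cls], b)
                        if cj[other_cls]:
                            pm = b * mult
                            cj[other_cls] -= rbinom(
                                cj[other_cls], pm if pm < 1.0 else 1.0
                            )
                if etot:
                    e = row[j]
                    if e:
                        if t_max is not None:
                            room = t_max - (cj[0] + cj[1] + cj[2])
                            e = min(e, room if room > 0 else 0)
                            if e == 0:
                                continue
                        spec = int(rbinom(e, frac))
                        cj[spec_cls] += spec
                        cj[0] += e - spec
        else:
            for j in range(g):
                cj = counts[j]
                tj = cj[0]
                if tj:
                    b = base[j] * exp(tj * lnc) if tj * lnc < 700 else math.inf
                    if b >= 1.0:
                        cj[0] = 0
                        if int(sizes[j]) == 0 and j not in flagged_dead:
                            flagged_dead.add(j)
                            events.append(
                                Event(step, "guild_died", f"guild {j} (size 0) lost all tools")
                            )
                    else:
                        cj[0] = tj - rbinom(tj, b)
                if etot:
                    e = row[j]
                    if e:
                        if t_max is not None:
                            room = t_max - cj[0]
                            e = min(e, room if room > 0 else 0)
                        cj[0] += e

        if coll is not None:
            reps_list = [c[0] + c[1] + c[2] for c in counts]
            hist[(step - 1) % coll.window_steps] = reps_list
            hist_n += 1
            if hist_n >= coll.window_steps and step >= coll.enabled_after_step:
                reps = np.array(reps_list, dtype=np.int64)
                peak = hist.max(axis=0)
                crashing = reps < (1.0 - coll.loss_fraction_threshold) * peak
                if (crashing & alive).any():
                    counts_arr = np.array(counts, dtype=np.int64)
                    gone = _apply_collapses(crashing, sizes, counts_arr, alive)
                    if gone:
                        counts = counts_arr.tolist()
                        for j in gone:
                            hist[:, j] = 0
                            events.append(Event(step, "collapse", f"guild {j} collapsed"))
                        refresh_base()
                        draw_chunk()

        if step % record_every == 0:
            rec_steps[k] = step
            rec_sizes[k] = sizes
            rec_env[k] = env
            rec_counts[k] = counts
            k += 1

    return Trajectory(
        steps=rec_steps,
        sizes=rec_sizes,
        env=rec_env,
        counts=rec_counts,
        events=events,
        config=config,
    )
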