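"""Per-time-step stochastic update of a single guild.

State is kept as per-class tool counts rather than per-tool records: once
established, tools within a class are exchangeable (each is lost
independently with the same probability), so losses collapse to one binomial
draw per class.  This is what makes million-step runs cheap.

Tool classes (fixed layout, two environments):

* class 0 — universal tools, never subject to the environment multiplier;
* class 1 — tools specific to environment 0;
* class 2 — tools specific to environment 1.

In runs without the environment model only class 0 is ever populated.

Two model variants are supported:

* ``capacity_exponent`` (main model): per-tool loss ``(p_loss/N) * c**t``;
* ``hard_cap``: per-tool loss ``p_loss/N`` but the guild repertoire cannot
  exceed ``t_max`` (establishments that would push it over are discarded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "UNIVERSAL",
    "N_CLASSES",
    "env_class",
    "VariantConfig",
    "GuildState",
    "draw_established_inventions",
    "loss_probability",
    "step_guild",
    "run_guild",
]

UNIVERSAL = 0
N_CLASSES = 3


def env_class(env: int) -> int:
    """Class index of tools specific to environment ``env`` (0 or 1)."""
    if env not in (0, 1):
        raise ValueError(f"environment id must be 0 or 1, got {env}")
    return 1 + env


@dataclass(frozen=True)
class VariantConfig:
    """Which loss model to run: capacity exponent (default) or hard cap."""

    variant: str = "capacity_exponent"
    t_max: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("capacity_exponent", "hard_cap"):
            raise ValueError(
                "variant must be 'capacity_exponent' or 'hard_cap', "
                f"got {self.variant!r}"
            )
        if self.variant == "hard_cap":
            if self.t_max is None or self.t_max < 0:
                raise ValueError("hard_cap requires t_max >= 0")


@dataclass
class GuildState:
    """One guild: its size N and tool counts per class (repertoire t = sum)."""

    size: int
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CLASSES, dtype=np.int64)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.size < 0:
            raise ValueError(f"guild size must be >= 0, got {self.size}")
        if self.counts.shape != (N_CLASSES,) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative vector of length 3")

    @property
    def repertoire(self) -> int:
        return int(self.counts.sum())


def _ln_c(params: ModelParams, variant: VariantConfig) -> float:
    """Capacity exponent rate; 0 under hard_cap (loss independent of t)."""
    return math.log(params.c) if variant.variant == "capacity_exponent" else 0.0


def _advance(
    counts: np.ndarray,
    sizes: np.ndarray,
    params: ModelParams,
    lnc: float,
    t_max: int | None,
    env: int,
    env_on: bool,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """One synchronous update of all guilds; mutates ``counts`` in place.

    Loss probabilities use the start-of-step repertoire; establishments are
    added afterwards.  A guild of size 0 loses its whole repertoire (no one
    is left to maintain the culture) and invents nothing; indices of guilds
    that lost tools this way are returned for event logging.

    ``counts`` has shape (g, 3); ``sizes`` shape (g,).
    """
    t = counts.sum(axis=1)
    dead = None
    if t.any():
        with np.errstate(divide="ignore", over="ignore"):
            base = (params.p_loss / sizes) * np.exp(t * lnc)
        if env_on:
            prob = np.broadcast_to(base[:, None], counts.shape).copy()
            prob[:, 2 - env] *= params.env_loss_multiplier  # mismatched class
            np.clip(prob, 0.0, 1.0, out=prob)
            counts -= rng.binomial(counts, prob)
        else:
            p0 = np.clip(base, 0.0, 1.0)
            counts[:, 0] -= rng.binomial(counts[:, 0], p0)
        zeroed = (sizes == 0) & (t > 0)
        if zeroed.any():
            dead = np.flatnonzero(zeroed)
    attempts = rng.binomial(sizes, params.p_inv)
    if attempts.any():
        for j in np.flatnonzero(attempts):
            a = int(attempts[j])
            s = rng.exponential(params.beta, a)
            est = int(np.count_nonzero(rng.random(a) < np.minimum(s, 1.0)))
            if est == 0:
                continue
            if t_max is not None:
                room = t_max - int(counts[j].sum())
                est = min(est, max(room, 0))
                if est == 0:
                    continue
            if env_on:
                spec = int(rng.binomial(est, params.env_specific_fraction))
                counts[j, 1 + env] += spec
                counts[j, 0] += est - spec
            else:
                counts[j, 0] += est
    return dead


def draw_established_inventions(
    size: int,
    params: ModelParams | None = None,
    current_env: int = 0,
    env_model_on: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Newly established tools this step, as per-class counts.

    Invention attempts are Binomial(size, p_inv); each attempt draws a
    selection coefficient s ~ Exponential(mean beta) and establishes with
    probability min(s, 1).  Established tools are tagged specific to the
    current environment with probability ``env_specific_fraction`` when the
    environment model is on, otherwise universal.
    """
    params = params if params is not None else ModelParams()
    if size < 0:
        raise ValueError(f"guild size must be >= 0, got {size}")
    rng = rng if rng is not None else np.random.default_rng()
    out = np.zeros(N_CLASSES, dtype=np.int64)
    a = int(rng.binomial(size, params.p_inv))
    if a == 0:
        return out
    s = rng.exponential(params.beta, a)
    est = int(np.count_nonzero(rng.random(a) < np.minimum(s, 1.0)))
    if est == 0:
        return out
    if env_model_on:
        spec = int(rng.binomial(est, params.env_specific_fraction))
        out[env_class(current_env)] = spec
        out[UNIVERSAL] = est - spec
    else:
        out[UNIVERSAL] = est
    return out


def loss_probability(
    state: GuildState,
    cls: int,
    params: ModelParams | None = None,
    current_env: int = 0,
    variant: VariantConfig | None = None,
) -> float:
    """Per-tool loss probability this step for tools of class ``cls``.

    ``(p_loss / N) * c**t`` under the capacity-exponent variant (t is the
    guild's start-of-step repertoire), ``p_loss / N`` under hard_cap; a
    further ``env_loss_multiplier`` applies to environment-specific tools
    when the current environment is mismatched.  The result is clamped to
    [0, 1]; a guild of size 0 loses every tool with certainty.
    """
    params = params if params is not None else ModelParams()
    variant = variant if variant is not None else VariantConfig()
    if cls not in (0, 1, 2):
        raise ValueError(f"tool class must be 0, 1 or 2, got {cls}")
    if state.size == 0:
        return 1.0
    # c**t evaluated in log space so huge repertoires cannot overflow.
    log_p = (
        math.log(params.p_loss) - math.log(state.size)
        + state.repertoire * _ln_c(params, variant)
    )
    if cls != UNIVERSAL and cls != env_class(current_env):
        log_p += math.log(params.env_loss_multiplier)
    return min(math.exp(log_p), 1.0)


def step_guild(
    state: GuildState,
    params: ModelParams | None = None,
    current_env: int = 0,
    variant: VariantConfig | None = None,
    rng: np.random.Generator | None = None,
    env_model_on: bool = False,
) -> GuildState:
    """One time step: binomial losses per class, then new establishments."""
    params = params if params is not None else ModelParams()
    variant = variant if variant is not None else VariantConfig()
    rng = rng if rng is not None else np.random.default_rng()
    counts = state.counts[None, :].copy()
    sizes = np.array([state.size], dtype=np.int64)
    _advance(
        counts,
        sizes,
        params,
        _ln_c(params, variant),
        variant.t_max,
        current_env,
        env_model_on,
        rng,
    )
    return GuildState(size=state.size, counts=counts[0])


def run_guild(
    size: int,
    params: ModelParams | None = None,
    variant: VariantConfig | None = None,
    n_steps: int = 500_000,
    record_every: int = 1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Repertoire time series of a single guild starting from an empty repertoire.

    Returns an integer array of length ``n_steps // record_every + 1`` whose
    entry i is the repertoire after ``i * record_every`` steps (entry 0 is
    the empty starting state).  Deterministic given ``seed``; identical to a
    one-guild, event-free scenario run with the same seed.
    """
    from .scenario import ScenarioConfig, run_scenario

    if size < 1:
        raise ValueError(f"guild size must be >= 1 to run, got {size}")
    if rng is not None:
        raise ValueError("run_guild is seed-driven; pass seed= instead of rng=")
    if seed is None:
        raise ValueError("run_guild requires a seed")
    config = ScenarioConfig(
        n_total=size,
        g=1,
        n_steps=n_steps,
        params=params if params is not None else ModelParams(),
        variant=variant if variant is not None else VariantConfig(),
        seed=seed,
        record_every=record_every,
    )
    return run_scenario(config).total_repertoire
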