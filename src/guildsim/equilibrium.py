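"""Closed-form equilibrium repertoire size and derived quantities.

At equilibrium the expected number of establishments per step equals the
expected number of losses per step::

    p_inv * N * beta = (p_loss / N) * c**t * t

Solving for t with the principal branch of the Lambert W function gives

    t*(N) = W(N**2 * ln(c) * p_inv * beta / p_loss) / ln(c)

For c == 1 the balance equation is linear in t and the equilibrium reduces to
``t*(N) = N**2 * p_inv * beta / p_loss`` (the ln(c) -> 0 limit).

A population of N individuals split into g equal guilds is g independent
copies of the single-guild process at size N/g, so its total equilibrium
repertoire is ``g * t*(N/g)``.  The analytic operations below treat guild
size as continuous; only the stochastic simulator requires integers.
"""

from __future__ import annotations

import math

from scipy.special import lambertw

from .params import ModelParams

__all__ = [
    "equilibrium_repertoire",
    "total_equilibrium",
    "optimal_guild_count",
    "guild_advantage_threshold",
    "doubling_threshold",
]


def equilibrium_repertoire(n: float, params: ModelParams | None = None) -> float:
    """Expected repertoire size at equilibrium for a single guild of size ``n``.

    ``n`` may be non-integer (continuous guild size).  Raises ``ValueError``
    for non-positive ``n``.
    """
    params = params if params is not None else ModelParams()
    if not n > 0:
        raise ValueError(f"guild size must be > 0, got {n}")
    k = params.p_inv * params.beta / params.p_loss
    if params.c == 1.0:
        # ln(c) -> 0 limit of the Lambert-W form.
        return n * n * k
    lnc = math.log(params.c)
    arg = n * n * lnc * k
    return float(lambertw(arg).real) / lnc


def total_equilibrium(
    n_total: float, g: int, params: ModelParams | None = None
) -> float:
    """Total equilibrium repertoire of ``n_total`` individuals in ``g`` equal guilds.

    Guild size ``n_total / g`` is treated as continuous.
    """
    if g < 1:
        raise ValueError(f"guild count must be >= 1, got {g}")
    if not n_total > 0:
        raise ValueError(f"population size must be > 0, got {n_total}")
    return g * equilibrium_repertoire(n_total / g, params)


def optimal_guild_count(
    n_total: float,
    params: ModelParams | None = None,
    g_max: int = 50,
) -> int:
    """Guild count in 1..g_max maximizing the total equilibrium repertoire.

    Ties are broken toward the smallest g (less subdivision: small guilds are
    the fragile ones, so subdividing without a repertoire gain is never
    preferred).
    """
    if g_max < 1:
        raise ValueError(f"g_max must be >= 1, got {g_max}")
    best_g, best_total = 1, -math.inf
    for g in range(1, g_max + 1):
        tot = total_equilibrium(n_total, g, params)
        if tot > best_total:
            best_g, best_total = g, tot
    return best_g


def guild_advantage_threshold(
    g: int,
    params: ModelParams | None = None,
    n_max: int = 10_000_000,
) -> int | None:
    """Largest integer population size at which one guild still beats ``g`` guilds.

    Returns the largest integer N with ``t*(N) >= g * t*(N/g)``, i.e. the
    population size below (and at) which a non-specialized population holds
    at least as large an equilibrium repertoire as the same population split
    into ``g`` equal guilds of continuous size N/g.  Returns ``None`` if no
    crossover exists at or below ``n_max`` (for instance when c == 1, where
    t* scales as N**2 and subdivision always loses).
    """
    if g < 2:
        raise ValueError(f"guild count must be >= 2, got {g}")
    params = params if params is not None else ModelParams()

    def gap(n: int) -> float:
        return equilibrium_repertoire(n, params) - total_equilibrium(n, g, params)

    # Exponential scan for the first power-of-two N where subdivision wins,
    # then binary search for the crossover; gap crosses zero once (the
    # single-guild curve saturates while the subdivided one still grows).
    lo = 1
    if gap(lo) < 0:
        return None  # subdivision already wins at N=1; no advantage region
    hi = 2
    while hi <= n_max and gap(hi) >= 0:
        lo, hi = hi, hi * 2
    if hi > n_max:
        return None
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if gap(mid) >= 0:
            lo = mid
        else:
            hi = mid
    return lo


def doubling_threshold(params: ModelParams | None = None) -> float:
    """Population size above which doubling N less than doubles t*(N).

    The continuous solution of ``t*(2N) = 2 t*(N)`` is
    ``N* = sqrt(2 ln 2 / k)`` with ``k = ln(c) * p_inv * beta / p_loss``
    (at the crossover the Lambert-W argument satisfies W(k N**2) = ln 2).
    Above N* a non-specialized population of 2N does better split into two
    guilds of N.  Requires c > 1 (no threshold exists at c == 1, where t*
    is quadratic in N and doubling always more than doubles it).
    """
    params = params if params is not None else ModelParams()
    if params.c == 1.0:
        raise ValueError("doubling threshold is undefined for c == 1")
    k = math.log(params.c) * params.p_inv * params.beta / params.p_loss
    return math.sqrt(2.0 * math.log(2.0) / k)
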