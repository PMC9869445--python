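"""Independent oracles used by the test suite.

Everything here is deliberately implemented through a different route than
the package: bisection instead of Lambert W, an explicit truncated Markov
chain instead of simulation, and a per-tool simulator driven by Python's
``random`` module instead of aggregated numpy binomials.
"""

from __future__ import annotations

import math
import random

import numpy as np
from scipy.integrate import quad
from scipy.stats import binom

from guildsim import ModelParams


def balance_gap(t: float, n: float, params: ModelParams) -> float:
    """Establishment rate minus loss rate at repertoire t (zero at equilibrium)."""
    return params.p_inv * n * params.beta - (params.p_loss / n) * params.c**t * t


def bisect_equilibrium(n: float, params: ModelParams, tol: float = 1e-12) -> float:
    """Equilibrium repertoire by bisection on the balance equation."""
    lo, hi = 0.0, 1.0
    while balance_gap(hi, n, params) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("no sign change found")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if balance_gap(mid, n, params) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


def establishment_prob(params: ModelParams) -> float:
    """E[min(s, 1)] for s ~ Exponential(mean beta), by numeric integration."""
    pdf = lambda x: math.exp(-x / params.beta) / params.beta
    inside, _ = quad(lambda x: x * pdf(x), 0.0, 1.0)
    above, _ = quad(pdf, 1.0, np.inf)
    return inside + above


def markov_stationary(
    size: int, params: ModelParams, t_ceiling: int
) -> tuple[float, np.ndarray]:
    """Stationary distribution of the repertoire-size birth-death chain.

    Births ~ Binomial(size, p_inv * q) with q from numeric integration;
    deaths ~ Binomial(t, min((p_loss/size) * c**t, 1)).  The chain is
    truncated at ``t_ceiling`` (excess birth mass lumped into the top
    state).  Returns (stationary mean, stationary pmf).
    """
    q = establishment_prob(params)
    n_states = t_ceiling + 1
    birth_pmf = binom.pmf(np.arange(size + 1), size, params.p_inv * q)
    P = np.zeros((n_states, n_states))
    for t in range(n_states):
        p_loss_t = min((params.p_loss / size) * params.c**t, 1.0)
        death_pmf = binom.pmf(np.arange(t + 1), t, p_loss_t)
        for d in range(t + 1):
            if death_pmf[d] < 1e-18:
                continue
            for b in range(size + 1):
                nxt = min(t - d + b, t_ceiling)
                P[t, nxt] += death_pmf[d] * birth_pmf[b]
    # Stationary vector: left eigenvector of P for eigenvalue 1.
    A = np.vstack([P.T - np.eye(n_states), np.ones(n_states)])
    rhs = np.zeros(n_states + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return float(pi @ np.arange(n_states)), pi


def batch_means_se(series: np.ndarray, n_batches: int = 10) -> float:
    """Standard error of the series mean via non-overlapping batch means."""
    n = len(series) // n_batches * n_batches
    batches = series[:n].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / math.sqrt(n_batches))


def per_tool_run(
    size: int, n_steps: int, seed: int, params: ModelParams
) -> np.ndarray:
    """Reference simulator tracking every tool individually.

    Uses Python's Mersenne-Twister ``random`` module (a generator unrelated
    to the package's PCG64 streams): per step each existing tool survives an
    independent Bernoulli loss trial, then each individual makes an
    independent invention attempt with an explicit selection-coefficient
    draw.  Returns the repertoire series (length n_steps + 1, start empty).
    """
    rnd = random.Random(seed)
    t = 0
    out = np.zeros(n_steps + 1, dtype=np.int64)
    for step in range(1, n_steps + 1):
        p = min((params.p_loss / size) * params.c**t, 1.0)
        survivors = 0
        for _ in range(t):
            if rnd.random() >= p:
                survivors += 1
        t = survivors
        for _ in range(size):
            if rnd.random() < params.p_inv:
                s = rnd.expovariate(1.0 / params.beta)
                if rnd.random() < min(s, 1.0):
                    t += 1
        out[step] = t
    return out
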