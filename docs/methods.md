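# Methods

## Model

A population of `n_total` individuals is partitioned into `g` equal guilds.
Guilds are culturally independent: no tools are shared, so a guild of size N
behaves exactly like a non-specialized population of size N, and the
population repertoire is the sum over guilds. Time is discrete; per step and
per guild of size N with repertoire t:

1. **Invention.** Each individual invents with probability `p_inv`
   (attempts ~ Binomial(N, p_inv)).
2. **Establishment.** Each attempt draws a selection coefficient
   s ~ Exponential(mean `beta`) and establishes with probability min(s, 1).
   The clamp makes s a valid probability; Exponential(0.1) exceeds 1 with
   probability e^-10 ≈ 4.5e-5, so its effect is negligible at the defaults.
   An established tool is treated as immediately at its equilibrium
   frequency in the guild — transmission dynamics are folded into the 1 − s
   failure probability.
3. **Loss.** Each established tool is independently lost with probability
   `(p_loss / N) · c^t`, evaluated with the start-of-step repertoire. The
   `c^t` factor models finite individual capacity: the larger the
   repertoire, the harder every tool is to retain and transmit. The
   exponent is computed in log space and the probability clamped to [0, 1].

Losses are drawn first (from start-of-step counts), then establishments are
added. This order makes the one-step expected drift vanish exactly at the
balance point and never exposes a new tool to same-step drift loss (its
pre-establishment attrition is already the 1 − s term).

Equating expected establishments `p_inv·N·beta` with expected losses
`(p_loss/N)·c^t·t` gives the equilibrium repertoire

    t*(N) = W(N² · ln(c) · p_inv · beta / p_loss) / ln(c)

on the principal Lambert-W branch (the argument is non-negative, so W₀
suffices); at c = 1 the balance equation is linear and t* = N²·p_inv·beta/
p_loss, handled as an explicit limit rather than a 0/0 evaluation. The
analytic layer treats guild size N/g as continuous (e.g. 81.3 individuals
per guild when probing the 10-guild crossover); only the simulator requires
integers. Derived quantities:

- `total_equilibrium(N, g) = g · t*(N/g)`;
- `optimal_guild_count`: argmax over g = 1..g_max (default 50, far beyond
  any optimum at the population sizes studied); ties break toward smaller g,
  favouring less subdivision since small guilds are the fragile ones;
- `guild_advantage_threshold(g)`: the largest integer N with
  t*(N) ≥ g·t*(N/g), found by exponential scan plus integer bisection (the
  gap changes sign once: the single-guild curve saturates first). With
  c = 1, t* is quadratic so subdivision never wins and the threshold is
  reported as `None`, not an exception;
- `doubling_threshold`: the continuous root of t*(2N) = 2t*(N), in closed
  form N* = sqrt(2·ln2 / (ln(c)·p_inv·beta/p_loss)) (at the crossover the
  W argument satisfies W = ln 2).

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `p_inv` | 0.001 | invention probability / individual / step |
| `p_loss` | 0.002 | baseline loss scale; per-tool loss is p_loss/N |
| `beta` | 0.1 | mean selection coefficient = establishment probability scale |
| `c` | 1.001 | capacity base multiplying loss by c^t |
| `env_specific_fraction` | 0.9 | share of new tools tied to the current environment |
| `env_loss_multiplier` | 10 | loss multiplier for mismatched environment-specific tools |

All four core rates are dimensionless per-step probabilities/scales; the
time step has no calendar unit.

## Simulation engine

Established tools within a class are exchangeable, so the state is a count
per tool class (universal, specific-to-environment-0, specific-to-
environment-1), not per-tool records. Losses collapse to one Binomial(count,
loss probability) draw per class, and establishments are drawn directly from
Binomial(N, p_inv·q), where q = E[min(s, 1)] = beta·(1 − e^(−1/beta)) is the
exact marginal establishment probability of one attempt. Both reductions are
exact in distribution (binomial thinning); they are what makes 10⁶-step
scenarios run in seconds. Establishment counts do not depend on the state,
so they are pre-drawn in chunks of 4096 steps and re-drawn whenever guild
sizes change. `step_guild` and `draw_established_inventions` retain the
explicit attempt-level sampling (per-attempt s draws) as a readable
reference path; the suite checks the two routes agree, including against a
per-tool Bernoulli simulator built on an unrelated random generator.

Runs start from an empty repertoire, record the state every `record_every`
steps (entry 0 is the initial state), and use a single PCG64 stream seeded
from the mandatory config seed, making trajectories reproducible
byte-for-byte. A guild of size 0 invents nothing and loses its entire
repertoire (no one remains to maintain the culture); this is flagged once in
the event log.

Two variants of the capacity assumption are available: the default
`capacity_exponent` (loss × c^t) and `hard_cap`, where loss stays p_loss/N
but the repertoire cannot exceed a user-supplied `t_max` — establishments
that would push past the cap are discarded. `t_max` has no default: it
represents an individual's knowledge capacity and is scenario-specific.

## Scenario engine

Events apply in a fixed order within each step — demography → environment
switch → bottleneck → guild updates → collapse check — chosen for
determinism; at the event probabilities used the ordering is statistically
invisible. Guild sizes are equal at initialization and all events preserve
exchangeability:

- **Demography.** With probability `change_prob` the total size moves by
  ±`delta` (direction equiprobable), rejected if it would exit `bounds` or
  drop a guild below one member; the delta is split equally across living
  guilds with any remainder assigned round-robin by guild index.
- **Environment.** Two environments; switches with probability
  `switch_prob`. Tools invented while environment e prevails are specific to
  e with probability 0.9 (the rest are universal and never penalized);
  mismatched specific tools are lost 10× faster.
- **Bottleneck.** Each living guild is resized to `new_total_size / g`
  (equal representation). Repertoires are not truncated at the moment of
  contraction — the intensified 1/N loss at the smaller sizes does the
  damage, which is how the model's loss structure propagates demography into
  culture.
- **Collapse.** A guild whose repertoire falls more than
  `loss_fraction_threshold` below its maximum within the trailing
  `window_steps` dissolves: its tools are lost, its members split equally
  among survivors (round-robin remainder), total population size conserved
  exactly. If every guild would collapse at once, the largest-repertoire
  guild (lowest index on ties) survives. Threshold and window have no
  defaults — they are scenario parameters, and `enabled_after_step` can
  defer the rule past the initial growth transient, during which small
  repertoires trivially halve.

Steady-state statistics use the window [200,000, 500,000) of 500,000-step
runs; bottleneck retention compares the pre-event steady-state window mean
with a post-event window that starts after a 200,000-step re-equilibration
lag and spans 300,000 steps (both configurable). Variance is the
population (divide-by-n) convention, indistinguishable from the sample
variance at 3·10⁵ records.

## What the simulations do and do not show

The generator's defaults are the published study conditions (rates above,
populations of 10–2500, 0.5–2·10⁶ steps, fluctuation bounds 600–1000,
bottlenecks to 200). The model deliberately omits: cultural transmission
between individuals (absorbed into 1 − s), tool interdependence and
recombination, inter-guild sharing, unequal guild sizes, guild-biased
bottleneck sampling, fitness feedback on demography, and more than two
environments. Passing tests therefore validate the stochastic process and
its analytic equilibrium, not the realism of any particular ethnographic
setting.

## Numerical choices and scaled test protocols

- Lambert W via `scipy.special.lambertw` (principal branch), cross-checked
  in the suite against an independent bisection root-finder to 6
  significant digits; the balance-equation residual of returned equilibria
  is below 1e-9 relative.
- Integer thresholds (the subdivision crossover) are located by exponential
  scan + bisection and verified at both boundary integers.
- Small-guild long-run behaviour is pinned to the exact stationary
  distribution of the truncated repertoire birth–death chain (births
  Binomial(N, p_inv·q), deaths Binomial(t, loss)), with agreement asserted
  within three batch-means standard errors (batching absorbs the ~5·10³-step
  autocorrelation time of small-guild runs).
- Qualitative multi-seed properties (specialization losing under switching
  and bottlenecks, fluctuation range shrinking with guild size) run on
  scaled protocols — 300,000–450,000 steps with proportionally earlier
  windows and 10 seeds — chosen so each property still has a decisive margin
  at those sizes.
- Published retention percentages are whole-percent figure readings, so
  reproduction tests use max(5%, 1 percentage point) bands; stochastic
  window means use max(5%, 3 batch-means SE).

## Known limitations

- The continuous-analytic optimal guild count can differ by one from a
  simulated optimum where the total-repertoire curve is nearly flat in g
  (e.g. at N = 2500 the analytic argmax is 11 with g = 10 within a fraction
  of a percent); no exact value is asserted there.
- Trajectory CSVs store per-guild repertoires, not per-class counts; reading
  a trajectory back preserves all summary statistics but collapses class
  structure into the universal class.
- The collapse rule reacts to relative crashes, so it can fire during the
  initial growth phase when peaks are only a few tools; use
  `enabled_after_step` to restrict it to the steady state if that is not
  intended.
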