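"""Closed-form equilibrium analysis: how repertoire size scales with
population size and subdivision into guilds.

Runs in well under a second; everything here is analytic (Lambert W)."""

from guildsim import (
    doubling_threshold,
    equilibrium_repertoire,
    guild_advantage_threshold,
    optimal_guild_count,
    total_equilibrium,
)

print("Equilibrium repertoire t*(N) of a non-specialized population:")
for n in (10, 20, 100, 1000, 10_000, 20_000):
    print(f"  N = {n:>6}: t* = {equilibrium_repertoire(n):9.2f}")
print(
    "Doubling 10 -> 20 quadruples the repertoire; doubling 10,000 -> 20,000 "
    f"multiplies it by only {equilibrium_repertoire(20_000)/equilibrium_repertoire(10_000):.2f}."
)

n_star = doubling_threshold()
print(f"\nDoubling N less than doubles t* above N* = {n_star:.1f} individuals,")
print("so beyond that size a population of 2N does better as two guilds of N.")

print("\nTotal repertoire of 1000 individuals split into g guilds:")
for g in (1, 2, 4, 10, 20):
    print(f"  g = {g:>2}: total = {total_equilibrium(1000, g):8.1f}")
g_best = optimal_guild_count(1000, g_max=50)
print(f"The repertoire-maximizing number of guilds for N = 1000 is {g_best}.")

n_cross = guild_advantage_threshold(10)
print(
    f"\nA 10-guild population only beats a non-specialized one above "
    f"N = {n_cross} individuals."
)
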