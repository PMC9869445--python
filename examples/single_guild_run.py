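"""Simulate one guild to its stochastic steady state and compare the
long-run window mean against the analytic equilibrium.

A guild of 100 at default rates plateaus near t* = 351.7 tools; the
simulated window mean lands within a couple of percent of that. Takes a
few seconds."""

import numpy as np

from guildsim import equilibrium_repertoire, run_guild

SIZE = 100
series = run_guild(SIZE, n_steps=300_000, record_every=1, seed=42)
window = series[150_000:]

print(f"Guild of {SIZE}, 300,000 steps (window: last 150,000 steps)")
print(f"  simulated mean : {window.mean():8.2f}")
print(f"  variance       : {window.var():8.2f}")
print(f"  min / max      : {window.min()} / {window.max()}")
print(f"  analytic t*    : {equilibrium_repertoire(SIZE):8.2f}")
rel_range = (window.max() - window.min()) / window.max()
print(f"  relative fluctuation range: {100 * rel_range:.1f}%")
print(
    "\nSmall guilds fluctuate much harder: a guild of 10 routinely hits "
    "0 tools, a 100% relative range."
)
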