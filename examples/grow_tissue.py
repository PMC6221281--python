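"""Grow one epithelium from a single 7-sided cell and watch the census.

Runs a single 12-cycle experiment under the Random division order with
the OrthRandN/evensplit cleavage strategy and prints the polygon-class
census at cycles 9-12.  Proportions should settle into the standard
hexagon-dominated shape (mode at k = 6, mean side count just below 6).
"""

from epitopo import SimulationConfig, StrategyConfig, run_experiment

config = SimulationConfig(
    strategy=StrategyConfig("OrthRandN", "evensplit", "Random"),
    initial_sides=7,
    cycles=12,
    batch_size=1,
    seed=42,
)
result = run_experiment(config, config.seed)

for cycle, census in sorted(result.snapshots.items()):
    props = ", ".join(f"k={k}: {p:.3f}" for k, p in sorted(census.proportions.items()))
    print(f"cycle {cycle:2d}  ({census.total_real_cells:5d} cells)  {props}")
print(f"final mean side count: {result.final_mean_sides:.4f} (< 6 by Euler bookkeeping)")
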