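"""Score two strategies against a reference distribution and rank them.

Builds a synthetic hexagon-dominated reference (stand-in for an
empirical polygon-class table), runs two small batches under different
cleavage strategies, computes both chi-square sheets for each, and
ranks the settings on the sheet-2 score (simulation denominators).
Smaller is better; rotNorm should beat the uniform-random side2 choice.
"""

from epitopo import (
    EmpiricalReference,
    SimulationConfig,
    StrategyConfig,
    compare_to_reference,
    rank_settings,
    run_batch,
    setting_name,
)

reference = EmpiricalReference(
    "SyntheticA", {4: 0.03, 5: 0.27, 6: 0.45, 7: 0.19, 8: 0.05, 9: 0.01}
)

strategies = [
    StrategyConfig("OrthRandN", "rotNorm", "Random", stdbeta=0.05),
    StrategyConfig("RandN", "random", "Random"),
]

results = []
for strategy in strategies:
    config = SimulationConfig(
        strategy=strategy, cycles=9, batch_size=20, snapshot_cycles={9}, seed=3
    )
    batch = run_batch(config)
    pooled = batch.pooled[9]
    results.append(compare_to_reference(pooled, reference, setting_name(config)))

print(f"fit against {reference.organism} (chi-square, smaller = better):")
for rank, r in enumerate(rank_settings(results, reference.organism), start=1):
    print(f"  {rank}. {r.setting:<40s} sheet1={r.sheet1:.5f}  sheet2={r.sheet2:.5f}")
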