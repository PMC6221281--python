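"""Seeded experiments, batches, and parameter sweeps.

An *experiment* grows a tissue from a single cell for a fixed number of
division cycles; every real cell divides exactly once per cycle, so an
experiment that starts from one cell ends with ``2 ** cycles`` cells.
A *batch* is a set of independent experiments under one configuration
whose polygon-class censuses are pooled.  A *sweep* runs one batch per
configuration and writes each to a folder named after its setting.

RNG discipline: the batch seed spawns one independent stream per
experiment (``numpy.random.SeedSequence``); within an experiment a
single stream is consumed in a fixed order — the division-order draw
for the cycle, then per dividing cell the side1 draw(s) followed by the
side2 draw — so any run can be replayed bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .fitstats import PolygonDistribution, polygon_distribution
from .strategies import StrategyConfig, choose_side1, choose_side2, make_division_order
from .tissue import TissueState, divide_cell, init_tissue

__all__ = [
    "SimulationConfig",
    "ExperimentResult",
    "BatchResult",
    "run_experiment",
    "run_batch",
    "sweep",
    "setting_name",
]


def _default_snapshots(cycles: int) -> frozenset[int]:
    return frozenset(c for c in (9, 10, 11, cycles) if 0 <= c <= cycles)


@dataclass(frozen=True)
class SimulationConfig:
    """All user-settable knobs of a batch of simulations."""

    strategy: StrategyConfig = field(default_factory=StrategyConfig)
    initial_sides: int = 7
    cycles: int = 12
    batch_size: int = 100
    snapshot_cycles: frozenset[int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.initial_sides < 4:
            raise ValueError("initial_sides must be >= 4")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        snaps = self.snapshot_cycles
        if snaps is None:
            snaps = _default_snapshots(self.cycles)
        else:
            snaps = frozenset(int(c) for c in snaps)
            if not snaps or min(snaps) < 0 or max(snaps) > self.cycles:
                raise ValueError(
                    f"snapshot_cycles must be within 0..{self.cycles}, got {sorted(snaps)}"
                )
        object.__setattr__(self, "snapshot_cycles", snaps)


@dataclass
class ExperimentResult:
    """Outcome of one experiment: snapshots and a final-state summary."""

    experiment_index: int
    snapshots: dict[int, PolygonDistribution]
    final_cells: int
    final_mean_sides: float
    n_divisions: int


@dataclass
class BatchResult:
    """Outcome of a batch: per-experiment results and pooled censuses."""

    config: SimulationConfig
    experiments: list[ExperimentResult]
    pooled: dict[int, PolygonDistribution]


def run_experiment(
    config: SimulationConfig,
    rng: np.random.Generator | int | np.random.SeedSequence,
    experiment_index: int = 0,
    return_tissue: bool = False,
):
    """Run one experiment and collect snapshots.

    ``rng`` may be a Generator, a seed, or a SeedSequence.  With
    ``return_tissue`` the final :class:`TissueState` (including the full
    division log) is returned alongside the result.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg = config.strategy
    t = init_tissue(config.initial_sides)
    snapshots: dict[int, PolygonDistribution] = {}
    if 0 in config.snapshot_cycles:
        snapshots[0] = polygon_distribution(t)
    previous_order: list[int] | None = None
    for cycle in range(1, config.cycles + 1):
        order = make_division_order(t, cfg, previous_order, rng)
        t.current_order = order
        for m in order:
            s1 = choose_side1(t, m, cfg, rng)
            i = len(t.cells[m].neighbors)
            u = choose_side2(i, cfg, rng)
            divide_cell(t, m, s1, u, cycle=cycle)
        t.cycle_index = cycle
        previous_order = order
        if cycle in config.snapshot_cycles:
            snapshots[cycle] = polygon_distribution(t)
    sides = [c.sides for c in t.real_cells()]
    result = ExperimentResult(
        experiment_index=experiment_index,
        snapshots=snapshots,
        final_cells=len(sides),
        final_mean_sides=float(np.mean(sides)),
        n_divisions=len(t.division_log),
    )
    if return_tissue:
        return result, t
    return result


def run_batch(config: SimulationConfig) -> BatchResult:
    """Run ``batch_size`` independent experiments and pool the censuses.

    Per-experiment streams are spawned from ``config.seed``, so the
    result is reproducible and independent of execution order.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.batch_size)
    experiments = [
        run_experiment(config, child, experiment_index=j)
        for j, child in enumerate(children)
    ]
    pooled: dict[int, PolygonDistribution] = {}
    for cycle in sorted(config.snapshot_cycles):
        pooled[cycle] = PolygonDistribution.pool(
            [e.snapshots[cycle] for e in experiments]
        )
    return BatchResult(config=config, experiments=experiments, pooled=pooled)


def _fmt_param(x: float | None) -> str:
    return "*" if x is None else format(x, "g")


def setting_name(config: SimulationConfig) -> str:
    """Folder-name descriptor ``order-choice1-choice2[-param1-param2]``.

    ``param1`` is the side1 parameter (smp), ``param2`` the side2
    parameter (probB or stdbeta); ``*`` marks a parameter the selected
    option does not use.  Both are omitted when neither option takes a
    parameter.
    """
    s = config.strategy
    p1 = s.smp if s.choice1 == "OrthSmpN" else None
    p2 = s.probB if s.choice2 == "Even-Binomial" else (
        s.stdbeta if s.choice2 in ("rotNorm", "rotTanNorm") else None
    )
    base = f"{s.order}-{s.choice1}-{s.choice2}"
    if p1 is None and p2 is None:
        return base
    return f"{base}-{_fmt_param(p1)}-{_fmt_param(p2)}"


def sweep(configs, output_root) -> dict[str, BatchResult]:
    """Run one batch per configuration, writing each to its own folder."""
    from . import io as _io

    output_root = Path(output_root)
    output_root.mkdir(parents=True, exist_ok=True)
    names = [setting_name(c) for c in configs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate setting names in sweep: {sorted(dupes)}")
    results: dict[str, BatchResult] = {}
    for name, config in zip(names, configs):
        batch = run_batch(config)
        _io.write_batch_result(batch, output_root / name)
        results[name] = batch
    return results
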