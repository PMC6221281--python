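"""Independent planar-coordinate oracle for the division mechanics.

The main simulator stores a rotation system (cyclic neighbor lists).
This module validates it with an entirely different representation:
every real cell is an explicit counterclockwise list of *vertex* labels
of its polygon.  A division inserts two new vertices — the midpoints of
the cut edges — and the new cleavage edge, and splits the mother's
vertex list into the two daughters' lists; a cell across a cut edge has
the midpoint inserted into its own list (it gains one side).  Side
counts are read off as list lengths, and two cells are adjacent exactly
when their lists share an edge (a consecutive vertex pair).

The oracle consumes the identical strategy-decision stream as the main
simulator: it replays the recorded division log (mother, side1
position, offset ``u``, daughter ids), so any disagreement in the
resulting side counts or adjacency isolates a defect in the neighbor
surgery of one of the two implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitstats import PolygonDistribution
from .simulator import SimulationConfig, run_experiment
from .tissue import DivisionEvent

__all__ = ["PlanarTissue", "OracleResult", "oracle_simulate"]


@dataclass
class PlanarTissue:
    """Cells as counterclockwise vertex-label lists in the plane."""

    cells: dict[int, list[int]] = field(default_factory=dict)
    _next_vertex: int = 0

    @classmethod
    def initial(cls, cell_id: int, k: int) -> "PlanarTissue":
        if k < 4:
            raise ValueError(f"initial side count must be >= 4, got {k}")
        t = cls()
        t.cells[cell_id] = list(range(k))
        t._next_vertex = k
        return t

    def new_vertex(self) -> int:
        v = self._next_vertex
        self._next_vertex += 1
        return v

    def side_counts(self) -> dict[int, int]:
        return {cid: len(vs) for cid, vs in self.cells.items()}

    def census(self) -> PolygonDistribution:
        counts: dict[int, int] = {}
        for vs in self.cells.values():
            counts[len(vs)] = counts.get(len(vs), 0) + 1
        return PolygonDistribution(counts)

    def adjacency(self) -> set[frozenset[int]]:
        """Pairs of cells sharing an edge (a consecutive vertex pair)."""
        owners: dict[frozenset[int], list[int]] = {}
        for cid, vs in self.cells.items():
            for j, v in enumerate(vs):
                owners.setdefault(frozenset((v, vs[(j + 1) % len(vs)])), []).append(cid)
        pairs: set[frozenset[int]] = set()
        for cids in owners.values():
            if len(cids) == 2:
                pairs.add(frozenset(cids))
            elif len(cids) > 2:
                raise AssertionError(f"edge shared by more than two cells: {cids}")
        return pairs

    def _insert_midpoint(self, a: int, b: int, p: int, exclude: int) -> None:
        """Insert vertex ``p`` into the cell (other than ``exclude``)
        whose boundary traverses the edge b -> a; no-op on a boundary edge."""
        for cid, vs in self.cells.items():
            if cid == exclude:
                continue
            n = len(vs)
            for j, v in enumerate(vs):
                if v == b and vs[(j + 1) % n] == a:
                    vs.insert(j + 1, p)
                    return
        # No other owner: the cut edge lies on the tissue boundary.

    def apply_division(self, ev: DivisionEvent) -> None:
        """Replay one logged division on the planar representation."""
        vs = self.cells[ev.mother_id]
        i = len(vs)
        if i != ev.mother_sides:
            raise AssertionError(
                f"cell {ev.mother_id}: planar side count {i} != logged {ev.mother_sides}"
            )
        if not 2 <= ev.u <= i - 2:
            raise AssertionError(f"illegal offset u={ev.u} for {i}-sided cell")
        # Rotate so side1 is the edge (r[0], r[1]).
        r = [vs[(ev.side1_position + j) % i] for j in range(i)]
        p = self.new_vertex()  # midpoint of side1's edge
        q = self.new_vertex()  # midpoint of side2's edge
        # Daughter A: p, the arc r[1]..r[u], then q, closed by the new edge q->p.
        self.cells[ev.daughterA_id] = [p] + r[1 : ev.u + 1] + [q]
        # Daughter B: q, the arc r[u+1]..r[i-1], r[0], then p, closed by p->q.
        self.cells[ev.daughterB_id] = [q] + r[ev.u + 1 :] + [r[0], p]
        # Neighbors across the cut edges gain the midpoints.
        self._insert_midpoint(r[0], r[1], p, exclude=ev.daughterA_id)
        self._insert_midpoint(r[ev.u], r[ev.u + 1], q, exclude=ev.daughterA_id)


@dataclass
class OracleResult:
    """Per-cycle censuses plus the final planar state."""

    censuses: list[PolygonDistribution]
    side_counts: dict[int, int]
    adjacency: set[frozenset[int]]


def oracle_simulate(
    config: SimulationConfig,
    rng: np.random.Generator | int | np.random.SeedSequence,
) -> OracleResult:
    """Run the main simulator, then replay its division log planarly.

    Returns the oracle's own censuses (index c = after cycle c), final
    side counts and final adjacency, all computed from the vertex-list
    representation alone.  Intended for small configurations (about six
    cycles or fewer).
    """
    result, tissue = run_experiment(config, rng, return_tissue=True)
    first_real = 0  # init_tissue allocates the initial real cell first
    planar = PlanarTissue.initial(first_real, config.initial_sides)
    censuses = [planar.census()]
    by_cycle: dict[int, list[DivisionEvent]] = {}
    for ev in tissue.division_log:
        by_cycle.setdefault(ev.cycle, []).append(ev)
    for cycle in range(1, config.cycles + 1):
        for ev in by_cycle.get(cycle, []):
            planar.apply_division(ev)
        censuses.append(planar.census())
    return OracleResult(
        censuses=censuses,
        side_counts=planar.side_counts(),
        adjacency=planar.adjacency(),
    )
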