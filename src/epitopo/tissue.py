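"""Topological representation of a growing epithelial monolayer.

A tissue is a planar cell-adjacency structure.  Each *real* cell is a
k-sided polygon represented purely combinatorially by the cyclic
(counterclockwise) sequence of its neighbors — a rotation system.  Each
boundary edge of the tissue borders exactly one *fake* cell, a
bookkeeping entity with side count 0 that stands in for the exterior
and never divides.

The single legal modification is cell division: the cleavage plane
intersects two non-adjacent edges of the mother, creating two trivalent
vertices and one new shared edge.  This precludes tetravalent vertices
and 3-sided cells, so every real cell has at least 4 sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "CellRecord",
    "DivisionEvent",
    "TissueState",
    "init_tissue",
    "divide_cell",
    "check_invariants",
    "tissue_to_json",
    "tissue_from_json",
]

REAL = "real"
FAKE = "fake"


@dataclass(slots=True)
class CellRecord:
    """One cell of the tissue.

    ``neighbors`` is the cyclic counterclockwise sequence of neighbor
    ids and is defined only for real cells (``None`` for fake cells).
    ``sister_id``/``mother_id`` record lineage; ``birth_sides`` is the
    side count at the moment of creation; exactly one daughter of each
    division keeps the mother's id (``retained_mother_label``).
    """

    id: int
    kind: str
    neighbors: list[int] | None
    sister_id: int | None = None
    mother_id: int | None = None
    birth_sides: int = 0
    born_cycle: int = 0
    retained_mother_label: bool = False

    @property
    def sides(self) -> int:
        """Side count: number of neighbors for real cells, 0 for fake."""
        return len(self.neighbors) if self.neighbors is not None else 0


@dataclass(slots=True)
class DivisionEvent:
    """Log entry for one division.

    ``u`` is the offset of side2 counterclockwise from side1 in the
    mother's cyclic neighbor list; legal values are ``2 <= u <= i - 2``
    for an ``i``-sided mother.  ``daughterA_id`` equals the mother's id
    (that daughter retains the label).
    """

    cycle: int
    mother_id: int
    mother_sides: int
    side1_position: int
    side1_neighbor_id: int
    u: int
    side2_neighbor_id: int
    daughterA_id: int
    daughterB_id: int
    side1_boundary: bool
    side2_boundary: bool


@dataclass
class TissueState:
    """The tissue: cells, completed-cycle counter, division log, order."""

    cells: dict[int, CellRecord] = field(default_factory=dict)
    cycle_index: int = 0
    division_log: list[DivisionEvent] = field(default_factory=list)
    current_order: list[int] = field(default_factory=list)
    initial_sides: int | None = None
    _next_id: int = 0

    def new_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def real_ids(self) -> list[int]:
        return [c.id for c in self.cells.values() if c.kind == REAL]

    def real_cells(self) -> Iterator[CellRecord]:
        return (c for c in self.cells.values() if c.kind == REAL)

    def n_real(self) -> int:
        return sum(1 for c in self.cells.values() if c.kind == REAL)

    def side_counts(self) -> dict[int, int]:
        """Map real-cell id -> current side count."""
        return {c.id: len(c.neighbors) for c in self.real_cells()}

    def adjacency(self) -> set[frozenset[int]]:
        """Unordered real-real adjacent pairs."""
        pairs: set[frozenset[int]] = set()
        for c in self.real_cells():
            for nb in c.neighbors:
                if self.cells[nb].kind == REAL:
                    pairs.add(frozenset((c.id, nb)))
        return pairs


def init_tissue(k: int) -> TissueState:
    """Create a tissue consisting of a single real ``k``-sided cell.

    Every edge of the initial cell is a boundary edge, so ``k`` fake
    cells are created, one per edge.  ``k`` must be at least 4: the
    model precludes 3-sided cells.
    """
    if not isinstance(k, int) or isinstance(k, bool):
        raise TypeError(f"initial side count must be an integer, got {k!r}")
    if k < 4:
        raise ValueError(
            f"initial side count must be >= 4 (3-sided cells are precluded), got {k}"
        )
    t = TissueState(initial_sides=k)
    cid = t.new_id()
    fake_ids = [t.new_id() for _ in range(k)]
    t.cells[cid] = CellRecord(
        id=cid, kind=REAL, neighbors=list(fake_ids), birth_sides=k, born_cycle=0
    )
    for fid in fake_ids:
        t.cells[fid] = CellRecord(id=fid, kind=FAKE, neighbors=None, born_cycle=0)
    t.current_order = [cid]
    return t


def divide_cell(
    t: TissueState,
    m: int,
    side1_position: int,
    u: int,
    cycle: int | None = None,
) -> DivisionEvent:
    """Divide real cell ``m`` through the edges at ``side1_position`` and
    ``u`` steps counterclockwise from it.

    The mother with ``i`` sides is replaced by daughters with ``u + 2``
    and ``i - u + 2`` sides (sum ``i + 4``).  The daughters are mutual
    sisters sharing the new edge.  Each cut edge splits in two: a real
    neighbor across a cut edge gains one side and becomes adjacent to
    both daughters; a boundary (fake-cell) cut edge keeps its fake cell
    on daughter A's segment and a fresh fake cell is minted for
    daughter B's segment.  Daughter A — the arc from side1
    counterclockwise to side2 — keeps the mother's id.
    """
    rec = t.cells.get(m)
    if rec is None:
        raise KeyError(f"unknown cell id {m}")
    if rec.kind != REAL:
        raise ValueError(f"cell {m} is fake and cannot divide")
    nb = rec.neighbors
    i = len(nb)
    if not 0 <= side1_position < i:
        raise ValueError(f"side1_position {side1_position} out of range for {i}-sided cell")
    if not 2 <= u <= i - 2:
        raise ValueError(
            f"u={u} illegal for {i}-sided cell: side2 must be non-adjacent to side1 "
            f"(2 <= u <= {i - 2})"
        )
    if cycle is None:
        cycle = t.cycle_index + 1

    # Rotate so side1 is at offset 0.
    r = [nb[(side1_position + j) % i] for j in range(i)]
    nb0, nbu = r[0], r[u]
    nb0_fake = t.cells[nb0].kind == FAKE
    nbu_fake = t.cells[nbu].kind == FAKE

    b_id = t.new_id()

    # Which id borders each daughter across the two halves of each cut edge.
    if nb0_fake:
        nb0_a, nb0_b = nb0, t.new_id()
        t.cells[nb0_b] = CellRecord(id=nb0_b, kind=FAKE, neighbors=None, born_cycle=cycle)
    else:
        nb0_a = nb0_b = nb0
    if nbu_fake:
        nbu_a, nbu_b = nbu, t.new_id()
        t.cells[nbu_b] = CellRecord(id=nbu_b, kind=FAKE, neighbors=None, born_cycle=cycle)
    else:
        nbu_a = nbu_b = nbu

    # Daughter A: half of side1 edge, the arc side1 -> side2 (exclusive),
    # half of side2 edge, then the new shared edge; keeps the mother's id.
    a_neighbors = [nb0_a] + r[1:u] + [nbu_a, b_id]
    # Daughter B: the complementary arc, then the new shared edge.
    b_neighbors = [nbu_b] + r[u + 1 :] + [nb0_b, m]

    t.cells[m] = CellRecord(
        id=m,
        kind=REAL,
        neighbors=a_neighbors,
        sister_id=b_id,
        mother_id=m,
        birth_sides=u + 2,
        born_cycle=cycle,
        retained_mother_label=True,
    )
    t.cells[b_id] = CellRecord(
        id=b_id,
        kind=REAL,
        neighbors=b_neighbors,
        sister_id=m,
        mother_id=m,
        birth_sides=i - u + 2,
        born_cycle=cycle,
        retained_mother_label=False,
    )

    # Non-cut neighbors on daughter B's arc now border B, not the mother;
    # rename the mother's id to B's in their lists (daughter A keeps the
    # mother's id, so its arc needs no renaming).
    for x in r[u + 1 :]:
        xrec = t.cells[x]
        if xrec.kind == REAL:
            xrec.neighbors[xrec.neighbors.index(m)] = b_id

    # A real neighbor across a cut edge gains one side: its single edge to
    # the mother becomes two edges, one to each daughter.  Traversed in the
    # neighbor's own counterclockwise order, the side1 neighbor sees
    # daughter A first, the side2 neighbor sees daughter B first.
    if not nb0_fake:
        xs = t.cells[nb0].neighbors
        j = xs.index(m)
        xs[j : j + 1] = [m, b_id]
    if not nbu_fake:
        ys = t.cells[nbu].neighbors
        j = ys.index(m)
        ys[j : j + 1] = [b_id, m]

    event = DivisionEvent(
        cycle=cycle,
        mother_id=m,
        mother_sides=i,
        side1_position=side1_position,
        side1_neighbor_id=nb0,
        u=u,
        side2_neighbor_id=nbu,
        daughterA_id=m,
        daughterB_id=b_id,
        side1_boundary=nb0_fake,
        side2_boundary=nbu_fake,
    )
    t.division_log.append(event)
    return event


def check_invariants(t: TissueState) -> list[str]:
    """Return a list of invariant violations (empty list = pass).

    Checks adjacency symmetry, the minimum side count of 4, that each
    fake cell is referenced by exactly one real cell, sister-pair label
    flags, and — for tissues grown from one cell — that the real-cell
    count is ``2 ** cycle_index``.
    """
    violations: list[str] = []
    fake_refs: dict[int, int] = {}
    for c in t.cells.values():
        if c.kind == FAKE:
            if c.neighbors is not None:
                violations.append(f"fake cell {c.id} has a neighbor list")
            continue
        nbs = c.neighbors
        if nbs is None:
            violations.append(f"real cell {c.id} has no neighbor list")
            continue
        if len(nbs) < 4:
            violations.append(f"real cell {c.id} has {len(nbs)} sides (< 4)")
        if len(set(nbs)) != len(nbs):
            violations.append(f"real cell {c.id} has repeated neighbor ids")
        for nb in nbs:
            other = t.cells.get(nb)
            if other is None:
                violations.append(f"real cell {c.id} references unknown id {nb}")
                continue
            if other.kind == FAKE:
                fake_refs[nb] = fake_refs.get(nb, 0) + 1
            elif c.id not in other.neighbors:
                violations.append(
                    f"adjacency asymmetry: {nb} in neighbors of {c.id} but not conversely"
                )
    for fid, c in ((c.id, c) for c in t.cells.values() if c.kind == FAKE):
        n = fake_refs.get(fid, 0)
        if n != 1:
            violations.append(f"fake cell {fid} referenced by {n} real cells (expected 1)")
    # Sister pairs: exactly one of each pair retains the mother's label.
    seen: set[frozenset[int]] = set()
    for c in t.real_cells():
        s = c.sister_id
        if s is None:
            continue
        pair = frozenset((c.id, s))
        if pair in seen:
            continue
        seen.add(pair)
        other = t.cells.get(s)
        if other is None or other.kind != REAL:
            # The sister may have divided since; its record was replaced.
            continue
        if other.sister_id == c.id:
            flags = (c.retained_mother_label, other.retained_mother_label)
            if sum(flags) != 1:
                violations.append(
                    f"sister pair ({c.id}, {s}) has retained-label flags {flags}"
                )
    if t.initial_sides is not None:
        actual = t.n_real()
        # Every division adds exactly one real cell.
        expected_from_log = 1 + len(t.division_log)
        if actual != expected_from_log:
            violations.append(
                f"real-cell count {actual} != 1 + {len(t.division_log)} divisions"
            )
        # Doubling per completed cycle; skip mid-cycle states whose log
        # already contains divisions beyond cycle_index.
        mid_cycle = any(ev.cycle > t.cycle_index for ev in t.division_log)
        if not mid_cycle and actual != 2**t.cycle_index:
            violations.append(
                f"real-cell count {actual} != 2^{t.cycle_index} = {2**t.cycle_index}"
            )
    return violations


def tissue_to_json(t: TissueState) -> str:
    """Serialize a tissue to JSON (debugging and fixtures)."""
    payload = {
        "cycle_index": t.cycle_index,
        "initial_sides": t.initial_sides,
        "next_id": t._next_id,
        "current_order": list(t.current_order),
        "division_log": [
            {
                "cycle": ev.cycle,
                "mother_id": ev.mother_id,
                "mother_sides": ev.mother_sides,
                "side1_position": ev.side1_position,
                "side1_neighbor_id": ev.side1_neighbor_id,
                "u": ev.u,
                "side2_neighbor_id": ev.side2_neighbor_id,
                "daughterA_id": ev.daughterA_id,
                "daughterB_id": ev.daughterB_id,
                "side1_boundary": ev.side1_boundary,
                "side2_boundary": ev.side2_boundary,
            }
            for ev in t.division_log
        ],
        "cells": [
            {
                "id": c.id,
                "kind": c.kind,
                "neighbors": c.neighbors,
                "sister_id": c.sister_id,
                "mother_id": c.mother_id,
                "birth_sides": c.birth_sides,
                "born_cycle": c.born_cycle,
                "retained_mother_label": c.retained_mother_label,
            }
            for c in t.cells.values()
        ],
    }
    return json.dumps(payload, indent=1)


def tissue_from_json(s: str) -> TissueState:
    payload = json.loads(s)
    t = TissueState(
        cycle_index=payload["cycle_index"],
        initial_sides=payload["initial_sides"],
        current_order=list(payload["current_order"]),
    )
    t._next_id = payload["next_id"]
    t.division_log = [DivisionEvent(**ev) for ev in payload.get("division_log", [])]
    for c in payload["cells"]:
        t.cells[c["id"]] = CellRecord(
            id=c["id"],
            kind=c["kind"],
            neighbors=list(c["neighbors"]) if c["neighbors"] is not None else None,
            sister_id=c["sister_id"],
            mother_id=c["mother_id"],
            birth_sides=c["birth_sides"],
            born_cycle=c["born_cycle"],
            retained_mother_label=c["retained_mother_label"],
        )
    return t
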