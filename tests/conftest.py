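"""Shared fixtures and hand-built tissue states for strategy tests."""

from __future__ import annotations

import numpy as np
import pytest

from epitopo.tissue import FAKE, REAL, CellRecord, TissueState


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_niece_scenario(
    sides_a: int,
    sides_b: int,
    born_a: int = 4,
    born_b: int = 4,
) -> tuple[TissueState, int, int, int]:
    """A cell ``m`` whose sister has already divided into two nieces.

    Niece A (id 2) retained the sister's label; niece B (id 5) carries a
    new id.  ``m`` borders both nieces, so the Orth* sub-rules apply.
    Neighbor lists of the nieces are padded with fake ids to give them
    the requested current side counts; only the fields read by
    ``choose_side1`` are populated.  Returns (tissue, m_id, pos_of_A,
    pos_of_B).
    """
    t = TissueState()
    t.cycle_index = 1
    m_id, niece_a, niece_b = 1, 2, 5
    fake_pool = iter(range(100, 160))

    def fakes(n):
        out = [next(fake_pool) for _ in range(n)]
        for f in out:
            t.cells[f] = CellRecord(id=f, kind=FAKE, neighbors=None)
        return out

    m_nbs = [niece_a, niece_b] + fakes(2)
    t.cells[m_id] = CellRecord(
        id=m_id, kind=REAL, neighbors=m_nbs, sister_id=niece_a,
        mother_id=0, birth_sides=4, born_cycle=1,
    )
    t.cells[niece_a] = CellRecord(
        id=niece_a, kind=REAL, neighbors=[m_id] + fakes(sides_a - 1),
        sister_id=niece_b, mother_id=niece_a, birth_sides=born_a,
        born_cycle=2, retained_mother_label=True,
    )
    t.cells[niece_b] = CellRecord(
        id=niece_b, kind=REAL, neighbors=[m_id] + fakes(sides_b - 1),
        sister_id=niece_a, mother_id=niece_a, birth_sides=born_b,
        born_cycle=2, retained_mother_label=False,
    )
    t._next_id = 200
    return t, m_id, 0, 1


def make_plain_cells(n: int) -> TissueState:
    """``n`` disconnected real cells (order-generation tests only)."""
    t = TissueState()
    for cid in range(n):
        t.cells[cid] = CellRecord(
            id=cid, kind=REAL, neighbors=[1000 + cid] * 4, born_cycle=0
        )
    return t


def make_sister_pairs(n_pairs: int) -> tuple[TissueState, list[int]]:
    """``n_pairs`` sister pairs; returns (tissue, mother order).

    Pair j descends from mother id ``2*j`` (daughter A keeps that id,
    daughter B is ``2*j + 1``)."""
    t = TissueState()
    t.cycle_index = 1
    for j in range(n_pairs):
        a, b = 2 * j, 2 * j + 1
        t.cells[a] = CellRecord(
            id=a, kind=REAL, neighbors=[b] * 1, sister_id=b, mother_id=a,
            born_cycle=1, retained_mother_label=True,
        )
        t.cells[b] = CellRecord(
            id=b, kind=REAL, neighbors=[a] * 1, sister_id=a, mother_id=a,
            born_cycle=1, retained_mother_label=False,
        )
    return t, [2 * j for j in range(n_pairs)]


def four_sigma_band(p: float, n: int) -> float:
    """Half-width of the 4-sigma binomial band for a frequency estimate."""
    return 4.0 * np.sqrt(p * (1.0 - p) / n)
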