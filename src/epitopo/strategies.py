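"""Cleavage-plane strategies and division orders.

A division requires two choices: *side1*, the edge holding the first
endpoint of the cleavage plane, and *side2*, the edge holding the
second, identified by its counterclockwise offset ``u`` from side1
(legal ``u`` in ``{2, ..., i-2}`` for an ``i``-sided mother, so the two
edges are never adjacent).

side1 options
  ``LaN`` / ``SmN``   neighbor with the most / least edges (ties random)
  ``RandN``           uniform over all edges
  ``Orth*``           the edge shared with the sister cell; when the
                      sister has already divided, one of the two edges
                      shared with the nieces, selected by the sub-rule
                      encoded in the option name (fewer/more current
                      sides; fewer/more sides at birth; uniform; or
                      fewer-with-probability ``smp``)

side2 options
  ``evensplit``       as even a split as possible
  ``random``          uniform over non-adjacent edges
  ``unevensplit``     as uneven as possible
  ``Binomial``        u - 2 ~ Binomial(i - 4, 1/2)
  ``Even-Binomial``   mixture: evensplit w.p. 1 - probB, Binomial w.p. probB
  ``rotNorm``         cleavage plane rotated about the midpoint of side1
                      by an angle beta ~ Normal(0, stdbeta)
  ``rotTanNorm``      same rotation picture with tan(beta) ~ Normal(0, stdbeta)

Division orders: ``Random`` (uniform permutation each cycle) and
``Strict`` (sister pairs divide consecutively, pairs in their mothers'
realized order, within-pair order uniform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from .tissue import FAKE, REAL, TissueState

__all__ = [
    "CHOICE1_OPTIONS",
    "CHOICE2_OPTIONS",
    "ORDER_OPTIONS",
    "StrategyConfig",
    "Side2Pmf",
    "beta_interval_table",
    "side2_pmf",
    "choose_side1",
    "choose_side2",
    "make_division_order",
]

CHOICE1_OPTIONS = (
    "LaN",
    "SmN",
    "RandN",
    "OrthSmN",
    "OrthLaN",
    "OrthRandN",
    "OrthBornSmN",
    "OrthBornLaN",
    "OrthSmpN",
)
CHOICE2_OPTIONS = (
    "evensplit",
    "random",
    "unevensplit",
    "Binomial",
    "Even-Binomial",
    "rotTanNorm",
    "rotNorm",
)
ORDER_OPTIONS = ("Random", "Strict")

_C1 = {s.lower(): s for s in CHOICE1_OPTIONS}
_C2 = {s.lower(): s for s in CHOICE2_OPTIONS}
_ORD = {s.lower(): s for s in ORDER_OPTIONS}


def _canon(name: str, table: dict[str, str], what: str) -> str:
    try:
        return table[name.strip().lower()]
    except (KeyError, AttributeError):
        raise ValueError(
            f"unknown {what} option {name!r}; choose from {sorted(table.values())}"
        ) from None


@dataclass(frozen=True)
class StrategyConfig:
    """A complete strategy: side1 option, side2 option, division order,
    and the numeric parameters the selected options require.

    ``smp`` (probability, OrthSmpN only), ``probB`` (probability,
    Even-Binomial only) and ``stdbeta`` (positive std. dev. in radians
    of beta for rotNorm, of tan(beta) for rotTanNorm).

    ``extremes_include_fake`` controls whether LaN/SmN rank fake
    neighbors (side count 0) alongside real ones; by default they
    compare real neighbors only.
    """

    choice1: str = "RandN"
    choice2: str = "random"
    order: str = "Random"
    smp: float | None = None
    probB: float | None = None
    stdbeta: float | None = None
    extremes_include_fake: bool = False

    def __post_init__(self):
        object.__setattr__(self, "choice1", _canon(self.choice1, _C1, "choice1"))
        object.__setattr__(self, "choice2", _canon(self.choice2, _C2, "choice2"))
        object.__setattr__(self, "order", _canon(self.order, _ORD, "order"))
        if self.choice1 == "OrthSmpN":
            if self.smp is None or not 0.0 <= self.smp <= 1.0:
                raise ValueError("OrthSmpN requires smp in [0, 1]")
        if self.choice2 == "Even-Binomial":
            if self.probB is None or not 0.0 <= self.probB <= 1.0:
                raise ValueError("Even-Binomial requires probB in [0, 1]")
        if self.choice2 in ("rotNorm", "rotTanNorm"):
            if self.stdbeta is None or not self.stdbeta > 0:
                raise ValueError(f"{self.choice2} requires stdbeta > 0")


@dataclass(frozen=True)
class Side2Pmf:
    """Probability mass function over the side2 offset ``u``."""

    i: int
    us: tuple[int, ...]
    probabilities: tuple[float, ...]

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.us, self.probabilities))

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.probabilities)


@lru_cache(maxsize=None)
def beta_interval_table(i: int) -> dict[int, tuple[float, float]]:
    """Angular interval of each edge offset for the rotation strategies.

    The mother is modeled as a regular ``i``-gon.  The cleavage plane is
    anchored at the midpoint of side1 and rotated by an angle beta;
    beta = 0 is the ray through the centroid (the perfectly even split).
    Edge ``u`` (counterclockwise offset from side1, ``1 <= u <= i-1``)
    receives the interval of beta for which the rotated ray exits
    through it.  The intervals tile ``(-pi/2, pi/2)`` and are symmetric
    under ``u <-> i - u``.
    """
    if i < 4:
        raise ValueError(f"side count must be >= 4, got {i}")
    # Vertices of the unit-circumradius i-gon, counterclockwise; side1 is
    # the edge (v0, v1) with midpoint M; the interior direction is -M.
    angles = 2.0 * math.pi * np.arange(i + 1) / i
    vx, vy = np.cos(angles), np.sin(angles)
    mx, my = (vx[0] + vx[1]) / 2.0, (vy[0] + vy[1]) / 2.0
    d0x, d0y = -mx, -my
    # Signed angle from the centroid ray to the ray M -> v_j.
    wx, wy = vx - mx, vy - my
    psi = np.arctan2(d0x * wy - d0y * wx, d0x * wx + d0y * wy)
    # v_1 sits at -pi/2 and v_i (= v_0 traversed the long way) at +pi/2;
    # atan2 returns +pi/2 for v_0 = v_i already, but force the exact ends.
    psi[1] = -math.pi / 2.0
    psi[i] = math.pi / 2.0
    return {int(u): (float(psi[u]), float(psi[u + 1])) for u in range(1, i)}


def _evensplit_probs(i: int, us: np.ndarray) -> np.ndarray:
    p = np.zeros(len(us))
    if i % 2 == 0:
        p[us == i // 2] = 1.0
    else:
        p[us == (i - 1) // 2] = 0.5
        p[us == (i + 1) // 2] = 0.5
    return p


def _binomial_probs(i: int, us: np.ndarray) -> np.ndarray:
    # u - 2 successes in i - 4 fair trials.
    from scipy.stats import binom

    return binom.pmf(us - 2, i - 4, 0.5)


def _rot_probs(i: int, stdbeta: float, tan_normal: bool) -> np.ndarray:
    """Per-edge masses for rotNorm / rotTanNorm over u = 2..i-2.

    Interval masses come from the CDF of beta — Normal(0, stdbeta)
    truncated to (-pi/2, pi/2) for rotNorm (the truncation constant
    cancels on renormalization), or induced by tan(beta) ~ Normal(0,
    stdbeta) for rotTanNorm.  Mass on the two adjacent edges' intervals
    is removed and the remainder renormalized.
    """
    table = beta_interval_table(i)
    masses = []
    for u in range(2, i - 1):
        a, b = table[u]
        if tan_normal:
            lo = norm.cdf(math.tan(a) / stdbeta) if a > -math.pi / 2 else 0.0
            hi = norm.cdf(math.tan(b) / stdbeta) if b < math.pi / 2 else 1.0
        else:
            lo = norm.cdf(a / stdbeta)
            hi = norm.cdf(b / stdbeta)
        masses.append(hi - lo)
    p = np.asarray(masses, dtype=float)
    total = p.sum()
    if total <= 0.0:  # numerically degenerate; fall back to the even split
        return _evensplit_probs(i, np.arange(2, i - 1))
    return p / total


@lru_cache(maxsize=None)
def _side2_pmf_cached(
    i: int, choice2: str, probB: float | None, stdbeta: float | None
) -> Side2Pmf:
    us = np.arange(2, i - 1)
    if choice2 == "evensplit":
        p = _evensplit_probs(i, us)
    elif choice2 == "random":
        p = np.full(len(us), 1.0 / (i - 3))
    elif choice2 == "unevensplit":
        p = np.zeros(len(us))
        if i == 4:
            p[0] = 1.0
        else:
            p[us == 2] = 0.5
            p[us == i - 2] = 0.5
    elif choice2 == "Binomial":
        p = _binomial_probs(i, us)
    elif choice2 == "Even-Binomial":
        p = (1.0 - probB) * _evensplit_probs(i, us) + probB * _binomial_probs(i, us)
    elif choice2 == "rotNorm":
        p = _rot_probs(i, stdbeta, tan_normal=False)
    elif choice2 == "rotTanNorm":
        p = _rot_probs(i, stdbeta, tan_normal=True)
    else:  # pragma: no cover - canonicalized upstream
        raise ValueError(f"unknown choice2 option {choice2!r}")
    p = p / p.sum()
    return Side2Pmf(i=i, us=tuple(int(u) for u in us), probabilities=tuple(p))


def side2_pmf(i: int, cfg: StrategyConfig) -> Side2Pmf:
    """The distribution of the side2 offset ``u`` for an ``i``-sided mother."""
    if i < 4:
        raise ValueError(f"side count must be >= 4, got {i}")
    return _side2_pmf_cached(i, cfg.choice2, cfg.probB, cfg.stdbeta)


def choose_side2(i: int, cfg: StrategyConfig, rng: np.random.Generator) -> int:
    """Sample the side2 offset from ``side2_pmf(i, cfg)``."""
    pmf = side2_pmf(i, cfg)
    cum = pmf.cumulative()
    j = int(np.searchsorted(cum, rng.random(), side="right"))
    j = min(j, len(pmf.us) - 1)  # guard the cum[-1] < 1 rounding sliver
    return pmf.us[j]


def _pick_uniform(positions: list[int], rng: np.random.Generator) -> int:
    if len(positions) == 1:
        return positions[0]
    return positions[int(rng.integers(len(positions)))]


def choose_side1(
    t: TissueState, m: int, cfg: StrategyConfig, rng: np.random.Generator
) -> int:
    """Choose side1 for cell ``m``: a position in its cyclic neighbor list."""
    rec = t.cells[m]
    if rec.kind != REAL:
        raise ValueError(f"cell {m} is fake and cannot divide")
    nb = rec.neighbors
    i = len(nb)
    option = cfg.choice1

    if option == "RandN":
        return int(rng.integers(i))

    if option in ("LaN", "SmN"):
        if cfg.extremes_include_fake:
            candidates = list(range(i))
        else:
            candidates = [j for j in range(i) if t.cells[nb[j]].kind == REAL]
            if not candidates:  # only boundary edges: fall back to uniform
                return int(rng.integers(i))
        sides = [t.cells[nb[j]].sides for j in candidates]
        best = max(sides) if option == "LaN" else min(sides)
        tied = [j for j, s in zip(candidates, sides) if s == best]
        return _pick_uniform(tied, rng)

    # Orth* family: side1 is an edge shared with the sister or a niece.
    sister = rec.sister_id
    if sister is None:
        # Only the initial cell has no sister; choose uniformly.
        return int(rng.integers(i))
    srec = t.cells.get(sister)
    if srec is None:
        raise RuntimeError(f"cell {m} references missing sister {sister}")
    if srec.born_cycle == rec.born_cycle and srec.sister_id == m:
        # Sister has not divided yet this cycle: the shared edge is unique.
        return nb.index(sister)
    # Sister divided already: the record with the sister's id is the niece
    # that retained the label; its sister is the other niece.
    niece_a = sister  # retained_mother_label = True
    niece_b = srec.sister_id
    positions = {cid: j for j, cid in enumerate(nb) if cid in (niece_a, niece_b)}
    if not positions:
        raise RuntimeError(
            f"cell {m} shares no edge with sister {sister} or its daughters"
        )
    if len(positions) == 1:
        # The sister's cleavage plane did not cut the shared edge, so m
        # borders exactly one niece.
        return next(iter(positions.values()))

    a_rec, b_rec = t.cells[niece_a], t.cells[niece_b]
    sides_a, sides_b = a_rec.sides, b_rec.sides
    born_a, born_b = a_rec.birth_sides, b_rec.birth_sides

    def pos(cid: int) -> int:
        return positions[cid]

    if option == "OrthRandN":
        return pos(niece_a if rng.random() < 0.5 else niece_b)
    if option == "OrthSmN":
        if sides_a == sides_b:
            return pos(niece_a)  # tie: the niece that retained the label
        return pos(niece_a if sides_a < sides_b else niece_b)
    if option == "OrthLaN":
        if sides_a == sides_b:
            return pos(niece_b)  # tie: the niece with the new label
        return pos(niece_a if sides_a > sides_b else niece_b)
    if option == "OrthBornSmN":
        if born_a == born_b:
            return pos(niece_a)
        return pos(niece_a if born_a < born_b else niece_b)
    if option == "OrthBornLaN":
        if born_a == born_b:
            return pos(niece_b)
        return pos(niece_a if born_a > born_b else niece_b)
    if option == "OrthSmpN":
        take = rng.random() < cfg.smp
        if sides_a == sides_b:
            # tie: the label-retaining niece with probability smp
            return pos(niece_a if take else niece_b)
        smaller, larger = (niece_a, niece_b) if sides_a < sides_b else (niece_b, niece_a)
        return pos(smaller if take else larger)
    raise ValueError(f"unknown choice1 option {option!r}")  # pragma: no cover


def make_division_order(
    t: TissueState,
    cfg: StrategyConfig,
    previous_order: list[int] | None,
    rng: np.random.Generator,
) -> list[int]:
    """Build the order in which the real cells divide this cycle.

    ``Random``: a uniform random permutation of all real cells.
    ``Strict``: each sister pair divides consecutively, pairs are
    sequenced by their mothers' positions in ``previous_order`` (the
    realized order of the preceding cycle), and the order within each
    pair is uniform and independent.
    """
    real = sorted(t.real_ids())
    if cfg.order == "Random":
        perm = rng.permutation(len(real))
        return [real[j] for j in perm]
    # Strict
    if len(real) == 1:
        return list(real)
    if previous_order is None:
        raise ValueError("Strict order requires the previous cycle's realized order")
    order: list[int] = []
    seen: set[int] = set()
    for mother in previous_order:
        rec = t.cells.get(mother)
        if rec is None or rec.kind != REAL or rec.sister_id is None:
            raise ValueError(f"cell {mother} from previous order has no daughter pair")
        pair = [mother, rec.sister_id]  # daughter A retained the mother's id
        if rng.random() < 0.5:
            pair.reverse()
        order.extend(pair)
        seen.update(pair)
    if seen != set(real):
        raise ValueError("previous order does not cover the current real cells")
    return order
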