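"""Polygon-class distributions and chi-square fit statistics.

The census of a tissue is the distribution of the proportions of
k-sided real cells.  A simulated census is compared to an empirical
reference distribution (k = 4..9 only) with a chi-square-style score

    sum_{k=4}^{9} (p_sim(k) - p_emp(k))^2 / d(k)

with denominators d(k) taken from the empirical proportions ("sheet 1")
or the simulated proportions ("sheet 2").  Rankings of parameter
settings use sheet 2, which avoids blow-ups where an empirical
proportion is very small or zero.  Proportions are taken over all real
cells; by default they are *not* renormalized to the 4..9 window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "FIT_K_RANGE",
    "PolygonDistribution",
    "EmpiricalReference",
    "Chi2Result",
    "polygon_distribution",
    "chi2_stat",
    "compare_to_reference",
    "rank_settings",
]

FIT_K_RANGE = range(4, 10)  # 4 <= k <= 9


@dataclass(frozen=True)
class PolygonDistribution:
    """Counts and proportions of k-sided real cells."""

    counts: dict[int, int]
    total_real_cells: int = field(init=False)

    def __post_init__(self):
        if not self.counts or any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be a nonempty map with nonnegative values")
        total = sum(self.counts.values())
        if total <= 0:
            raise ValueError("distribution must contain at least one cell")
        object.__setattr__(self, "counts", dict(sorted(self.counts.items())))
        object.__setattr__(self, "total_real_cells", total)

    @property
    def proportions(self) -> dict[int, float]:
        n = self.total_real_cells
        return {k: c / n for k, c in self.counts.items()}

    def proportion(self, k: int) -> float:
        return self.counts.get(k, 0) / self.total_real_cells

    def mean_sides(self) -> float:
        return sum(k * c for k, c in self.counts.items()) / self.total_real_cells

    def mode(self) -> int:
        return max(self.counts, key=lambda k: (self.counts[k], -k))

    @staticmethod
    def pool(parts: list["PolygonDistribution"]) -> "PolygonDistribution":
        counts: dict[int, int] = {}
        for p in parts:
            for k, c in p.counts.items():
                counts[k] = counts.get(k, 0) + c
        return PolygonDistribution(counts)


def polygon_distribution(t) -> PolygonDistribution:
    """Census of k-sided real cells in a tissue (fake cells excluded)."""
    counts: dict[int, int] = {}
    for c in t.real_cells():
        k = len(c.neighbors)
        counts[k] = counts.get(k, 0) + 1
    if not counts:
        raise ValueError("tissue contains no real cells")
    return PolygonDistribution(counts)


@dataclass(frozen=True)
class EmpiricalReference:
    """Empirical polygon-class proportions for one organism, k = 4..9.

    Mass outside the 4..9 window is permitted (proportions may sum to
    less than 1)."""

    organism: str
    proportions: dict[int, float]

    def __post_init__(self):
        props = {int(k): float(v) for k, v in self.proportions.items()}
        if any(k not in FIT_K_RANGE for k in props):
            raise ValueError(f"reference k values must lie in 4..9, got {sorted(props)}")
        if any(v < 0 for v in props.values()):
            raise ValueError("reference proportions must be nonnegative")
        if sum(props.values()) > 1.0 + 1e-9:
            raise ValueError("reference proportions must sum to at most 1")
        full = {k: props.get(k, 0.0) for k in FIT_K_RANGE}
        object.__setattr__(self, "proportions", full)


def chi2_stat(
    sim: PolygonDistribution,
    emp: EmpiricalReference,
    mode: str,
    renormalize: bool = False,
) -> float:
    """Chi-square fit score over k = 4..9.

    ``mode='sheet1'`` uses empirical denominators, ``mode='sheet2'``
    simulation denominators.  A term with zero denominator contributes
    0 when its numerator is also 0; otherwise the statistic is
    undefined and NaN is returned with a warning.  With ``renormalize``
    both distributions are rescaled to sum to 1 over the 4..9 window
    before differencing (off by default).
    """
    if mode not in ("sheet1", "sheet2"):
        raise ValueError(f"mode must be 'sheet1' or 'sheet2', got {mode!r}")
    p_sim = {k: sim.proportion(k) for k in FIT_K_RANGE}
    p_emp = dict(emp.proportions)
    if renormalize:
        s = sum(p_sim.values())
        e = sum(p_emp.values())
        if s == 0 or e == 0:
            raise ValueError("cannot renormalize a distribution with no mass in 4..9")
        p_sim = {k: v / s for k, v in p_sim.items()}
        p_emp = {k: v / e for k, v in p_emp.items()}
    total = 0.0
    for k in FIT_K_RANGE:
        d = p_emp[k] if mode == "sheet1" else p_sim[k]
        num = (p_sim[k] - p_emp[k]) ** 2
        if d == 0.0:
            if num == 0.0:
                continue
            warnings.warn(
                f"chi2 undefined for {emp.organism} ({mode}): zero denominator at k={k} "
                f"with nonzero difference",
                stacklevel=2,
            )
            return math.nan
        total += num / d
    return total


@dataclass(frozen=True)
class Chi2Result:
    """Both fit scores of one setting against one organism."""

    organism: str
    setting: str
    sheet1: float
    sheet2: float

    @property
    def sheet1_defined(self) -> bool:
        return not math.isnan(self.sheet1)

    @property
    def sheet2_defined(self) -> bool:
        return not math.isnan(self.sheet2)


def compare_to_reference(
    sim: PolygonDistribution,
    emp: EmpiricalReference,
    setting: str,
    renormalize: bool = False,
) -> Chi2Result:
    """Compute both sheets for one setting/organism pair."""
    return Chi2Result(
        organism=emp.organism,
        setting=setting,
        sheet1=chi2_stat(sim, emp, "sheet1", renormalize=renormalize),
        sheet2=chi2_stat(sim, emp, "sheet2", renormalize=renormalize),
    )


def rank_settings(results: list[Chi2Result], organism: str) -> list[Chi2Result]:
    """Rank settings for one organism, ascending by the sheet-2 score.

    Ties break lexicographically on the setting name.  Results whose
    sheet-2 statistic is undefined are listed last (flagged by NaN).
    """
    mine = [r for r in results if r.organism == organism]
    valid = sorted(
        (r for r in mine if r.sheet2_defined), key=lambda r: (r.sheet2, r.setting)
    )
    if not valid:
        raise ValueError(f"no valid chi2 results for organism {organism!r}")
    flagged = sorted((r for r in mine if not r.sheet2_defined), key=lambda r: r.setting)
    if flagged:
        warnings.warn(
            f"{len(flagged)} setting(s) with undefined chi2 for {organism} listed last",
            stacklevel=2,
        )
    return valid + flagged
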