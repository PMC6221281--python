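"""Laws of the cleavage-plane strategies and division orders."""

import itertools
import math

import numpy as np
import pytest

from epitopo.strategies import (
    CHOICE2_OPTIONS,
    StrategyConfig,
    beta_interval_table,
    choose_side1,
    choose_side2,
    make_division_order,
    side2_pmf,
)
from epitopo.tissue import init_tissue, divide_cell

from conftest import (
    four_sigma_band,
    make_niece_scenario,
    make_plain_cells,
    make_sister_pairs,
)


def _cfg2(choice2, **kw):
    return StrategyConfig("RandN", choice2, "Random", **kw)


class TestStrategyConfig:
    def test_names_are_case_insensitive(self):
        cfg = StrategyConfig("orthsmpn", "ROTNORM", "random", smp=0.5, stdbeta=0.1)
        assert (cfg.choice1, cfg.choice2, cfg.order) == ("OrthSmpN", "rotNorm", "Random")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"choice1": "nope"},
            {"choice2": "nope"},
            {"order": "nope"},
            {"choice1": "OrthSmpN"},  # missing smp
            {"choice1": "OrthSmpN", "smp": 1.5},
            {"choice2": "Even-Binomial"},  # missing probB
            {"choice2": "rotNorm"},  # missing stdbeta
            {"choice2": "rotTanNorm", "stdbeta": -0.1},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StrategyConfig(**kwargs)


class TestSide2Pmf:
    def test_binomial_i6(self):
        pmf = side2_pmf(6, _cfg2("Binomial"))
        assert pmf.as_dict() == pytest.approx({2: 0.25, 3: 0.5, 4: 0.25})

    def test_evensplit_even_and_odd(self):
        assert side2_pmf(6, _cfg2("evensplit")).as_dict() == pytest.approx({2: 0, 3: 1.0, 4: 0})
        assert side2_pmf(7, _cfg2("evensplit")).as_dict() == pytest.approx(
            {2: 0, 3: 0.5, 4: 0.5, 5: 0}
        )

    def test_unevensplit(self):
        assert side2_pmf(4, _cfg2("unevensplit")).as_dict() == pytest.approx({2: 1.0})
        assert side2_pmf(8, _cfg2("unevensplit")).as_dict() == pytest.approx(
            {2: 0.5, 3: 0, 4: 0, 5: 0, 6: 0.5}
        )

    def test_random_uniform(self):
        pmf = side2_pmf(8, _cfg2("random"))
        assert pmf.as_dict() == pytest.approx({u: 0.2 for u in range(2, 7)})

    def test_even_binomial_mixture_i8(self):
        pmf = side2_pmf(8, _cfg2("Even-Binomial", probB=0.3))
        assert pmf.as_dict() == pytest.approx(
            {2: 0.01875, 3: 0.075, 4: 0.8125, 5: 0.075, 6: 0.01875}
        )

    @pytest.mark.parametrize("i", range(4, 13))
    @pytest.mark.parametrize("probB", [0.0, 0.3, 1.0])
    def test_even_binomial_is_exact_mixture(self, i, probB):
        mix = side2_pmf(i, _cfg2("Even-Binomial", probB=probB))
        even = side2_pmf(i, _cfg2("evensplit"))
        bino = side2_pmf(i, _cfg2("Binomial"))
        expect = [
            (1 - probB) * e + probB * b
            for e, b in zip(even.probabilities, bino.probabilities)
        ]
        assert mix.probabilities == pytest.approx(expect, abs=1e-15)

    @pytest.mark.parametrize("option", ["rotNorm", "rotTanNorm"])
    def test_rotation_on_square_has_single_choice(self, option):
        assert side2_pmf(4, _cfg2(option, stdbeta=0.7)).as_dict() == pytest.approx({2: 1.0})

    @pytest.mark.parametrize("i", range(4, 13))
    @pytest.mark.parametrize(
        "option,kw",
        [
            ("evensplit", {}),
            ("random", {}),
            ("unevensplit", {}),
            ("Binomial", {}),
            ("Even-Binomial", {"probB": 0.3}),
            ("rotNorm", {"stdbeta": 0.15}),
            ("rotTanNorm", {"stdbeta": 0.15}),
        ],
    )
    def test_pmf_normalized_supported_and_symmetric(self, i, option, kw):
        """Every pmf sums to 1, lives on u in 2..i-2, and is symmetric
        under u <-> i-u."""
        pmf = side2_pmf(i, _cfg2(option, **kw))
        assert pmf.us == tuple(range(2, i - 1))
        assert sum(pmf.probabilities) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= 0 for p in pmf.probabilities)
        d = pmf.as_dict()
        for u in pmf.us:
            assert d[u] == pytest.approx(d[i - u], abs=1e-12)

    @pytest.mark.parametrize("option", ["rotNorm", "rotTanNorm"])
    @pytest.mark.parametrize("i", [4, 6, 8, 10, 12])
    def test_rotation_converges_to_evensplit(self, option, i):
        """As stdbeta -> 0 the rotation pmfs collapse onto the even split."""
        pmf = side2_pmf(i, _cfg2(option, stdbeta=1e-4))
        even = side2_pmf(i, _cfg2("evensplit"))
        tv = 0.5 * sum(
            abs(a - b) for a, b in zip(pmf.probabilities, even.probabilities)
        )
        assert tv < 1e-6

    @pytest.mark.parametrize("i", [5, 7, 9])
    def test_rotation_small_stdbeta_odd_tie(self, i):
        """For odd i the beta = 0 ray hits the opposite vertex, so the
        small-stdbeta limit splits evenly over the two central edges."""
        for option in ("rotNorm", "rotTanNorm"):
            d = side2_pmf(i, _cfg2(option, stdbeta=1e-4)).as_dict()
            assert d[(i - 1) // 2] == pytest.approx(0.5, abs=1e-9)
            assert d[(i + 1) // 2] == pytest.approx(0.5, abs=1e-9)

    def test_rejects_too_few_sides(self):
        with pytest.raises(ValueError):
            side2_pmf(3, _cfg2("random"))


class TestBetaIntervals:
    def test_square_opposite_edge(self):
        """For a square anchored at a side midpoint, the opposite edge
        subtends (-atan(1/2), +atan(1/2))."""
        table = beta_interval_table(4)
        a, b = table[2]
        assert a == pytest.approx(-math.atan(0.5))
        assert b == pytest.approx(math.atan(0.5))
        assert table[1][0] == pytest.approx(-math.pi / 2)
        assert table[3][1] == pytest.approx(math.pi / 2)

    @pytest.mark.parametrize("i", range(4, 13))
    def test_intervals_tile_a_half_turn(self, i):
        table = beta_interval_table(i)
        prev = -math.pi / 2
        for u in range(1, i):
            a, b = table[u]
            assert a == pytest.approx(prev, abs=1e-12)
            assert b > a
            prev = b
        assert prev == pytest.approx(math.pi / 2, abs=1e-12)

    @pytest.mark.parametrize("i", range(4, 13))
    def test_symmetry_under_u_reflection(self, i):
        table = beta_interval_table(i)
        for u in range(1, i):
            a, b = table[u]
            ra, rb = table[i - u]
            assert a == pytest.approx(-rb, abs=1e-12)
            assert b == pytest.approx(-ra, abs=1e-12)

    def test_even_center_edge_is_centered(self):
        for i in (6, 8, 10):
            a, b = beta_interval_table(i)[i // 2]
            assert a == pytest.approx(-b, abs=1e-12)


class TestChooseSide2Sampling:
    N = 10**5

    @pytest.mark.parametrize(
        "option,kw,i",
        [
            ("random", {}, 8),
            ("Binomial", {}, 8),
            ("Even-Binomial", {"probB": 0.3}, 8),
            ("rotNorm", {"stdbeta": 0.15}, 8),
            ("rotTanNorm", {"stdbeta": 0.15}, 8),
            ("unevensplit", {}, 7),
            ("evensplit", {}, 7),
        ],
    )
    def test_empirical_frequencies_match_pmf(self, option, kw, i, rng):
        cfg = _cfg2(option, **kw)
        pmf = side2_pmf(i, cfg)
        draws = np.array([choose_side2(i, cfg, rng) for _ in range(self.N)])
        for u, p in zip(pmf.us, pmf.probabilities):
            freq = np.mean(draws == u)
            assert abs(freq - p) <= four_sigma_band(p, self.N) + 1e-12

    def test_evensplit_even_i_is_deterministic(self, rng):
        assert all(choose_side2(6, _cfg2("evensplit"), rng) == 3 for _ in range(100))


class TestChooseSide1:
    def test_smn_picks_unique_minimum(self, rng):
        """SmN targets the real neighbor with the fewest sides."""
        t = init_tissue(8)
        (m,) = t.real_ids()
        divide_cell(t, m, 0, 4)  # 6-and-6 sisters
        sister = t.cells[m].sister_id
        divide_cell(t, sister, t.cells[sister].neighbors.index(m), 2)
        # m now borders two nieces with distinct side counts (4 and 6).
        nb = t.cells[m].neighbors
        sides = {x: t.cells[x].sides for x in nb if t.cells[x].kind == "real"}
        small = min(sides, key=sides.get)
        big = max(sides, key=sides.get)
        cfg_sm = StrategyConfig("SmN", "random", "Random")
        cfg_la = StrategyConfig("LaN", "random", "Random")
        for _ in range(25):
            assert nb[choose_side1(t, m, cfg_sm, rng)] == small
            assert nb[choose_side1(t, m, cfg_la, rng)] == big

    def test_randn_uniform_over_all_edges(self, rng):
        t = init_tissue(6)
        (m,) = t.real_ids()
        cfg = StrategyConfig("RandN", "random", "Random")
        n = 60_000
        draws = np.array([choose_side1(t, m, cfg, rng) for _ in range(n)])
        for j in range(6):
            assert abs(np.mean(draws == j) - 1 / 6) <= four_sigma_band(1 / 6, n)

    def test_orth_undivided_sister_edge_is_forced(self, rng):
        t = init_tissue(8)
        (m,) = t.real_ids()
        divide_cell(t, m, 0, 4)
        sister = t.cells[m].sister_id
        pos = t.cells[m].neighbors.index(sister)
        for option in ("OrthSmN", "OrthLaN", "OrthRandN", "OrthBornSmN",
                       "OrthBornLaN"):
            cfg = StrategyConfig(option, "random", "Random")
            assert choose_side1(t, m, cfg, rng) == pos

    def test_orthsmn_prefers_smaller_niece(self, rng):
        t, m, pos_a, pos_b = make_niece_scenario(sides_a=7, sides_b=5)
        cfg = StrategyConfig("OrthSmN", "random", "Random")
        assert all(choose_side1(t, m, cfg, rng) == pos_b for _ in range(25))

    def test_orthlan_prefers_larger_niece(self, rng):
        t, m, pos_a, pos_b = make_niece_scenario(sides_a=7, sides_b=5)
        cfg = StrategyConfig("OrthLaN", "random", "Random")
        assert all(choose_side1(t, m, cfg, rng) == pos_a for _ in range(25))

    def test_orth_born_uses_birth_sides_not_current(self, rng):
        # Current sides favor niece B, birth sides favor niece A.
        t, m, pos_a, pos_b = make_niece_scenario(
            sides_a=7, sides_b=5, born_a=4, born_b=6
        )
        assert choose_side1(
            t, m, StrategyConfig("OrthBornSmN", "random", "Random"), rng
        ) == pos_a
        assert choose_side1(
            t, m, StrategyConfig("OrthBornLaN", "random", "Random"), rng
        ) == pos_b

    def test_tie_breaks_follow_mother_label(self, rng):
        t, m, pos_a, pos_b = make_niece_scenario(sides_a=6, sides_b=6)
        # Niece A retained the mother's label.
        assert choose_side1(t, m, StrategyConfig("OrthSmN", "random", "Random"), rng) == pos_a
        assert choose_side1(t, m, StrategyConfig("OrthLaN", "random", "Random"), rng) == pos_b
        assert choose_side1(t, m, StrategyConfig("OrthBornSmN", "random", "Random"), rng) == pos_a
        assert choose_side1(t, m, StrategyConfig("OrthBornLaN", "random", "Random"), rng) == pos_b

    def test_orthsmpn_boundary_parameters_match_deterministic_rules(self, rng):
        t, m, pos_a, pos_b = make_niece_scenario(sides_a=7, sides_b=5)
        smp1 = StrategyConfig("OrthSmpN", "random", "Random", smp=1.0)
        smp0 = StrategyConfig("OrthSmpN", "random", "Random", smp=0.0)
        for _ in range(25):
            assert choose_side1(t, m, smp1, rng) == pos_b  # = OrthSmN
            assert choose_side1(t, m, smp0, rng) == pos_a  # complement

    def test_orthsmpn_tie_frequency(self, rng):
        """Tied nieces: the label-retaining niece is chosen with
        probability smp (checked over 1e5 draws)."""
        t, m, pos_a, pos_b = make_niece_scenario(sides_a=6, sides_b=6)
        cfg = StrategyConfig("OrthSmpN", "random", "Random", smp=0.55)
        n = 10**5
        hits = sum(choose_side1(t, m, cfg, rng) == pos_a for _ in range(n))
        assert abs(hits / n - 0.55) <= four_sigma_band(0.55, n)

    def test_orthsmpn_smaller_niece_frequency(self, rng):
        t, m, pos_a, pos_b = make_niece_scenario(sides_a=7, sides_b=5)
        cfg = StrategyConfig("OrthSmpN", "random", "Random", smp=0.7)
        n = 10**5
        hits = sum(choose_side1(t, m, cfg, rng) == pos_b for _ in range(n))
        assert abs(hits / n - 0.7) <= four_sigma_band(0.7, n)

    def test_orthrandn_fair_coin(self, rng):
        t, m, pos_a, pos_b = make_niece_scenario(sides_a=7, sides_b=5)
        cfg = StrategyConfig("OrthRandN", "random", "Random")
        n = 10**5
        hits = sum(choose_side1(t, m, cfg, rng) == pos_a for _ in range(n))
        assert abs(hits / n - 0.5) <= four_sigma_band(0.5, n)

    def test_initial_cell_fallback_uniform(self, rng):
        """The first cycle has no sister; Orth* falls back to a uniform
        edge choice."""
        t = init_tissue(7)
        (m,) = t.real_ids()
        cfg = StrategyConfig("OrthSmN", "random", "Random")
        n = 70_000
        draws = np.array([choose_side1(t, m, cfg, rng) for _ in range(n)])
        for j in range(7):
            assert abs(np.mean(draws == j) - 1 / 7) <= four_sigma_band(1 / 7, n)


class TestDivisionOrder:
    def test_random_order_uniform_over_permutations(self, rng):
        t = make_plain_cells(4)
        cfg = StrategyConfig("RandN", "random", "Random")
        n = 10**5
        counts = {}
        for _ in range(n):
            order = tuple(make_division_order(t, cfg, None, rng))
            counts[order] = counts.get(order, 0) + 1
        assert len(counts) == 24
        for c in counts.values():
            assert abs(c / n - 1 / 24) <= four_sigma_band(1 / 24, n)

    def test_strict_order_two_pairs_enumeration(self, rng):
        """Mothers [a, b]: exactly the four orders with consecutive
        sister pairs in the mothers' sequence, each ~1/4."""
        t, mothers = make_sister_pairs(2)
        cfg = StrategyConfig("RandN", "random", "Strict")
        n = 10**5
        counts = {}
        for _ in range(n):
            order = tuple(make_division_order(t, cfg, mothers, rng))
            counts[order] = counts.get(order, 0) + 1
        a, b = mothers
        legal = {
            (a, a + 1, b, b + 1), (a + 1, a, b, b + 1),
            (a, a + 1, b + 1, b), (a + 1, a, b + 1, b),
        }
        assert set(counts) == legal
        for c in counts.values():
            assert abs(c / n - 0.25) <= four_sigma_band(0.25, n)

    def test_single_cell_order(self, rng):
        t = make_plain_cells(1)
        for order_opt in ("Random", "Strict"):
            cfg = StrategyConfig("RandN", "random", order_opt)
            assert make_division_order(t, cfg, None, rng) == [0]

    def test_strict_requires_previous_order(self, rng):
        t, _ = make_sister_pairs(2)
        cfg = StrategyConfig("RandN", "random", "Strict")
        with pytest.raises(ValueError):
            make_division_order(t, cfg, None, rng)
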