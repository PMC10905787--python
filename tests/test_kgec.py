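"""Genetic knapsack, exact oracles, and key-group selection."""

import itertools

import numpy as np
import pytest

from kgecnet.fixtures import FixtureSpec, gen_planted_frs
from kgecnet.frs import FRS
from kgecnet.kgec import (
    GAConfig,
    KnapsackInstance,
    dp_knapsack_oracle,
    frs_knapsack_instance,
    ga_knapsack,
    greedy_cover_oracle,
    select_kgec,
)


def inst(v, w, C, items=None):
    items = items or tuple(f"I{i}" for i in range(len(v)))
    return KnapsackInstance(items, np.array(v, float), np.array(w, float), float(C))


class TestGAKnapsack:
    def test_small_instance_reaches_enumerated_optimum(self):
        """v=(6,10,12), w=(1,2,3), C=5: best of all 8 subsets is 22."""
        best = max(
            sum(np.array([6, 10, 12])[list(s)])
            for r in range(4)
            for s in itertools.combinations(range(3), r)
            if sum(np.array([1, 2, 3])[list(s)]) <= 5
        )
        assert best == 22
        res = ga_knapsack(inst([6, 10, 12], [1, 2, 3], 5), GAConfig(seed=0))
        assert res.V == 22
        assert set(res.selection) == {"I1", "I2"}

    def test_single_item_fits(self):
        res = ga_knapsack(inst([7], [2], 5), GAConfig(seed=0))
        assert res.selection == ("I0",) and res.V == 7

    def test_zero_capacity_returns_empty(self):
        res = ga_knapsack(inst([5, 5], [1, 1], 0), GAConfig(seed=0))
        assert res.selection == () and res.W == 0

    def test_feasibility_always_holds(self):
        rng = np.random.default_rng(5)
        for i in range(20):
            n = int(rng.integers(2, 20))
            v = rng.integers(0, 30, n).astype(float)
            w = rng.integers(1, 9, n).astype(float)
            C = float(rng.integers(0, int(w.sum()) + 1))
            res = ga_knapsack(inst(v, w, C), GAConfig(seed=100 + i))
            assert res.W <= C

    def test_bitwise_reproducibility(self):
        i1 = inst([3, 9, 4, 7, 2], [2, 3, 1, 4, 2], 6)
        a = ga_knapsack(i1, GAConfig(seed=42))
        b = ga_knapsack(i1, GAConfig(seed=42))
        assert a == b
        c = ga_knapsack(i1, GAConfig(seed=43))
        assert c.W <= 6  # different seed still feasible

    def test_all_zero_fitness_population_survives(self):
        res = ga_knapsack(inst([0, 0, 0], [1, 1, 1], 2), GAConfig(seed=1))
        assert res.V == 0 and res.W <= 2


class TestDPOracle:
    def test_enumerated_example(self):
        assert dp_knapsack_oracle(inst([6, 10, 12], [1, 2, 3], 5))[0] == 22

    def test_zero_capacity(self):
        v, sel = dp_knapsack_oracle(inst([5, 6], [1, 1], 0))
        assert v == 0 and sel == ()

    def test_all_items_too_heavy(self):
        v, sel = dp_knapsack_oracle(inst([5, 6], [4, 7], 3))
        assert v == 0 and sel == ()

    def test_non_integer_weights_fatal(self):
        with pytest.raises(ValueError, match="integer weights"):
            dp_knapsack_oracle(inst([1], [0.5], 1))

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            n = int(rng.integers(2, 10))
            v = rng.integers(1, 20, n).astype(float)
            w = rng.integers(1, 6, n).astype(float)
            C = float(rng.integers(1, int(w.sum()) + 1))
            best = max(
                (sum(v[list(s)]) for r in range(n + 1)
                 for s in itertools.combinations(range(n), r)
                 if sum(w[list(s)]) <= C),
                default=0,
            )
            assert dp_knapsack_oracle(inst(v, w, C))[0] == best


class TestGreedyCover:
    def test_single_item_covers_all(self):
        sel = greedy_cover_oracle({"A": frozenset("xyz")}, "xyz")
        assert sel == ("A",)

    def test_partition_needs_every_block(self):
        sets = {"A": frozenset("abc"), "B": frozenset("def"), "C": frozenset("ghi")}
        assert set(greedy_cover_oracle(sets, "abcdefghi")) == {"A", "B", "C"}

    def test_uncoverable_is_fatal_and_lists_missing(self):
        with pytest.raises(ValueError, match="'z'"):
            greedy_cover_oracle({"A": frozenset("ab")}, "abz")

    def test_greedy_at_least_exhaustive_optimum(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            universe = [f"p{i}" for i in range(12)]
            sets = {}
            for i in range(10):
                size = int(rng.integers(1, 6))
                picked = rng.choice(12, size=size, replace=False)
                sets[f"I{i}"] = frozenset(universe[j] for j in picked)
            if set().union(*sets.values()) != set(universe):
                continue
            greedy = greedy_cover_oracle(sets, universe)
            opt = next(
                r for r in range(1, 11)
                for combo in itertools.combinations(sorted(sets), r)
                if set().union(*(sets[c] for c in combo)) == set(universe)
            )
            assert len(greedy) >= opt


class TestSelectKGEC:
    def test_single_covering_component(self):
        frs = FRS(
            selected_components=("A", "B"),
            target_sets={"A": frozenset("xyz"), "B": frozenset("x")},
            effective_proteins=frozenset("xyz"),
        )
        res = select_kgec(frs, GAConfig(seed=0))
        assert res.selection == ("A",) and res.coverage == 1.0

    def test_planted_cover_recovered(self):
        frs, planted = gen_planted_frs(FixtureSpec(seed=2))
        res = select_kgec(frs, GAConfig(seed=2))
        assert res.coverage == 1.0
        assert res.size <= len(planted) + 1

    def test_capacity_override_runs_single_ga(self):
        frs, planted = gen_planted_frs(FixtureSpec(seed=4))
        res = select_kgec(frs, GAConfig(seed=4), capacity=len(planted))
        assert res.capacity == len(planted)
        assert res.W <= len(planted)

    def test_no_effective_proteins_fatal(self):
        frs = FRS(("A",), {"A": frozenset()}, frozenset())
        with pytest.raises(ValueError, match="no effective proteins"):
            select_kgec(frs, GAConfig(seed=0))


class TestCoverageMonotonicity:
    def test_adding_item_never_decreases_coverage(self):
        frs, _ = gen_planted_frs(FixtureSpec(seed=6, n_components=12, n_targets=40,
                                             planted_cover_size=3))
        ki = frs_knapsack_instance(frs)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.random(ki.n) < 0.3
            cov = ki.membership[x].any(axis=0).sum() if x.any() else 0
            off = np.nonzero(~x)[0]
            if off.size == 0:
                continue
            y = x.copy()
            y[off[0]] = True
            cov2 = ki.membership[y].any(axis=0).sum()
            assert cov2 >= cov
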