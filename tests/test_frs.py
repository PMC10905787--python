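"""Goal program and function response space, checked against brute force."""

import itertools

import numpy as np
import pytest

from kgecnet.frs import (
    GoalProgramSpec,
    build_frs,
    select_max_degree_subset,
    solve_goal_program,
)
from kgecnet.networks import CTNetwork, build_ct_network
from kgecnet.records import ComponentRecord, CTEdge, DiseaseGeneRecord


def make_net(target_sets):
    """CTNetwork directly from a {component: targets} mapping."""
    comps = tuple(sorted(target_sets))
    targets = frozenset().union(*target_sets.values())
    return CTNetwork(
        components=comps,
        targets=targets,
        target_sets={c: frozenset(t) for c, t in target_sets.items()},
    )


def dgenes(symbols):
    return [DiseaseGeneRecord(s, 1.0, 1) for s in symbols]


def exhaustive_goal_oracle(net, disease, spec=GoalProgramSpec()):
    """Brute force: every k, every size-k subset; max total degree wins the
    subset slot (first in lexicographic id order on ties), then lexicographic
    deviation minimization across k with ties to the smallest k."""
    disease_syms = {g.symbol for g in disease}
    C_com, C_tar = net.n_components, net.n_targets
    C_overlap = len(set(net.targets) & disease_syms)
    g1, g2, g3 = spec.a1 * C_tar, spec.a2 * C_overlap, spec.a3 * C_com
    best = None
    for k in range(1, C_com + 1):
        best_subset, best_deg = None, -1
        for subset in itertools.combinations(sorted(net.components), k):
            deg = sum(len(net.target_sets[c]) for c in subset)
            if deg > best_deg:
                best_subset, best_deg = subset, deg
        n_tar = len(set().union(*(net.target_sets[c] for c in best_subset)))
        d1m = max(0.0, g1 - (k + n_tar))
        d2m = max(0.0, g2 - k)
        d3p = max(0.0, k - g3)
        key = (d1m, d2m, d3p, k)
        if best is None or key < best[0]:
            best = (key, k, n_tar, best_subset)
    return best


def random_ct_fixture(rng):
    n_comp = int(rng.integers(2, 13))
    n_prot = int(rng.integers(3, 15))
    proteins = [f"P{j}" for j in range(n_prot)]
    sets = {}
    for i in range(n_comp):
        deg = int(rng.integers(1, n_prot + 1))
        picked = rng.choice(n_prot, size=deg, replace=False)
        sets[f"C{i:02d}"] = {proteins[j] for j in picked}
    disease = [proteins[j] for j in rng.choice(n_prot, size=max(1, n_prot // 3),
                                               replace=False)]
    return make_net(sets), dgenes(disease)


class TestMaxDegreeSubset:
    def test_matches_pair_enumeration(self):
        net = make_net({"A": set("vwxyz"), "B": set("wxyz"), "C": set("xyz"),
                        "D": set("yz")})
        chosen = select_max_degree_subset(net, 2)
        assert set(chosen) == {"A", "B"}
        best = max(
            itertools.combinations(net.components, 2),
            key=lambda s: sum(net.degree(c) for c in s),
        )
        assert sum(net.degree(c) for c in chosen) == sum(net.degree(c) for c in best)

    def test_boundary_sizes(self):
        net = make_net({"A": {"x"}, "B": {"y"}})
        assert select_max_degree_subset(net, 0) == ()
        assert set(select_max_degree_subset(net, 2)) == {"A", "B"}
        with pytest.raises(ValueError):
            select_max_degree_subset(net, 3)

    def test_ties_break_by_component_id(self):
        net = make_net({"B": {"x"}, "A": {"y"}, "C": {"z", "w"}})
        assert select_max_degree_subset(net, 2) == ("C", "A")


class TestGoalProgram:
    def test_zero_deviation_fixture(self):
        """All three goals exactly attainable at one k -> Z = 0."""
        # C_com=5, C_tar=10: goal1 wants k + n_tar = 7, goal2 wants k = 2
        # (C_overlap chosen so 0.8*C_overlap = 2), goal3 caps k at 2.
        sets = {
            "A": {"T1", "T2", "T3"},
            "B": {"T3", "T4"},
            "C": {"T5"},
            "D": {"T6"},
            "E": {"T7", "T8", "T9", "T10"},
        }
        # top-2 by degree: E(4), A(3) -> 7 targets, k + n_tar = 9
        spec = GoalProgramSpec(a1=0.9, a2=0.8, a3=0.4)
        net = make_net(sets)
        disease = dgenes(["T1", "T2", "T5"])  # overlap 3 genes; 0.8*3 = 2.4
        sol = solve_goal_program(net, disease, spec)
        oracle = exhaustive_goal_oracle(net, disease, spec)
        assert sol.C_com_sel == oracle[1]
        assert sol.C_tar_sel == oracle[2]

    def test_star_fixture_matches_enumeration(self):
        """Hub component plus leaves; optimum k checked exhaustively."""
        sets = {"HUB": {f"T{i}" for i in range(6)}}
        for i in range(9):
            sets[f"L{i}"] = {f"T{i % 6}"}
        net = make_net(sets)
        disease = dgenes(["T0", "T1", "T2", "T3", "T4"])
        sol = solve_goal_program(net, disease)
        key, k, n_tar, _ = exhaustive_goal_oracle(net, disease)
        assert (sol.C_com_sel, sol.C_tar_sel) == (k, n_tar)
        assert (sol.d1_minus, sol.d2_minus, sol.d3_plus) == key[:3]

    def test_random_fixtures_match_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            net, disease = random_ct_fixture(rng)
            sol = solve_goal_program(net, disease)
            key, k, n_tar, _ = exhaustive_goal_oracle(net, disease)
            assert (sol.C_com_sel, sol.C_tar_sel) == (k, n_tar)

    def test_induced_target_count_monotone_in_k(self):
        rng = np.random.default_rng(11)
        net, _ = random_ct_fixture(rng)
        counts = []
        for k in range(1, net.n_components + 1):
            subset = select_max_degree_subset(net, k)
            counts.append(len(set().union(*(net.target_sets[c] for c in subset))))
        assert counts == sorted(counts)

    def test_complementary_slackness(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            net, disease = random_ct_fixture(rng)
            sol = solve_goal_program(net, disease)
            assert sol.d1_minus * sol.d1_plus == 0
            assert sol.d2_minus * sol.d2_plus == 0
            assert sol.d3_minus * sol.d3_plus == 0
            for d in (sol.d1_minus, sol.d1_plus, sol.d2_minus, sol.d2_plus,
                      sol.d3_minus, sol.d3_plus):
                assert d >= 0

    def test_analytic_mode_zeroes_goal_one(self):
        net = make_net({"A": {"T1", "T2"}, "B": {"T2", "T3"}, "C": {"T4"}})
        sol = solve_goal_program(net, dgenes(["T1"]), mode="analytic")
        assert sol.d1_minus == 0
        assert sol.mode == "analytic"

    def test_bad_coefficient_rejected(self):
        with pytest.raises(ValueError, match="a1"):
            GoalProgramSpec(a1=1.5)


class TestBuildFRS:
    def test_single_component_counts(self):
        net = make_net({"A": {"T1", "T2", "T3"}, "B": {"T1"}})
        sol = solve_goal_program(net, dgenes(["T1"]))
        frs = build_frs(net, sol)
        assert len(frs.effective_proteins) == sol.C_tar_sel
        if sol.C_com_sel == 1:
            assert frs.n_nodes == 4 and frs.n_edges == 3

    def test_effective_proteins_equal_target_side(self):
        sets = {f"C{i}": {f"T{j}" for j in range(i + 1)} for i in range(5)}
        net = make_net(sets)
        sol = solve_goal_program(net, dgenes(["T0", "T1"]))
        frs = build_frs(net, sol)
        target_side = {n for n, d in frs.to_graph().nodes(data=True)
                       if d["type"] == "target"}
        assert frs.effective_proteins == target_side
        assert len(frs.effective_proteins) == sol.C_tar_sel
        assert frs.n_edges == sum(len(t) for t in frs.target_sets.values())
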