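"""Goal program defining the Function Response Space (FRS).

The FRS is the C-T subnetwork induced by a component subset chosen to
balance three goals, expressed with deviation variables (d- under-attainment,
d+ over-attainment) and preemptive priorities p1 > p2 > p3:

* goal 1:  C_com' + C_tar'  should reach  a1 * C_tar          (a1 = 0.70)
* goal 2:  C_com'           should reach  a2 * C_overlap      (a2 = 0.80)
* goal 3:  C_com'           should stay below  a3 * C_com     (a3 = 0.40)

with the objective  min Z = p1*d1- + p2*d2- + p3*d3+.  C_overlap is the
number of distinct genes shared by the component targets and the disease
genes.  Among subsets of the chosen size C_com', the one with maximal total
C-T degree is taken; because degree sums are separable this is exactly the
top-k components by degree.  The target side of the induced subgraph
defines the effective proteins.

In the default "induced" mode C_tar' is not free: for each candidate k it
is the number of targets actually induced by the top-k subset, coupling the
goal program to the graph.  The "analytic" mode instead treats C_tar' as a
free non-negative variable and solves the pure goal program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import networkx as nx

from .networks import CTNetwork
from .records import DiseaseGeneRecord

logger = logging.getLogger(__name__)

#: Priority weights used to report a scalar Z in preemptive mode; the actual
#: optimization is lexicographic, these only collapse it to one number.
PREEMPTIVE_WEIGHTS = (1e6, 1e3, 1.0)


@dataclass(frozen=True)
class GoalProgramSpec:
    """Goal coefficients and priority handling.

    ``priorities=None`` means preemptive (lexicographic) minimization of
    (d1-, d2-, d3+); a 3-tuple of positive weights switches to weighted
    minimization of Z = p1*d1- + p2*d2- + p3*d3+.
    """

    a1: float = 0.70
    a2: float = 0.80
    a3: float = 0.40
    priorities: Optional[Tuple[float, float, float]] = None

    def __post_init__(self):
        for name in ("a1", "a2", "a3"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"goal coefficient {name} must be in (0, 1]: {v}")


@dataclass(frozen=True)
class GoalProgramSolution:
    """Selected counts, deviation variables and objective value."""

    C_com_sel: int
    C_tar_sel: int
    d1_minus: float
    d1_plus: float
    d2_minus: float
    d2_plus: float
    d3_minus: float
    d3_plus: float
    Z: float
    C_com: int
    C_tar: int
    C_overlap: int
    mode: str = "induced"

    def as_dict(self) -> dict:
        return {
            "C_com_sel": self.C_com_sel,
            "C_tar_sel": self.C_tar_sel,
            "d1_minus": self.d1_minus,
            "d1_plus": self.d1_plus,
            "d2_minus": self.d2_minus,
            "d2_plus": self.d2_plus,
            "d3_minus": self.d3_minus,
            "d3_plus": self.d3_plus,
            "Z": self.Z,
            "C_com": self.C_com,
            "C_tar": self.C_tar,
            "C_overlap": self.C_overlap,
            "mode": self.mode,
        }


@dataclass
class FRS:
    """Function Response Space: the selected components, their induced
    bipartite subgraph and the effective proteins (its target side)."""

    selected_components: Tuple[str, ...]
    target_sets: Dict[str, FrozenSet[str]]
    effective_proteins: FrozenSet[str]

    @property
    def n_nodes(self) -> int:
        return len(self.selected_components) + len(self.effective_proteins)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.target_sets.values())

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for comp in self.selected_components:
            g.add_node(comp, type="component")
        for tgt in sorted(self.effective_proteins):
            g.add_node(tgt, type="target")
        for comp in self.selected_components:
            for tgt in sorted(self.target_sets[comp]):
                g.add_edge(comp, tgt, interaction="targets")
        return g


def select_max_degree_subset(net: CTNetwork, k: int) -> Tuple[str, ...]:
    """The size-k component subset with maximal total C-T degree.

    Degrees are independent of co-selection, so the exact optimum is the
    top-k components by degree; ties break by component_id ascending, which
    also makes the result the lexicographically smallest optimal subset.
    """
    if not (0 <= k <= net.n_components):
        raise ValueError(f"k={k} out of range 0..{net.n_components}")
    order = sorted(net.components, key=lambda c: (-net.degree(c), c))
    return tuple(order[:k])


def _deviation(attained: float, goal: float) -> Tuple[float, float]:
    """(d-, d+) for one goal; at most one of the pair is positive."""
    return max(0.0, goal - attained), max(0.0, attained - goal)


def compute_overlap(net: CTNetwork, disease_genes: Iterable[DiseaseGeneRecord]) -> int:
    """|union of all component targets  ∩  disease gene symbols|."""
    disease = {g.symbol for g in disease_genes}
    return len(set(net.targets) & disease)


def solve_goal_program(
    net: CTNetwork,
    disease_genes: Iterable[DiseaseGeneRecord],
    spec: GoalProgramSpec = GoalProgramSpec(),
    mode: str = "induced",
) -> GoalProgramSolution:
    """Solve the deviation-variable goal program for the FRS size.

    Induced mode iterates k = 1..C_com (linear after one degree sort; the
    range always covers the a3-window the third goal cares about), computes
    the induced target count of the top-k subset, scores the three goals
    and returns the k minimizing (d1-, d2-, d3+) lexicographically under
    preemptive priorities (or the weighted Z), ties to the smallest k.
    Complementary slackness (d- * d+ = 0 per goal) holds by construction.
    """
    if net.n_components == 0:
        raise ValueError("C-T network has no components")
    C_com, C_tar = net.n_components, net.n_targets
    C_overlap = compute_overlap(net, disease_genes)
    g1 = spec.a1 * C_tar
    g2 = spec.a2 * C_overlap
    g3 = spec.a3 * C_com

    if mode == "induced":
        order = sorted(net.components, key=lambda c: (-net.degree(c), c))
        best = None
        induced: set = set()
        for k, comp in enumerate(order, start=1):
            induced |= net.target_sets[comp]
            n_tar = len(induced)
            d1m, d1p = _deviation(k + n_tar, g1)
            d2m, d2p = _deviation(k, g2)
            d3m, d3p = _deviation(k, g3)
            key = (
                (d1m, d2m, d3p, k)
                if spec.priorities is None
                else (
                    spec.priorities[0] * d1m
                    + spec.priorities[1] * d2m
                    + spec.priorities[2] * d3p,
                    k,
                )
            )
            if best is None or key < best[0]:
                best = (key, k, n_tar, (d1m, d1p, d2m, d2p, d3m, d3p))
        _, k, n_tar, (d1m, d1p, d2m, d2p, d3m, d3p) = best
        C_com_sel, C_tar_sel = k, n_tar
    elif mode == "analytic":
        # C_tar' free: any shortfall on goal 1 is absorbed by C_tar', so
        # d1- is always 0; pick the integer C_com' minimizing (d2-, d3+).
        upper = max(1, int(g2) + 1, int(g3) + 1, C_com)
        best = None
        for k in range(0, upper + 1):
            d2m, d2p = _deviation(k, g2)
            d3m, d3p = _deviation(k, g3)
            key = (d2m, d3p, k) if spec.priorities is None else (
                spec.priorities[1] * d2m + spec.priorities[2] * d3p,
                k,
            )
            if best is None or key < best[0]:
                best = (key, k, (d2m, d2p, d3m, d3p))
        _, k, (d2m, d2p, d3m, d3p) = best
        C_com_sel = k
        C_tar_sel = max(0, int(round(g1)) - k)
        d1m, d1p = _deviation(k + C_tar_sel, g1)
    else:
        raise ValueError(f"unknown mode {mode!r}; choose 'induced' or 'analytic'")

    p = spec.priorities if spec.priorities is not None else PREEMPTIVE_WEIGHTS
    Z = p[0] * d1m + p[1] * d2m + p[2] * d3p
    logger.info(
        "goal program (%s): k=%d targets=%d  d1-=%.2f d2-=%.2f d3+=%.2f",
        mode, C_com_sel, C_tar_sel, d1m, d2m, d3p,
    )
    return GoalProgramSolution(
        C_com_sel=C_com_sel,
        C_tar_sel=C_tar_sel,
        d1_minus=d1m,
        d1_plus=d1p,
        d2_minus=d2m,
        d2_plus=d2p,
        d3_minus=d3m,
        d3_plus=d3p,
        Z=Z,
        C_com=C_com,
        C_tar=C_tar,
        C_overlap=C_overlap,
        mode=mode,
    )


def build_frs(net: CTNetwork, solution: GoalProgramSolution) -> FRS:
    """Materialize the FRS as the induced bipartite subgraph of the top-k
    max-degree components; its target side is the effective-protein set."""
    selected = select_max_degree_subset(net, solution.C_com_sel)
    target_sets = {cid: net.target_sets[cid] for cid in selected}
    effective = frozenset().union(*target_sets.values()) if selected else frozenset()
    frs = FRS(
        selected_components=selected,
        target_sets=target_sets,
        effective_proteins=effective,
    )
    logger.info("FRS: %d nodes, %d edges, %d effective proteins",
                frs.n_nodes, frs.n_edges, len(effective))
    return frs
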