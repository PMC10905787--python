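"""Weighted disease-gene network and bipartite component-target network.

The disease network is the PPI subgraph induced on the disease-associated
genes, with each node weighted by sqrt(relevance_score x literature_count):
the geometric mean of association strength and literature support.

The component-target (C-T) network is the bipartite graph linking active
components to their protein targets; its side sizes and mean degrees are
the standard polypharmacology summary statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, List, Tuple

import networkx as nx
import pandas as pd

from .records import ComponentRecord, CTEdge, DiseaseGeneRecord, InteractionRecord

logger = logging.getLogger(__name__)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how printed tables round."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def node_weight(record: DiseaseGeneRecord) -> float:
    """sqrt(relevance_score * literature_count)."""
    return math.sqrt(record.relevance_score * record.literature_count)


@dataclass
class WeightedGeneNetwork:
    """Disease-gene-induced PPI subgraph with weighted nodes."""

    graph: nx.Graph

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, symbol: str) -> float:
        return self.graph.nodes[symbol]["weight"]

    def top_weighted(self, k: int) -> list:
        return sorted(
            self.graph.nodes, key=lambda n: (-self.graph.nodes[n]["weight"], n)
        )[:k]


def build_weighted_network(
    ppi: Iterable[InteractionRecord],
    disease_genes: Iterable[DiseaseGeneRecord],
    keep_isolates: bool = False,
) -> WeightedGeneNetwork:
    """Map disease genes onto the merged PPI and weight the induced subgraph.

    Disease genes absent from the PPI are lost in the mapping; mapped genes
    without any intra-set edge are isolates and dropped unless
    ``keep_isolates``.
    """
    by_symbol = {}
    for rec in disease_genes:
        by_symbol[rec.symbol] = rec
    full = nx.Graph()
    for edge in ppi:
        full.add_edge(edge.gene_a, edge.gene_b)
    mapped = set(by_symbol) & set(full.nodes)
    if not mapped:
        raise ValueError("no overlap between disease genes and PPI")
    # rebuild in sorted order so exports are byte-stable across processes
    view = full.subgraph(mapped)
    sub = nx.Graph()
    sub.add_nodes_from(sorted(view.nodes))
    sub.add_edges_from(sorted(tuple(sorted(e)) for e in view.edges))
    if not keep_isolates:
        sub.remove_nodes_from(list(nx.isolates(sub)))
    for sym in sub.nodes:
        sub.nodes[sym]["weight"] = node_weight(by_symbol[sym])
        sub.nodes[sym]["type"] = "gene"
    logger.info(
        "weighted gene network: %d/%d disease genes mapped, %d nodes, %d edges",
        len(mapped), len(by_symbol), sub.number_of_nodes(), sub.number_of_edges(),
    )
    return WeightedGeneNetwork(sub)


@dataclass
class CTNetwork:
    """Bipartite component<->target network.

    ``target_sets`` maps each component to its target symbols; components
    retained with an empty target set are listed in ``targetless`` and are
    excluded from degree rankings (they can never enter the function
    response space but still belong in composition reports).
    """

    components: Tuple[str, ...]
    targets: FrozenSet[str]
    target_sets: Dict[str, FrozenSet[str]]
    targetless: FrozenSet[str] = frozenset()

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.target_sets.values())

    def degree(self, component_id: str) -> int:
        return len(self.target_sets[component_id])

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for comp in self.components:
            g.add_node(comp, type="component")
        for tgt in sorted(self.targets):
            g.add_node(tgt, type="target")
        for comp, tset in self.target_sets.items():
            for tgt in sorted(tset):
                g.add_edge(comp, tgt, interaction="targets")
        return g


def build_ct_network(
    active: Iterable[ComponentRecord], edges: Iterable[CTEdge]
) -> CTNetwork:
    """Assemble the bipartite C-T network from screened components and edges.

    Edges referencing components outside the active set are dropped with a
    warning.  Active components with no surviving edge are retained with an
    empty target set and flagged.
    """
    active_ids = tuple(c.component_id for c in active)
    active_set = set(active_ids)
    edges = list(edges)
    if not edges:
        raise ValueError("empty C-T edge list")
    target_sets: Dict[str, set] = {cid: set() for cid in active_ids}
    dropped = 0
    for e in edges:
        if e.component_id not in active_set:
            dropped += 1
            continue
        target_sets[e.component_id].add(e.target_symbol)
    if dropped:
        logger.warning("dropped %d C-T edges referencing screened-out components", dropped)
    all_targets = frozenset().union(*target_sets.values()) if target_sets else frozenset()
    targetless = frozenset(cid for cid, t in target_sets.items() if not t)
    if targetless:
        logger.warning("%d active components have no targets", len(targetless))
    return CTNetwork(
        components=active_ids,
        targets=all_targets,
        target_sets={cid: frozenset(t) for cid, t in target_sets.items()},
        targetless=targetless,
    )


@dataclass
class CTStatistics:
    """Topology summary of a C-T network."""

    n_components: int
    n_targets: int
    n_edges: int
    mean_targets_per_component: float
    mean_components_per_target: float
    component_degrees: pd.DataFrame
    target_degrees: pd.DataFrame
    top_components: List[Tuple[str, int]]
    top_targets: List[Tuple[str, int]]

    def as_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "n_targets": self.n_targets,
            "n_edges": self.n_edges,
            "mean_targets_per_component": self.mean_targets_per_component,
            "mean_components_per_target": self.mean_components_per_target,
            "top_components": self.top_components,
            "top_targets": self.top_targets,
        }


def ct_statistics(net: CTNetwork, top_k: int = 20) -> CTStatistics:
    """Degree tables and mean degrees of both sides of the C-T network.

    Means are |E|/|components| and |E|/|targets|, reported half-up at two
    decimals as composition papers print them.  Targetless components count
    in the denominator but are excluded from the degree ranking.
    """
    n_edges = net.n_edges
    comp_rows = [
        (cid, net.degree(cid))
        for cid in net.components
        if cid not in net.targetless
    ]
    comp_df = pd.DataFrame(comp_rows, columns=["component_id", "degree"]).sort_values(
        ["degree", "component_id"], ascending=[False, True], ignore_index=True
    )
    tgt_counts: Dict[str, int] = {}
    for tset in net.target_sets.values():
        for t in tset:
            tgt_counts[t] = tgt_counts.get(t, 0) + 1
    tgt_df = pd.DataFrame(
        sorted(tgt_counts.items()), columns=["target_symbol", "degree"]
    ).sort_values(["degree", "target_symbol"], ascending=[False, True], ignore_index=True)
    return CTStatistics(
        n_components=net.n_components,
        n_targets=net.n_targets,
        n_edges=n_edges,
        mean_targets_per_component=round_half_up(n_edges / net.n_components),
        mean_components_per_target=round_half_up(n_edges / net.n_targets),
        component_degrees=comp_df,
        target_degrees=tgt_df,
        top_components=[tuple(r) for r in comp_df.head(top_k).itertuples(index=False)],
        top_targets=[tuple(r) for r in tgt_df.head(top_k).itertuples(index=False)],
    )
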