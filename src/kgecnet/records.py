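"""Core record types shared across the pipeline.

All gene and target identifiers are plain HGNC-style symbols, normalized to
uppercase with surrounding whitespace stripped.  No alias resolution is
attempted: mapping synonyms onto canonical symbols is the caller's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: ADME property names carried by a :class:`ComponentRecord`.
ADME_PROPERTIES = ("mw", "hbd", "hba", "clogp", "rotatable_bonds")


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip whitespace, uppercase."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One undirected protein-protein interaction.

    The pair is stored in sorted order so that (A, B) and (B, A) compare
    equal.  ``sources`` accumulates the database labels that reported the
    edge (e.g. BioGRID, STRING); ``confidence`` keeps the maximum score
    seen across sources, or ``None`` when no source carried one.
    """

    gene_a: str
    gene_b: str
    sources: frozenset = frozenset()
    confidence: Optional[float] = None

    def __post_init__(self):
        a, b = normalize_symbol(self.gene_a), normalize_symbol(self.gene_b)
        if a > b:
            a, b = b, a
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        if a == b:
            raise ValueError(f"self-interaction {a!r} is not a valid record")

    @property
    def key(self) -> tuple:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class DiseaseGeneRecord:
    """A disease-associated gene with its relevance score and literature count.

    ``relevance_score`` is a GeneCards-style non-negative association score;
    ``literature_count`` is the number of supporting publications.  The node
    weight used in the weighted gene network is
    ``sqrt(relevance_score * literature_count)``.
    """

    symbol: str
    relevance_score: float
    literature_count: int

    def __post_init__(self):
        object.__setattr__(self, "symbol", normalize_symbol(self.symbol))
        if not (self.relevance_score >= 0):
            raise ValueError(
                f"negative or non-finite relevance score for {self.symbol}: "
                f"{self.relevance_score}"
            )
        if self.literature_count < 0:
            raise ValueError(f"negative literature count for {self.symbol}")


@dataclass(frozen=True)
class ComponentRecord:
    """One herbal compound with its ADME properties and herb provenance.

    A compound present in several herbs carries every herb label.  ADME
    properties may be unknown (``None``); screening decides how to treat
    missing values.  ``concentration`` is an optional mg/g assay value.
    """

    component_id: str
    name: str
    herbs: frozenset
    mw: Optional[float] = None
    hbd: Optional[int] = None
    hba: Optional[int] = None
    clogp: Optional[float] = None
    rotatable_bonds: Optional[int] = None
    concentration: Optional[float] = None

    def __post_init__(self):
        if not self.herbs:
            raise ValueError(f"component {self.component_id} has no herb labels")
        object.__setattr__(self, "herbs", frozenset(self.herbs))
        if self.mw is not None and not self.mw > 0:
            raise ValueError(f"component {self.component_id}: mw must be > 0")
        for prop in ("hbd", "hba", "rotatable_bonds"):
            v = getattr(self, prop)
            if v is not None and v < 0:
                raise ValueError(f"component {self.component_id}: {prop} must be >= 0")

    @property
    def unknown_properties(self) -> frozenset:
        """Names of ADME properties missing from this record."""
        return frozenset(p for p in ADME_PROPERTIES if getattr(self, p) is None)


@dataclass(frozen=True)
class CTEdge:
    """A component -> protein target edge of the bipartite C-T network."""

    component_id: str
    target_symbol: str

    def __post_init__(self):
        object.__setattr__(self, "component_id", self.component_id.strip())
        object.__setattr__(self, "target_symbol", normalize_symbol(self.target_symbol))


@dataclass(frozen=True)
class AnnotationSet:
    """A named gene set (GO/KEGG-style term) for over-representation tests."""

    term_id: str
    term_name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"annotation term {self.term_id} has an empty gene set")
        object.__setattr__(
            self, "genes", frozenset(normalize_symbol(g) for g in self.genes)
        )
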