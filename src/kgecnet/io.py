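"""Readers and writers for every table and graph format the pipeline touches.

Tabular inputs are plain TSV/CSV with headers; gene sets use the standard
GMT format; graphs are exported as SIF (Cytoscape), GraphML or an edge-list
TSV.  All loaders normalize gene symbols (uppercase, stripped) and are
idempotent when re-reading their own writer output.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .records import (
    AnnotationSet,
    ComponentRecord,
    CTEdge,
    DiseaseGeneRecord,
    InteractionRecord,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

#: Default STRING-style confidence cutoff, applied only when a score column exists.
DEFAULT_MIN_CONFIDENCE = 0.7


class FormatError(ValueError):
    """A file did not match its expected layout."""


def _read_table(path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep=sep, dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _parse_sif(path) -> list:
    """Parse a SIF file ('A interaction B [C ...]') into raw edge tuples."""
    edges = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t") if "\t" in line else line.split()
            if not fields or not fields[0]:
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}: SIF line needs >= 3 fields: {line!r}")
            src, _rel, *targets = fields
            for tgt in targets:
                edges.append((src, tgt, None))
    return edges


def load_ppi(
    paths: Iterable,
    min_confidence: Optional[float] = DEFAULT_MIN_CONFIDENCE,
) -> list:
    """Load and union PPI edge tables from several source databases.

    Each file is either a TSV with columns ``gene_a``, ``gene_b`` and
    optional ``confidence`` / ``source`` columns, or a SIF file (extension
    ``.sif``).  Duplicate edges across files are merged keeping the union
    of source labels and the maximum confidence; self-loops are dropped
    with a warning; edges whose confidence falls below ``min_confidence``
    are discarded (the cutoff applies only where a score is present).
    """
    merged: dict = {}
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"PPI input file not found: {path}")
        default_source = path.stem
        if path.suffix.lower() == ".sif":
            rows = [(a, b, None, default_source) for a, b, _ in _parse_sif(path)]
        else:
            df = _read_table(path, sep="\t")
            if df.empty:
                logger.warning("PPI file %s is empty", path)
                continue
            _require_columns(df, ["gene_a", "gene_b"], path)
            has_conf = "confidence" in df.columns
            has_src = "source" in df.columns
            rows = []
            for rec in df.itertuples(index=False):
                conf = float(getattr(rec, "confidence")) if has_conf else None
                src = str(getattr(rec, "source")) if has_src else default_source
                rows.append((rec.gene_a, rec.gene_b, conf, src))
        for a, b, conf, src in rows:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                logger.warning("dropping self-loop %s-%s in %s", a, b, path)
                continue
            if conf is not None and min_confidence is not None and conf < min_confidence:
                continue
            key = (a, b) if a < b else (b, a)
            if key in merged:
                prev_conf, prev_src = merged[key]
                conf = prev_conf if conf is None else (
                    conf if prev_conf is None else max(conf, prev_conf)
                )
                merged[key] = (conf, prev_src | {src})
            else:
                merged[key] = (conf, {src})
    return [
        InteractionRecord(a, b, sources=frozenset(srcs), confidence=conf)
        for (a, b), (conf, srcs) in sorted(merged.items())
    ]


def load_disease_genes(path) -> list:
    """Load a disease-gene table (symbol, relevance_score, literature_count).

    Rows sharing a symbol are merged keeping the maximum relevance score and
    summing literature counts: the score is a ceiling of evidence strength
    while publication counts are additive across curation sources.
    """
    df = _read_table(path, sep="\t")
    if df.empty:
        logger.warning("disease-gene file %s is empty", path)
        return []
    _require_columns(df, ["symbol", "relevance_score", "literature_count"], path)
    merged: dict = {}
    for rec in df.itertuples(index=False):
        sym = normalize_symbol(rec.symbol)
        score = float(rec.relevance_score)
        if score < 0:
            raise FormatError(f"{path}: negative relevance score for {sym}")
        lit = int(rec.literature_count)
        if sym in merged:
            prev_score, prev_lit = merged[sym]
            merged[sym] = (max(prev_score, score), prev_lit + lit)
        else:
            merged[sym] = (score, lit)
    return [
        DiseaseGeneRecord(sym, score, lit)
        for sym, (score, lit) in sorted(merged.items())
    ]


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return float(s) if s else None


def _opt_int(value) -> Optional[int]:
    f = _opt_float(value)
    return None if f is None else int(round(f))


def load_components(path) -> list:
    """Load a component property CSV.

    Expected columns: ``component_id``, ``name``, ``herbs`` (";"-joined
    labels), ``mw``, ``hbd``, ``hba``, ``clogp``, ``rotatable_bonds`` and
    optionally ``concentration_mg_g``.  Missing property cells load as
    unknown rather than being dropped; the screening stage decides their
    fate.
    """
    df = _read_table(path, sep=",")
    if df.empty:
        logger.warning("component file %s is empty", path)
        return []
    _require_columns(
        df,
        ["component_id", "name", "herbs", "mw", "hbd", "hba", "clogp", "rotatable_bonds"],
        path,
    )
    records = []
    for rec in df.itertuples(index=False):
        herbs = frozenset(h.strip() for h in str(rec.herbs).split(";") if h.strip())
        conc = (
            _opt_float(getattr(rec, "concentration_mg_g"))
            if "concentration_mg_g" in df.columns
            else None
        )
        records.append(
            ComponentRecord(
                component_id=str(rec.component_id).strip(),
                name=str(rec.name).strip(),
                herbs=herbs,
                mw=_opt_float(rec.mw),
                hbd=_opt_int(rec.hbd),
                hba=_opt_int(rec.hba),
                clogp=_opt_float(rec.clogp),
                rotatable_bonds=_opt_int(rec.rotatable_bonds),
                concentration=conc,
            )
        )
    return records


def load_ct_edges(path) -> list:
    """Load a component->target edge TSV, de-duplicating exact pairs."""
    df = _read_table(path, sep="\t")
    if df.empty:
        logger.warning("C-T edge file %s is empty", path)
        return []
    _require_columns(df, ["component_id", "target_symbol"], path)
    seen = set()
    edges = []
    for rec in df.itertuples(index=False):
        edge = CTEdge(str(rec.component_id), str(rec.target_symbol))
        key = (edge.component_id, edge.target_symbol)
        if key not in seen:
            seen.add(key)
            edges.append(edge)
    return edges


def load_gmt(path) -> list:
    """Load gene sets from a standard GMT file (term, description, genes...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    sets = []
    seen_ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term_id, term_name, *genes = fields
            if term_id in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            seen_ids.add(term_id)
            sets.append(AnnotationSet(term_id, term_name, frozenset(genes)))
    return sets


# ---------------------------------------------------------------------------
# Graph export / import

GRAPH_FORMATS = ("sif", "graphml", "tsv")


def write_graph(graph: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a graph as SIF, GraphML or an edge-list TSV.

    GraphML preserves node and edge attributes on reload; SIF keeps only
    the edge relation (attribute ``interaction``, default ``interacts``).
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b, data in sorted(graph.edges(data=True)):
                rel = data.get("interaction", "interacts")
                fh.write(f"{a}\t{rel}\t{b}\n")
            for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
                fh.write(f"{node}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tinteraction\n")
            for a, b, data in sorted(graph.edges(data=True)):
                rel = data.get("interaction", "interacts")
                fh.write(f"{a}\t{b}\t{rel}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")


def load_graph(path, fmt: str = "graphml") -> nx.Graph:
    """Load a graph written by :func:`write_graph`."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) == 1 and fields[0]:
                    g.add_node(fields[0])
                elif len(fields) >= 3:
                    src, rel, *targets = fields
                    for tgt in targets:
                        g.add_edge(src, tgt, interaction=rel)
        return g
    if fmt == "tsv":
        g = nx.Graph()
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                a, b, rel = line.rstrip("\n").split("\t")
                g.add_edge(a, b, interaction=rel)
        return g
    raise ValueError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")


# ---------------------------------------------------------------------------
# Tabular writers (round-trippable with the loaders above)


def write_disease_genes(records: Iterable[DiseaseGeneRecord], path) -> None:
    df = pd.DataFrame(
        [(r.symbol, r.relevance_score, r.literature_count) for r in records],
        columns=["symbol", "relevance_score", "literature_count"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_ppi(records: Iterable[InteractionRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            (r.gene_a, r.gene_b,
             "" if r.confidence is None else r.confidence,
             ";".join(sorted(r.sources)))
        )
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence", "source"]).to_csv(
        path, sep="\t", index=False
    )


def write_components(records: Iterable[ComponentRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "component_id": r.component_id,
                "name": r.name,
                "herbs": ";".join(sorted(r.herbs)),
                "mw": r.mw,
                "hbd": r.hbd,
                "hba": r.hba,
                "clogp": r.clogp,
                "rotatable_bonds": r.rotatable_bonds,
                "concentration_mg_g": r.concentration,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ct_edges(edges: Iterable[CTEdge], path) -> None:
    pd.DataFrame(
        [(e.component_id, e.target_symbol) for e in edges],
        columns=["component_id", "target_symbol"],
    ).to_csv(path, sep="\t", index=False)


def write_gmt(sets: Iterable[AnnotationSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.genes)]) + "\n")
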