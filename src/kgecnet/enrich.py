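"""Over-representation analysis and pathway-coverage statistics.

A query gene set is tested against each annotation term with the one-sided
hypergeometric tail P(X >= k) for drawing k term genes in a query of size n
from a background of N genes of which K belong to the term.  P-values are
Benjamini-Hochberg adjusted across all tested terms.  Coverage statistics
compare the significant term sets of two queries: the fraction of the
reference query's significant terms recovered by the other query.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .records import AnnotationSet, normalize_symbol


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's over-representation test result."""

    term_id: str
    term_name: str
    k: int          # overlap: query genes in the term
    K: int          # term size within the background
    n: int          # query size within the background
    N: int          # background size
    p: float        # one-sided hypergeometric tail P(X >= k)
    p_adj: float    # BH-adjusted p


@dataclass(frozen=True)
class CoverageReport:
    """Overlap of two significant-term sets relative to a reference."""

    reference_terms: frozenset
    query_terms: frozenset
    shared_terms: frozenset
    coverage_fraction: float


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Step-up Benjamini-Hochberg adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in p_adj]


def hypergeom_enrich(
    query: Iterable[str],
    annotations: Iterable[AnnotationSet],
    background: Optional[Iterable[str]] = None,
) -> List[EnrichmentRecord]:
    """Hypergeometric over-representation of ``query`` in each annotation.

    The background defaults to the union of all annotation genes; the
    query is intersected with the background before testing.  Records come
    back sorted by raw p (ties by term id).
    """
    annotations = list(annotations)
    if background is None:
        bg = set().union(*(a.genes for a in annotations)) if annotations else set()
    else:
        bg = {normalize_symbol(g) for g in background}
    q = {normalize_symbol(g) for g in query} & bg
    if not q:
        raise ValueError("query has no genes in the background universe")
    N, n = len(bg), len(q)
    records = []
    pvals = []
    for ann in annotations:
        term_genes = ann.genes & bg
        K = len(term_genes)
        k = len(term_genes & q)
        p = hypergeom_tail(k, N, K, n)
        records.append((ann, k, K, p))
        pvals.append(p)
    adjusted = bh_adjust(pvals)
    out = [
        EnrichmentRecord(
            term_id=ann.term_id,
            term_name=ann.term_name,
            k=k, K=K, n=n, N=N, p=p, p_adj=p_adj,
        )
        for (ann, k, K, p), p_adj in zip(records, adjusted)
    ]
    out.sort(key=lambda r: (r.p, r.term_id))
    return out


def significant_terms(
    records: Iterable[EnrichmentRecord], alpha: float = 0.05, on: str = "raw"
) -> frozenset:
    """Term ids significant at ``alpha`` on raw or BH-adjusted p-values."""
    if on not in ("raw", "adjusted"):
        raise ValueError("on must be 'raw' or 'adjusted'")
    return frozenset(
        r.term_id
        for r in records
        if (r.p if on == "raw" else r.p_adj) < alpha
    )


def pathway_coverage(
    query_records: Iterable[EnrichmentRecord],
    reference_records: Iterable[EnrichmentRecord],
    alpha: float = 0.05,
    on: str = "raw",
) -> CoverageReport:
    """Fraction of the reference's significant terms recovered by the query.

    The raw-p cutoff is the default; BH-adjusted mode (``on='adjusted'``)
    is available and preferable when many terms are tested.
    """
    ref = significant_terms(reference_records, alpha=alpha, on=on)
    if not ref:
        raise ValueError(
            "no significant reference terms at alpha="
            f"{alpha} ({on} p); relax alpha or check the annotation universe"
        )
    qry = significant_terms(query_records, alpha=alpha, on=on)
    shared = ref & qry
    return CoverageReport(
        reference_terms=ref,
        query_terms=qry,
        shared_terms=shared,
        coverage_fraction=len(shared) / len(ref),
    )


def enrichment_table(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    """Tidy DataFrame view, ready for TSV export."""
    return pd.DataFrame(
        [
            (r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p, r.p_adj)
            for r in records
        ],
        columns=["term_id", "term_name", "k", "K", "n", "N", "p", "p_adj"],
    )
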