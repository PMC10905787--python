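"""Seeded synthetic inputs with the statistical structure real data shows.

Every generator is a deterministic function of the spec's seed (PCG64
integer-state generator) and emits records in the exact shapes the loaders
read, so the whole pipeline is testable offline:

* a preferential-attachment PPI with a heavy-tailed degree distribution,
  standing in for merged interaction databases;
* disease genes sampled mostly from the PPI (a configurable fraction lies
  off-network, emulating mapping loss), with lognormal relevance scores
  and Poisson literature counts;
* a component-target table whose degrees are heavy-tailed and which hides
  a planted exact cover: m designated components whose target sets
  partition a designated effective-protein set, giving an unambiguous
  ground-truth key group;
* ADME property tables where each Lipinski rule fails independently with a
  stated probability (planted components always pass, so they survive
  screening);
* GMT annotations containing planted terms drawn from the planted cover's
  targets (guaranteed enrichable) plus random decoy terms.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from . import io as kio
from .frs import FRS
from .records import (
    AnnotationSet,
    ComponentRecord,
    CTEdge,
    DiseaseGeneRecord,
    InteractionRecord,
)

HERBS = ("GZ", "BZ", "ZX", "FL", "ZL")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic input bundle."""

    seed: int = 0
    n_genes: int = 300
    ppi_attachment: int = 2
    n_disease_genes: int = 60
    score_lognormal: Tuple[float, float] = (1.0, 0.75)
    litcount_poisson: float = 5.0
    off_network_fraction: float = 0.15
    n_components: int = 40
    n_targets: int = 200
    planted_cover_size: int = 5
    ct_degree_exponent: float = 2.0
    disease_target_fraction: float = 0.05
    lipinski_fail_fraction: float = 0.10
    planted_term_count: int = 3
    planted_term_size: int = 20
    decoy_term_count: int = 20
    n_background_genes: int = 300

    def __post_init__(self):
        if self.planted_cover_size > self.n_components:
            raise ValueError("planted cover cannot exceed the component count")
        if self.ppi_attachment < 1:
            raise ValueError("ppi_attachment must be >= 1")


def _rng(spec: FixtureSpec, stream: str) -> np.random.Generator:
    # crc32 keys each generator stream; Python's str hash is salted per process
    ss = np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(zlib.crc32(stream.encode()),)
    )
    return np.random.default_rng(ss)


def gen_ppi(spec: FixtureSpec) -> List[InteractionRecord]:
    """Preferential-attachment PPI over labels G0001..G{n}.

    Construction: two seed nodes joined by one edge; each subsequent node
    attaches ``ppi_attachment`` edges to distinct existing nodes drawn
    proportionally to degree.  For attachment a and n >= a+1 nodes the
    edge count is exactly 1 + a*(n-2) when a = 2 (more generally
    1 + sum_i min(a, i-1)).  Confidence scores are uniform on [0.4, 1.0].
    """
    if spec.n_genes < 3:
        raise ValueError("need at least 3 genes for a PPI fixture")
    rng = _rng(spec, "ppi")
    labels = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    degree_bag = [0, 1]  # node indices repeated by degree
    edges = [(0, 1)]
    for new in range(2, spec.n_genes):
        n_attach = min(spec.ppi_attachment, new)
        chosen: set = set()
        while len(chosen) < n_attach:
            pick = degree_bag[rng.integers(0, len(degree_bag))]
            chosen.add(int(pick))
        for other in sorted(chosen):
            edges.append((other, new))
            degree_bag.extend([other, new])
    records = []
    for a, b in edges:
        conf = float(0.4 + 0.6 * rng.random())
        records.append(
            InteractionRecord(labels[a], labels[b],
                              sources=frozenset({"synthetic"}),
                              confidence=round(conf, 3))
        )
    return records


def gen_disease_genes(
    spec: FixtureSpec, ppi: List[InteractionRecord]
) -> List[DiseaseGeneRecord]:
    """Disease genes: mostly PPI members, a fraction off-network.

    Relevance scores are lognormal; literature counts are 1 + Poisson so
    every gene has at least one supporting publication (a zero count would
    zero out its network weight).
    """
    rng = _rng(spec, "disease")
    nodes = sorted({g for e in ppi for g in (e.gene_a, e.gene_b)})
    n_off = int(round(spec.off_network_fraction * spec.n_disease_genes))
    n_on = spec.n_disease_genes - n_off
    if n_on > len(nodes):
        raise ValueError("not enough PPI nodes for the requested disease genes")
    on = [nodes[i] for i in rng.choice(len(nodes), size=n_on, replace=False)]
    off = [f"OFF{i + 1:04d}" for i in range(n_off)]
    mu, sigma = spec.score_lognormal
    records = []
    for sym in on + off:
        score = float(rng.lognormal(mu, sigma))
        lit = int(1 + rng.poisson(spec.litcount_poisson))
        records.append(DiseaseGeneRecord(sym, round(score, 4), lit))
    return records


@dataclass
class CTFixture:
    """A component-target fixture with its planted ground truth."""

    components: List[ComponentRecord]
    edges: List[CTEdge]
    planted_components: Tuple[str, ...]
    proteins: FrozenSet[str]


def _adme_properties(rng: np.random.Generator, fail: np.ndarray) -> dict:
    """Draw one component's properties; fail[r] forces a violation of rule r."""
    return {
        "mw": float(round(rng.uniform(520, 900) if fail[0] else rng.uniform(150, 480), 2)),
        "hbd": int(rng.integers(6, 11) if fail[1] else rng.integers(0, 6)),
        "hba": int(rng.integers(10, 16) if fail[2] else rng.integers(0, 10)),
        "clogp": float(round(rng.uniform(5.5, 9.0) if fail[3] else rng.uniform(-2, 5), 2)),
        "rotatable_bonds": int(rng.integers(11, 21) if fail[4] else rng.integers(0, 11)),
    }


def gen_ct(
    spec: FixtureSpec,
    disease_genes: Optional[List[DiseaseGeneRecord]] = None,
) -> CTFixture:
    """Component records plus C-T edges with a planted exact cover.

    The designated effective-protein set has ``n_targets`` members; when
    disease genes are supplied, a ``disease_target_fraction`` of the set
    reuses disease symbols so the goal program sees a non-trivial overlap.
    The planted components partition the protein set (chunk sizes differ by
    at most one when the partition is uneven); the other components draw
    heavy-tailed (Zipf) numbers of targets from the same set, capped below
    the planted chunk size so the planted cover stays the unambiguous
    optimum.  Planted components always pass the Lipinski screen; every
    other component fails each rule independently with probability
    ``lipinski_fail_fraction``.
    """
    rng = _rng(spec, "ct")
    n_dis_targets = 0
    proteins: List[str] = []
    if disease_genes is not None:
        dis_syms = sorted(g.symbol for g in disease_genes)
        n_dis_targets = min(
            len(dis_syms), int(round(spec.disease_target_fraction * spec.n_targets))
        )
        picked = rng.choice(len(dis_syms), size=n_dis_targets, replace=False)
        proteins.extend(dis_syms[i] for i in sorted(picked))
    proteins.extend(f"P{i + 1:04d}" for i in range(spec.n_targets - n_dis_targets))

    shuffled = list(proteins)
    rng.shuffle(shuffled)
    m = spec.planted_cover_size
    chunks = [set(chunk) for chunk in np.array_split(np.array(shuffled), m)]

    ids = [f"CMP{i + 1:03d}" for i in range(spec.n_components)]
    planted_idx = sorted(
        int(i) for i in rng.choice(spec.n_components, size=m, replace=False)
    )
    planted_ids = tuple(ids[i] for i in planted_idx)
    chunk_cap = max(3, int(0.6 * spec.n_targets / m))

    components: List[ComponentRecord] = []
    edges: List[CTEdge] = []
    chunk_iter = iter(chunks)
    for i, cid in enumerate(ids):
        n_herbs = int(rng.integers(1, 3))
        herbs = frozenset(
            HERBS[j] for j in rng.choice(len(HERBS), size=n_herbs, replace=False)
        )
        if i in planted_idx:
            targets = next(chunk_iter)
            fail = np.zeros(5, dtype=bool)
        else:
            deg = int(min(chunk_cap, rng.zipf(spec.ct_degree_exponent)))
            picked = rng.choice(len(proteins), size=deg, replace=False)
            targets = {proteins[j] for j in picked}
            fail = rng.random(5) < spec.lipinski_fail_fraction
        props = _adme_properties(rng, fail)
        components.append(
            ComponentRecord(component_id=cid, name=f"compound {cid}", herbs=herbs, **props)
        )
        edges.extend(CTEdge(cid, t) for t in sorted(targets))
    return CTFixture(
        components=components,
        edges=edges,
        planted_components=planted_ids,
        proteins=frozenset(proteins),
    )


def gen_annotations(
    spec: FixtureSpec, ct: Optional[CTFixture] = None
) -> List[AnnotationSet]:
    """Planted-enrichable terms plus random decoys over a wide background.

    Planted terms draw all their genes from the planted cover's targets
    (the effective-protein set), so a query of those targets is strongly
    over-represented; decoy terms are drawn from the full universe, which
    includes extra background genes to keep term/query overlaps modest.
    """
    rng = _rng(spec, "annot")
    protein_pool = sorted(ct.proteins) if ct is not None else [
        f"P{i + 1:04d}" for i in range(spec.n_targets)
    ]
    background = [f"BG{i + 1:04d}" for i in range(spec.n_background_genes)]
    universe = protein_pool + background
    sets: List[AnnotationSet] = []
    for t in range(spec.planted_term_count):
        size = min(spec.planted_term_size, len(protein_pool))
        picked = rng.choice(len(protein_pool), size=size, replace=False)
        sets.append(
            AnnotationSet(
                term_id=f"PLANT{t + 1:03d}",
                term_name=f"planted term {t + 1}",
                genes=frozenset(protein_pool[i] for i in picked),
            )
        )
    for t in range(spec.decoy_term_count):
        size = int(rng.integers(10, 41))
        picked = rng.choice(len(universe), size=size, replace=False)
        sets.append(
            AnnotationSet(
                term_id=f"DECOY{t + 1:03d}",
                term_name=f"decoy term {t + 1}",
                genes=frozenset(universe[i] for i in picked),
            )
        )
    return sets


def gen_planted_frs(spec: FixtureSpec) -> Tuple[FRS, Tuple[str, ...]]:
    """A ready-made function response space with a planted exact cover.

    Returns the FRS (all fixture components, effective proteins = the
    designated protein set) and the planted component ids, for exercising
    the key-group selector directly.
    """
    ct = gen_ct(spec)
    target_sets: Dict[str, FrozenSet[str]] = {}
    for c in ct.components:
        target_sets[c.component_id] = frozenset(
            e.target_symbol for e in ct.edges if e.component_id == c.component_id
        )
    frs = FRS(
        selected_components=tuple(c.component_id for c in ct.components),
        target_sets=target_sets,
        effective_proteins=ct.proteins,
    )
    return frs, ct.planted_components


def make_fixture_bundle(spec: FixtureSpec, outdir) -> Dict[str, str]:
    """Write a complete input bundle (PPI, disease genes, components, C-T
    edges, GMT) plus a manifest recording the spec and the planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ppi = gen_ppi(spec)
    disease = gen_disease_genes(spec, ppi)
    ct = gen_ct(spec, disease_genes=disease)
    annotations = gen_annotations(spec, ct)
    paths = {
        "ppi": str(outdir / "ppi.tsv"),
        "disease_genes": str(outdir / "disease_genes.tsv"),
        "components": str(outdir / "components.csv"),
        "ct_edges": str(outdir / "ct_edges.tsv"),
        "gmt": str(outdir / "annotations.gmt"),
    }
    kio.write_ppi(ppi, paths["ppi"])
    kio.write_disease_genes(disease, paths["disease_genes"])
    kio.write_components(ct.components, paths["components"])
    kio.write_ct_edges(ct.edges, paths["ct_edges"])
    kio.write_gmt(annotations, paths["gmt"])
    manifest = {
        "spec": asdict(spec),
        "files": paths,
        "planted_components": list(ct.planted_components),
        "n_proteins": len(ct.proteins),
    }
    with open(outdir / "fixture_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = str(outdir / "fixture_manifest.json")
    return paths
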