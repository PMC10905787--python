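"""End-to-end orchestration: screen -> networks -> FRS -> KGEC -> enrichment.

A run is a pure function of (input files, config, seed).  Every stage
writes its outputs under the configured output directory and the run
manifest records content checksums for inputs and outputs, so a rerun with
an identical config either reproduces the outputs byte-for-byte or, with
``resume=True``, skips stages whose recorded input checksums still match.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import io as kio
from .enrich import enrichment_table, hypergeom_enrich, pathway_coverage
from .frs import FRS, GoalProgramSpec, build_frs, solve_goal_program
from .kgec import GAConfig, select_kgec
from .networks import build_ct_network, build_weighted_network, ct_statistics
from .screen import herb_tally, screen_components, write_screen_report

logger = logging.getLogger(__name__)


class GASettings(BaseModel):
    pop_size: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    max_generations: int = 500
    elitism: int = 1
    stagnation: int = 25


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    ppi: List[str]
    disease_genes: str
    components: str
    ct_edges: str
    gmt: Optional[str] = None
    outdir: str
    seed: int = 0
    min_confidence: Optional[float] = 0.7
    strict_screen: bool = True
    keep_isolates: bool = False
    a1: float = 0.70
    a2: float = 0.80
    a3: float = 0.40
    priorities: Optional[Tuple[float, float, float]] = None
    gp_mode: str = "induced"
    ga: GASettings = Field(default_factory=GASettings)
    capacity: Optional[int] = None
    fitness: str = "coverage"
    alpha: float = 0.05
    p_mode: str = "raw"
    run_enrichment: bool = True

    @field_validator("a1", "a2", "a3")
    @classmethod
    def _coef_range(cls, v):
        if not (0 < v <= 1):
            raise ValueError("goal coefficients must lie in (0, 1]")
        return v

    def validate_inputs(self) -> None:
        missing = [p for p in [*self.ppi, self.disease_genes, self.components,
                               self.ct_edges] if not Path(p).exists()]
        if self.run_enrichment:
            if self.gmt is None:
                raise FileNotFoundError(
                    "enrichment is enabled but no GMT annotation file is configured"
                )
            if not Path(self.gmt).exists():
                missing.append(self.gmt)
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


STAGES = ("screen", "networks", "frs", "kgec", "enrich")


class _CachedKgec:
    """Minimal stand-in for a KGECResult reloaded from stage outputs."""

    def __init__(self, selection, size, coverage):
        self.selection = selection
        self.size = size
        self.coverage = coverage


def run_pipeline(cfg: RunConfig, resume: bool = False) -> dict:
    """Execute the pipeline and return the run manifest.

    With ``resume=True``, a stage is skipped when a previous manifest in
    the output directory records the same input/config checksum and all of
    the stage's output files still exist; skipped stages are reloaded from
    their outputs.
    """
    cfg.validate_inputs()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = None
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh)

    input_files = [*cfg.ppi, cfg.disease_genes, cfg.components, cfg.ct_edges]
    if cfg.gmt:
        input_files.append(cfg.gmt)
    config_digest = hashlib.sha256(
        cfg.model_dump_json().encode()
    ).hexdigest()
    input_digests = {p: _sha256(p) for p in input_files}
    run_key = hashlib.sha256(
        (config_digest + json.dumps(input_digests, sort_keys=True)).encode()
    ).hexdigest()

    manifest: dict = {
        "config": json.loads(cfg.model_dump_json()),
        "config_digest": config_digest,
        "input_checksums": input_digests,
        "run_key": run_key,
        "stages": {},
    }

    stage_outputs = {
        "screen": ["screen_report.tsv", "active_components.csv", "herb_tally.tsv"],
        "networks": ["gene_network.graphml", "ct_network.graphml", "ct_stats.json",
                     "component_degrees.tsv", "target_degrees.tsv"],
        "frs": ["frs_solution.json", "frs.graphml", "frs.sif",
                "effective_proteins.tsv"],
        "kgec": ["kgec.tsv", "kgec_meta.json"],
        "enrich": ["enrichment_kgec.tsv", "enrichment_cap.tsv", "coverage.json"],
    }

    def can_skip(stage: str) -> bool:
        if previous is None or previous.get("run_key") != run_key:
            return False
        if stage not in previous.get("stages", {}):
            return False
        return all((outdir / f).exists() for f in stage_outputs[stage])

    def finish(stage: str, t0: float, skipped: bool = False) -> None:
        manifest["stages"][stage] = {
            "outputs": {
                f: _sha256(outdir / f) for f in stage_outputs[stage]
                if (outdir / f).exists()
            },
            "seconds": round(time.time() - t0, 3),
            "skipped": skipped,
        }

    # --- screen -----------------------------------------------------------
    t0 = time.time()
    all_components = kio.load_components(cfg.components)
    if can_skip("screen"):
        active = kio.load_components(outdir / "active_components.csv")
        finish("screen", t0, skipped=True)
    else:
        active, verdicts = screen_components(all_components, strict=cfg.strict_screen)
        write_screen_report(verdicts, outdir / "screen_report.tsv")
        kio.write_components(active, outdir / "active_components.csv")
        herb_tally(all_components, verdicts).to_csv(
            outdir / "herb_tally.tsv", sep="\t", index=False
        )
        finish("screen", t0)

    # --- networks ---------------------------------------------------------
    t0 = time.time()
    disease = kio.load_disease_genes(cfg.disease_genes)
    edges = kio.load_ct_edges(cfg.ct_edges)
    ct_net = build_ct_network(active, edges)
    if can_skip("networks"):
        finish("networks", t0, skipped=True)
    else:
        ppi = kio.load_ppi(cfg.ppi, min_confidence=cfg.min_confidence)
        gene_net = build_weighted_network(ppi, disease, keep_isolates=cfg.keep_isolates)
        kio.write_graph(gene_net.graph, outdir / "gene_network.graphml", "graphml")
        kio.write_graph(ct_net.to_graph(), outdir / "ct_network.graphml", "graphml")
        stats = ct_statistics(ct_net)
        _dump_json(stats.as_dict(), outdir / "ct_stats.json")
        stats.component_degrees.to_csv(
            outdir / "component_degrees.tsv", sep="\t", index=False
        )
        stats.target_degrees.to_csv(
            outdir / "target_degrees.tsv", sep="\t", index=False
        )
        finish("networks", t0)

    # --- FRS --------------------------------------------------------------
    t0 = time.time()
    gp_spec = GoalProgramSpec(a1=cfg.a1, a2=cfg.a2, a3=cfg.a3,
                              priorities=cfg.priorities)
    solution = solve_goal_program(ct_net, disease, gp_spec, mode=cfg.gp_mode)
    frs = build_frs(ct_net, solution)
    if can_skip("frs"):
        finish("frs", t0, skipped=True)
    else:
        _dump_json(solution.as_dict(), outdir / "frs_solution.json")
        kio.write_graph(frs.to_graph(), outdir / "frs.graphml", "graphml")
        kio.write_graph(frs.to_graph(), outdir / "frs.sif", "sif")
        pd.DataFrame(
            sorted(frs.effective_proteins), columns=["target_symbol"]
        ).to_csv(outdir / "effective_proteins.tsv", sep="\t", index=False)
        finish("frs", t0)

    # --- KGEC -------------------------------------------------------------
    t0 = time.time()
    if can_skip("kgec"):
        kgec_df = pd.read_csv(outdir / "kgec.tsv", sep="\t")
        with open(outdir / "kgec_meta.json") as fh:
            meta = json.load(fh)
        result = _CachedKgec(
            selection=tuple(kgec_df["component_id"]),
            size=int(meta["size"]), coverage=meta["coverage"],
        )
        finish("kgec", t0, skipped=True)
    else:
        ga_cfg = GAConfig(seed=cfg.seed, **cfg.ga.model_dump())
        result = select_kgec(frs, ga_cfg, capacity=cfg.capacity, fitness=cfg.fitness)
        comp_by_id = {c.component_id: c for c in all_components}
        rows = []
        for cid in result.selection:
            covered = len(frs.target_sets[cid] & frs.effective_proteins)
            comp = comp_by_id.get(cid)
            rows.append(
                (cid, covered,
                 ";".join(sorted(comp.herbs)) if comp else "",
                 comp.name if comp else "")
            )
        pd.DataFrame(
            rows, columns=["component_id", "covered_proteins", "herbs", "name"]
        ).to_csv(outdir / "kgec.tsv", sep="\t", index=False)
        _dump_json(
            {
                "size": result.size,
                "V": result.V,
                "W": result.W,
                "capacity": result.capacity,
                "coverage": result.coverage,
                "generations_run": result.generations_run,
                "seed": result.seed,
                "ga_config": cfg.ga.model_dump(),
            },
            outdir / "kgec_meta.json",
        )
        finish("kgec", t0)

    # --- enrichment -------------------------------------------------------
    coverage_fraction = None
    if cfg.run_enrichment:
        t0 = time.time()
        if can_skip("enrich"):
            with open(outdir / "coverage.json") as fh:
                coverage_fraction = json.load(fh)["coverage_fraction"]
            finish("enrich", t0, skipped=True)
        else:
            annotations = kio.load_gmt(cfg.gmt)
            kgec_targets = set().union(
                *(frs.target_sets[cid] for cid in result.selection)
            ) & frs.effective_proteins
            cap_genes = set(ct_net.targets) & {g.symbol for g in disease}
            kgec_records = hypergeom_enrich(kgec_targets, annotations)
            enrichment_table(kgec_records).to_csv(
                outdir / "enrichment_kgec.tsv", sep="\t", index=False
            )
            cap_report = {"coverage_fraction": None, "n_reference": 0, "n_shared": 0}
            if cap_genes:
                cap_records = hypergeom_enrich(cap_genes, annotations)
                enrichment_table(cap_records).to_csv(
                    outdir / "enrichment_cap.tsv", sep="\t", index=False
                )
                try:
                    report = pathway_coverage(
                        kgec_records, cap_records, alpha=cfg.alpha, on=cfg.p_mode
                    )
                except ValueError as err:  # no significant reference terms
                    logger.warning("pathway coverage unavailable: %s", err)
                    cap_report = {"coverage_fraction": None, "n_reference": 0,
                                  "n_shared": 0}
                else:
                    coverage_fraction = report.coverage_fraction
                    cap_report = {
                        "coverage_fraction": report.coverage_fraction,
                        "n_reference": len(report.reference_terms),
                        "n_shared": len(report.shared_terms),
                    }
            else:
                (outdir / "enrichment_cap.tsv").write_text(
                    "term_id\tterm_name\tk\tK\tn\tN\tp\tp_adj\n"
                )
            _dump_json(cap_report, outdir / "coverage.json")
            finish("enrich", t0)

    manifest["summary"] = {
        "n_components": len(all_components),
        "n_active": len(active),
        "ct_edges": ct_net.n_edges,
        "frs_components": solution.C_com_sel,
        "effective_proteins": len(frs.effective_proteins),
        "kgec_size": result.size,
        "kgec_coverage": result.coverage,
        "pathway_coverage": coverage_fraction,
    }
    _dump_json(manifest, manifest_path)
    return manifest
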