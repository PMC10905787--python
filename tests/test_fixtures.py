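"""Synthetic generators: determinism, planted structure, statistical shape."""

import numpy as np
import pytest
from scipy import stats

from kgecnet import io as kio
from kgecnet.fixtures import (
    FixtureSpec,
    gen_annotations,
    gen_ct,
    gen_disease_genes,
    gen_planted_frs,
    gen_ppi,
    make_fixture_bundle,
)
from kgecnet.enrich import hypergeom_enrich
from kgecnet.frs import build_frs, solve_goal_program
from kgecnet.kgec import GAConfig, select_kgec
from kgecnet.networks import build_ct_network
from kgecnet.screen import screen_components


class TestPPI:
    def test_deterministic_per_seed(self):
        a = gen_ppi(FixtureSpec(seed=5))
        b = gen_ppi(FixtureSpec(seed=5))
        assert a == b
        assert a != gen_ppi(FixtureSpec(seed=6))

    def test_edge_count_formula(self):
        """Seed pair + 2 attachments per later node: 1 + 2*(n-2) edges."""
        ppi = gen_ppi(FixtureSpec(seed=0, n_genes=100, ppi_attachment=2))
        assert len(ppi) == 197
        nodes = {g for e in ppi for g in (e.gene_a, e.gene_b)}
        assert len(nodes) == 100

    def test_heavy_tailed_degrees(self):
        """Preferential attachment: hubs far exceed the median degree."""
        hits = 0
        for seed in range(20):
            ppi = gen_ppi(FixtureSpec(seed=seed, n_genes=200))
            deg: dict = {}
            for e in ppi:
                deg[e.gene_a] = deg.get(e.gene_a, 0) + 1
                deg[e.gene_b] = deg.get(e.gene_b, 0) + 1
            values = sorted(deg.values())
            if values[-1] > 3 * np.median(values):
                hits += 1
        assert hits == 20

    def test_too_few_genes_fatal(self):
        with pytest.raises(ValueError):
            gen_ppi(FixtureSpec(n_genes=2))

    def test_confidence_in_declared_range(self):
        ppi = gen_ppi(FixtureSpec(seed=1, n_genes=50))
        assert all(0.4 <= e.confidence <= 1.0 for e in ppi)


class TestDiseaseGenes:
    def test_off_network_fraction(self):
        spec = FixtureSpec(seed=3, n_disease_genes=100, off_network_fraction=0.15)
        ppi = gen_ppi(spec)
        nodes = {g for e in ppi for g in (e.gene_a, e.gene_b)}
        records = gen_disease_genes(spec, ppi)
        off = [r for r in records if r.symbol not in nodes]
        assert len(records) == 100
        assert len(off) == 15

    def test_positive_weights(self):
        spec = FixtureSpec(seed=3)
        records = gen_disease_genes(spec, gen_ppi(spec))
        assert all(r.relevance_score > 0 and r.literature_count >= 1
                   for r in records)


class TestCTFixture:
    def test_planted_partition_is_exact(self):
        """Planted component target sets partition the protein set."""
        ct = gen_ct(FixtureSpec(seed=8, n_targets=60, planted_cover_size=5))
        sets = {}
        for c in ct.planted_components:
            sets[c] = {e.target_symbol for e in ct.edges if e.component_id == c}
        union = set().union(*sets.values())
        assert union == set(ct.proteins) and len(ct.proteins) == 60
        total = sum(len(s) for s in sets.values())
        assert total == 60  # pairwise disjoint
        sizes = sorted(len(s) for s in sets.values())
        assert sizes[-1] - sizes[0] <= 1

    def test_active_fraction_within_binomial_bounds(self):
        """Each rule fails independently at rate f; non-planted components
        pass with prob (1-f)^5, so the active count is binomial."""
        spec = FixtureSpec(seed=10, n_components=100, planted_cover_size=5,
                           lipinski_fail_fraction=0.3)
        ct = gen_ct(spec)
        active, _ = screen_components(ct.components)
        n_other = 100 - 5
        p_pass = (1 - 0.3) ** 5
        lo, hi = stats.binom.ppf([0.005, 0.995], n_other, p_pass)
        assert lo <= len(active) - 5 <= hi

    def test_planted_components_always_screen_active(self):
        ct = gen_ct(FixtureSpec(seed=12, lipinski_fail_fraction=0.9))
        active, _ = screen_components(ct.components)
        assert set(ct.planted_components) <= {c.component_id for c in active}


class TestAnnotations:
    def test_planted_term_strongly_enriched(self):
        """A planted 20-gene term inside a 30-gene query from the protein
        pool is overwhelmingly over-represented against the background."""
        spec = FixtureSpec(seed=14, n_targets=200, n_background_genes=300)
        ct = gen_ct(spec)
        annotations = gen_annotations(spec, ct)
        planted = next(a for a in annotations if a.term_id.startswith("PLANT"))
        query = set(planted.genes) | set(sorted(ct.proteins)[:10])
        records = hypergeom_enrich(query, annotations)
        by_id = {r.term_id: r for r in records}
        assert by_id[planted.term_id].p < 1e-6

    def test_decoy_terms_present(self):
        spec = FixtureSpec(seed=14)
        annotations = gen_annotations(spec, gen_ct(spec))
        assert sum(a.term_id.startswith("DECOY") for a in annotations) == 20


class TestBundleAndRecovery:
    def test_bundle_roundtrips_through_loaders(self, tmp_path):
        paths = make_fixture_bundle(FixtureSpec(seed=2), tmp_path)
        assert len(kio.load_ppi([paths["ppi"]], min_confidence=None)) > 0
        assert len(kio.load_disease_genes(paths["disease_genes"])) == 60
        assert len(kio.load_components(paths["components"])) == 40
        assert len(kio.load_ct_edges(paths["ct_edges"])) > 0
        assert len(kio.load_gmt(paths["gmt"])) == 23

    def test_pipeline_recovers_planted_cover_across_seeds(self):
        """Screen -> C-T net -> goal program -> FRS -> KGEC recovers a
        key group no larger than the planted cover + 1 in >= 9/10 seeds."""
        good = 0
        for seed in range(10):
            spec = FixtureSpec(seed=seed)
            ppi = gen_ppi(spec)
            disease = gen_disease_genes(spec, ppi)
            ct = gen_ct(spec, disease_genes=disease)
            active, _ = screen_components(ct.components)
            net = build_ct_network(active, ct.edges)
            frs = build_frs(net, solve_goal_program(net, disease))
            res = select_kgec(frs, GAConfig(seed=seed))
            assert res.coverage == 1.0
            if res.size <= spec.planted_cover_size + 1:
                good += 1
        assert good >= 9
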