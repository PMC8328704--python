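"""Synthetic-bundle generators: determinism, planted truth, degeneracy knobs."""

import networkx as nx
import numpy as np
import pytest

from netpharm.diffexpr import call_degs, test_genes
from netpharm.synthetic import (
    SimConfig,
    gen_annotations,
    gen_bundle,
    gen_compounds,
    gen_expression,
    gen_interactome,
    write_bundle,
)

test_genes.__test__ = False  # imported library function, not a test


class TestSimConfig:
    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            SimConfig(n_deg=3000, n_genes=2000)
        with pytest.raises(ValueError):
            SimConfig(lfc_range=(0.5, 2.0))  # planted effects must clear |log2FC| > 1
        with pytest.raises(ValueError):
            SimConfig(n_case=1, n_control=1)
        with pytest.raises(ValueError):
            SimConfig(interactome_nodes=3, attachment_m=3)
        with pytest.raises(ValueError):
            SimConfig(fraction_targetless=1.5)

    def test_default_design_is_9v13(self):
        cfg = SimConfig()
        assert (cfg.n_case, cfg.n_control) == (9, 13)


class TestGenExpression:
    def test_zero_noise_exact_shift(self):
        cfg = SimConfig(seed=1, n_genes=20, n_deg=1, noise_sd=0.0, term_size_range=(2, 5))
        expr, labels, planted = gen_expression(cfg)
        (gene, lfc), = planted.items()
        case_mean = expr.loc[gene, [s for s, g in zip(expr.columns, labels) if g == "case"]].mean()
        control_mean = expr.loc[gene, [s for s, g in zip(expr.columns, labels) if g == "control"]].mean()
        assert case_mean - control_mean == pytest.approx(lfc, abs=1e-12)

    def test_determinism(self):
        cfg = SimConfig(seed=7, n_genes=100, n_deg=10)
        a, la, pa = gen_expression(cfg)
        b, lb, pb = gen_expression(cfg)
        assert (a.to_numpy() == b.to_numpy()).all() and la == lb and pa == pb

    def test_planted_effects_exceed_one(self):
        _, _, planted = gen_expression(SimConfig(seed=2, n_genes=500, n_deg=100))
        assert all(abs(lfc) > 1 for lfc in planted.values())

    def test_downstream_recovery_power(self):
        # default study conditions: caller recovers >= 90% of planted DEGs
        sens = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_genes=2000, n_deg=200, lfc_range=(1.5, 3.0), noise_sd=0.5)
            expr, labels, planted = gen_expression(cfg)
            called = call_degs(test_genes(expr, labels))
            hits = set(called.loc[called["call"] != "ns", "gene"]) & set(planted)
            sens.append(len(hits) / len(planted))
        assert np.mean(sens) >= 0.9


class TestGenInteractome:
    def test_tree_when_m1(self):
        g, _ = gen_interactome(SimConfig(seed=1, attachment_m=1, n_hubs=0))
        assert nx.is_tree(g)

    def test_determinism(self):
        cfg = SimConfig(seed=5)
        g1, h1 = gen_interactome(cfg)
        g2, h2 = gen_interactome(cfg)
        assert sorted(g1.edges) == sorted(g2.edges) and h1 == h2

    def test_simple_undirected(self):
        g, _ = gen_interactome(SimConfig(seed=3))
        assert not any(u == v for u, v in g.edges)
        assert not g.is_directed()

    def test_heavy_tail(self):
        # scale-free degree spread: max degree well above the median
        for seed in range(20):
            g, _ = gen_interactome(SimConfig(seed=seed, n_hubs=0))
            degrees = np.array([d for _, d in g.degree()])
            assert degrees.max() > 4 * np.median(degrees)

    def test_planted_hubs_exceed_twice_median(self):
        g, hubs = gen_interactome(SimConfig(seed=11))
        degrees = dict(g.degree())
        median = np.median(list(degrees.values()))
        assert all(degrees[h] > 2 * median for h in hubs)


class TestGenCompounds:
    def test_targetless_fraction_zero(self):
        cfg = SimConfig(seed=1, fraction_targetless=0.0)
        _, target_map = gen_compounds(cfg)
        assert all(target_map.values())

    def test_targetless_fraction_one(self):
        cfg = SimConfig(seed=1, fraction_targetless=1.0)
        _, target_map = gen_compounds(cfg)
        assert not any(target_map.values())

    def test_default_exclusion_count(self):
        # 27 compounds with 5/27 targetless: exactly 22 keep a target set
        records, target_map = gen_compounds(SimConfig(seed=4))
        assert len(records) == 27
        assert sum(bool(v) for v in target_map.values()) == 22

    def test_ob_dl_span_thresholds(self):
        records, _ = gen_compounds(SimConfig(seed=2, n_compounds=100))
        obs = [r.OB for r in records]
        dls = [r.DL for r in records]
        assert min(obs) < 30 < max(obs)
        assert min(dls) < 0.18 < max(dls)

    def test_shared_targets(self):
        _, target_map = gen_compounds(SimConfig(seed=3))
        sets = [s for s in target_map.values() if s]
        assert any(a & b for i, a in enumerate(sets) for b in sets[i + 1:])


class TestGenAnnotations:
    def test_full_overlap_minimal_p(self):
        cfg = SimConfig(seed=1, n_genes=200, n_deg=30, n_terms=5,
                        term_size_range=(20, 20), planted_term_overlap=1.0, n_planted_terms=1)
        planted_genes = cfg.gene_ids()[:30]
        annotations, planted = gen_annotations(cfg, planted_genes=planted_genes)
        (term,) = planted
        assert annotations[term] <= set(planted_genes)

    def test_zero_overlap_not_enriched(self):
        from netpharm.enrichment import hypergeom_ora

        cfg = SimConfig(seed=2, n_genes=1000, n_deg=50, n_terms=10,
                        term_size_range=(30, 30), planted_term_overlap=0.0, n_planted_terms=2)
        study = cfg.gene_ids()[:50]
        annotations, planted = gen_annotations(cfg, planted_genes=study)
        out = hypergeom_ora(study, annotations, universe=cfg.gene_ids(), p_max=0.01)
        assert not (planted & set(out["term_id"]))

    def test_terms_within_universe(self):
        cfg = SimConfig(seed=3)
        annotations, _ = gen_annotations(cfg, planted_genes=cfg.gene_ids()[:100])
        universe = set(cfg.gene_ids())
        assert all(genes <= universe for genes in annotations.values())


class TestBundle:
    def test_bundle_determinism(self):
        a = gen_bundle(SimConfig(seed=9, n_genes=200, n_deg=20, interactome_nodes=80))
        b = gen_bundle(SimConfig(seed=9, n_genes=200, n_deg=20, interactome_nodes=80))
        assert (a.expression.to_numpy() == b.expression.to_numpy()).all()
        assert sorted(a.interactome.edges) == sorted(b.interactome.edges)
        assert a.compound_targets == b.compound_targets
        assert a.annotations == b.annotations
        assert a.truth["degs"] == b.truth["degs"]

    def test_truth_subsets_of_universe(self, bundle):
        universe = set(bundle.config.gene_ids())
        assert set(bundle.truth["degs"]) <= universe
        assert bundle.truth["hubs"] <= set(bundle.interactome.nodes) <= universe
        assert bundle.truth["enriched_terms"] <= set(bundle.annotations)

    def test_write_bundle_files(self, bundle, tmp_path):
        paths = write_bundle(bundle, tmp_path / "out")
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
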