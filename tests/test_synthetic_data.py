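import dataclasses

import networkx as nx
import numpy as np
import pytest

from crosstalknet.synthetic_data import (
    SimulationConfig,
    simulate_expression,
    simulate_genesets,
    simulate_network,
    simulate_tissue_panel,
)
from crosstalknet.topology import powerlaw_fit


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"frac_down": 1.5},
            {"inhibitory_fraction": -0.1},
            {"conditions": ("mock", "A", "A")},
            {"conditions": ("A", "B")},  # no mock
            {"n_exclusive_focal": 10**6},
            {"geneset_size_range": (5, 2)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()

    def test_planted_counts_exceeding_genes_rejected(self):
        cfg = SimulationConfig(n_genes=30, n_exclusive_focal=71)
        with pytest.raises(ValueError):
            simulate_expression(cfg)


class TestExpression:
    def test_shape_and_determinism(self, small_config):
        expr1, _ = simulate_expression(small_config)
        expr2, _ = simulate_expression(small_config)
        n_samples = len(small_config.conditions) * small_config.n_replicates
        assert expr1.values.shape == (small_config.n_genes, n_samples)
        assert expr1.values.equals(expr2.values)

    def test_truth_consistency(self, small_scenario):
        expr, truth, _, _ = small_scenario
        genes = set(expr.gene_ids)
        for table in truth.planted_degs.values():
            assert set(table) <= genes
        for members in truth.exclusive_degs.values():
            assert set(members) <= genes

    def test_exclusive_sets_are_exclusive(self, small_scenario):
        _, truth, _, _ = small_scenario
        for c, members in truth.exclusive_degs.items():
            assert set(members) <= set(truth.planted_degs[c])
            for other, table in truth.planted_degs.items():
                if other != c:
                    assert not set(members) & set(table)

    def test_exclusive_focal_count_matches_config(self, small_config, small_scenario):
        _, truth, _, _ = small_scenario
        assert len(truth.exclusive_degs[small_config.focal]) == small_config.n_exclusive_focal

    def test_planted_effect_recovered(self, small_config, small_scenario):
        """Empirical log2FC of planted DEGs is within 3.0 +/- 0.5 per gene and
        the mean absolute effect is within 10% of the planted size."""
        expr, truth, _, _ = small_scenario
        focal = small_config.focal
        fc = (
            expr.condition_values(focal).mean(axis=1)
            - expr.condition_values("mock").mean(axis=1)
        )
        effects = {g: e for g, e in truth.planted_degs[focal].items()}
        observed = np.array([fc[g] for g in effects])
        expected = np.array(list(effects.values()))
        # mean of 3 N(3, .25) draws minus mean of 3 N(0, .25): sd ~ 0.20,
        # so each gene lands within +/- 0.5 with ~99% probability
        assert np.mean(np.abs(observed - expected) < 0.5) >= 0.95
        assert abs(np.mean(np.abs(observed)) - small_config.effect_size) < 0.1 * small_config.effect_size

    def test_no_planted_effects_means_flat_conditions(self):
        cfg = SimulationConfig(
            n_genes=300,
            n_degs_per_condition={c: 0 for c in SimulationConfig().conditions if c != "mock"},
            n_exclusive_focal=0,
            seed=5,
        )
        expr, truth = simulate_expression(cfg)
        assert all(len(t) == 0 for t in truth.planted_degs.values())
        fc = (
            expr.condition_values(cfg.focal).mean(axis=1)
            - expr.condition_values("mock").mean(axis=1)
        )
        # pure noise: mean difference of 3-replicate means, sd ~ 0.2
        assert np.abs(fc).max() < 1.0

    def test_down_fraction_near_planted(self):
        cfg = SimulationConfig(
            n_genes=800,
            n_degs_per_condition={"Doxo": 10, "E2": 10, "TNFa": 10,
                                  "Doxo+E2": 10, "Doxo+TNFa": 10, "Doxo+E2+TNFa": 200},
            n_exclusive_focal=200,
            seed=17,
        )
        _, truth = simulate_expression(cfg)
        signs = [v for v in truth.planted_degs[cfg.focal].values()]
        frac_down = np.mean([s < 0 for s in signs])
        assert abs(frac_down - 43 / 71) < 0.1


class TestNetwork:
    def test_determinism_and_size(self, small_config, small_scenario):
        _, truth, net, _ = small_scenario
        net2 = simulate_network(small_config, dataclasses.replace(truth))
        assert set(net.graph.edges) == set(net2.graph.edges)
        assert len(net.nodes) == small_config.network_size

    def test_inhibitory_share_near_default(self, small_scenario):
        _, _, net, _ = small_scenario
        counts = net.sign_counts()
        share = counts["inhibits"] / (counts["inhibits"] + counts["activates"])
        assert abs(share - 58 / 337) < 0.08

    def test_receptor_reaches_every_module_gene(self, small_scenario):
        _, truth, net, _ = small_scenario
        for r, module in truth.receptor_assignments.items():
            for g in module:
                assert nx.has_path(net.graph, r, g)

    def test_degree_distribution_has_negative_loglog_slope(self):
        cfg = SimulationConfig(n_genes=600, network_size=400, n_exclusive_focal=20,
                               n_degs_per_condition={"Doxo": 30, "Doxo+E2+TNFa": 40},
                               conditions=("mock", "Doxo", "Doxo+E2+TNFa"), seed=3)
        _, truth = simulate_expression(cfg)
        net = simulate_network(cfg, truth)
        _, b, _ = powerlaw_fit(net)
        assert b < 0

    def test_module_too_large_for_budget(self, small_config):
        cfg = dataclasses.replace(small_config, network_size=10)
        _, truth = simulate_expression(cfg)
        with pytest.raises(ValueError):
            simulate_network(cfg, truth)


class TestGenesets:
    def test_enriched_sets_cover_their_module(self, small_scenario):
        _, truth, _, collection = small_scenario
        assert truth.enriched_sets
        for name in truth.enriched_sets:
            receptor = name.split("_")[1]
            module = set(truth.receptor_assignments[receptor])
            overlap = len(module & set(collection.sets[name]))
            assert overlap >= 0.7 * len(module)

    def test_decoy_overlap_near_hypergeometric_mean(self, small_config, small_scenario):
        _, truth, _, collection = small_scenario
        module = set().union(*truth.receptor_assignments.values())
        decoys = [n for n in collection.names() if n not in truth.enriched_sets]
        overlaps, expected = [], []
        for name in decoys:
            s = len(collection.sets[name])
            overlaps.append(len(module & set(collection.sets[name])))
            expected.append(s * len(module) / small_config.n_genes)
        assert abs(np.mean(overlaps) - np.mean(expected)) < 2.0

    def test_empty_module_gets_no_enriched_set(self, small_config):
        _, truth = simulate_expression(small_config)
        truth.receptor_assignments = {"R1": []}
        collection = simulate_genesets(small_config, truth)
        assert truth.enriched_sets == []
        assert len(collection) == small_config.n_genesets


class TestTissuePanel:
    def test_default_tissue_count_and_determinism(self):
        cfg = SimulationConfig(n_genes=500, seed=9)
        panel, truth = simulate_tissue_panel(cfg)
        panel2, _ = simulate_tissue_panel(cfg)
        assert len(set(panel.design["condition"])) == 30
        assert panel.values.equals(panel2.values)
        assert len(truth.tissue_markers) == 30

    def test_marker_positive_after_centering(self):
        cfg = SimulationConfig(n_genes=400, n_tissues=5, seed=21)
        panel, truth = simulate_tissue_panel(cfg)
        centered = panel.values.sub(panel.values.mean(axis=1), axis=0)
        for t, markers in truth.tissue_markers.items():
            cols = panel.samples_of(t)
            assert (centered.loc[markers, cols].mean(axis=1) > 0).all()

    def test_non_marker_tissue_means_flat(self):
        cfg = SimulationConfig(n_genes=400, n_tissues=5, seed=21)
        panel, truth = simulate_tissue_panel(cfg)
        marked = set().union(*truth.tissue_markers.values())
        gene = next(g for g in panel.gene_ids if g not in marked)
        means = [panel.values.loc[gene, panel.samples_of(t)].mean()
                 for t in sorted(set(panel.design["condition"]))]
        assert np.ptp(means) < 1.0

    def test_overlapping_markers_rejected(self):
        cfg = SimulationConfig(n_genes=100, n_tissues=2, seed=0)
        with pytest.raises(ValueError, match="assigned to both"):
            simulate_tissue_panel(
                cfg, markers={"Tissue01": ["G0001"], "Tissue02": ["G0001"]}
            )
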