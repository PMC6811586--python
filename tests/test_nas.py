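"""NAS engine: formula closed forms, path oracle, enrichment exactness."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from crosstalknet.io_formats import BackgroundNetwork, GeneSetCollection
from crosstalknet.nas import (
    compute_nas,
    enrich_genesets,
    extract_subnetwork,
    map_molecules,
    nas_significance,
    run_nasfinder,
    score_receptors,
    weight_edges,
)


def signed_digraph(edges, receptors=()):
    g = nx.DiGraph()
    g.add_edges_from((u, v, {"sign": "activates"}) for u, v in edges)
    return BackgroundNetwork(graph=g, receptors=frozenset(receptors))


def brute_force_min_cost(graph: nx.DiGraph, source, target):
    """Minimum information cost over ALL simple paths, with lex tie-break."""
    best = None
    for path in nx.all_simple_paths(graph, source, target):
        cost = sum(graph.edges[u, v]["weight"] for u, v in zip(path, path[1:]))
        key = (round(cost, 9), tuple(path))
        if best is None or key < best:
            best = key
    return best


class TestMapMolecules:
    def test_partition(self):
        net = signed_digraph([("A", "B"), ("B", "C")])
        mapped, unmapped = map_molecules(net, ["A", "B", "Z"])
        assert mapped == ["A", "B"]
        assert unmapped == ["Z"]

    def test_all_mapped(self):
        net = signed_digraph([("A", "B")])
        assert map_molecules(net, ["A", "B"]) == (["A", "B"], [])

    def test_none_mapped_is_error(self):
        net = signed_digraph([("A", "B")])
        with pytest.raises(ValueError):
            map_molecules(net, ["X", "Y"])


class TestWeightEdges:
    def test_out_degree_four_gives_two_bits(self):
        net = signed_digraph([("h", t) for t in "abcd"])
        wnet = weight_edges(net)
        assert all(wnet.graph.edges["h", t]["weight"] == 2.0 for t in "abcd")

    def test_forced_step_is_free(self):
        net = signed_digraph([("a", "b")])
        wnet = weight_edges(net)
        assert wnet.graph.edges["a", "b"]["weight"] == 0.0

    def test_chain_cost_sums(self):
        net = signed_digraph([("r", "a"), ("r", "x"), ("a", "b")])
        wnet = weight_edges(net)
        cost = (
            wnet.graph.edges["r", "a"]["weight"] + wnet.graph.edges["a", "b"]["weight"]
        )
        assert cost == pytest.approx(1.0)  # -log2(1/2) + 0


class TestScoreReceptors:
    def test_full_coverage_zero_cost(self):
        edges = [(f"r", f"m{i}") for i in range(5)]
        # out-degree 5 would cost log2(5); use 5 separate chains instead
        net = signed_digraph(
            [("r", "a1"), ("a1", "m1")], receptors={"r"}
        )
        # single chain: r->a1->m1, out-degrees 1 -> zero cost
        wnet = weight_edges(net)
        table = score_receptors(wnet, ["m1"])
        assert table.loc[0, "score"] == pytest.approx(1.0)

    def test_formula_and_ranking(self):
        # r1 reaches m at cost 1 bit, r2 at 3 bits, both coverage 1
        net = signed_digraph(
            [("r1", "a"), ("r1", "x"), ("a", "m"),
             ("r2", "b"), ("r2", "c"), ("r2", "d"), ("r2", "e"),
             ("b", "f"), ("b", "g"), ("f", "m"), ("x", "x2")],
            receptors={"r1", "r2"},
        )
        wnet = weight_edges(net)
        table = score_receptors(wnet, ["m"]).set_index("receptor")
        assert table.loc["r1", "score"] == pytest.approx(1 / (1 + 1.0))
        assert table.loc["r2", "score"] == pytest.approx(1 / (1 + 3.0))
        assert table.index.tolist() == ["r1", "r2"]

    def test_unreaching_receptor_excluded(self):
        net = signed_digraph([("r1", "m"), ("x", "r2")], receptors={"r1", "r2"})
        table = score_receptors(weight_edges(net), ["m"])
        assert table["receptor"].tolist() == ["r1"]

    def test_no_receptor_reaches_error(self):
        net = signed_digraph([("m", "r1")], receptors={"r1"})
        with pytest.raises(ValueError, match="no receptor"):
            score_receptors(weight_edges(net), ["m"])


class TestExtractSubnetwork:
    def test_unique_path(self):
        net = signed_digraph([("r", "a"), ("a", "m")], receptors={"r"})
        sub = extract_subnetwork(weight_edges(net), "r", ["m"])
        assert set(sub.graph.nodes) == {"r", "a", "m"}
        assert sub.graph.number_of_edges() == 2
        assert sub.paths["m"] == (0.0, ("r", "a", "m"))

    def test_lexicographic_tie_break(self):
        net = signed_digraph([("r", "a"), ("r", "b"), ("a", "m"), ("b", "m")],
                             receptors={"r"})
        sub = extract_subnetwork(weight_edges(net), "r", ["m"])
        assert sub.paths["m"][1] == ("r", "a", "m")
        assert "b" not in sub.graph.nodes  # pruned

    def test_unreachable_listed_not_fatal(self):
        net = signed_digraph([("r", "m1"), ("x", "m2")], receptors={"r"})
        sub = extract_subnetwork(weight_edges(net), "r", ["m1", "m2"])
        assert sub.unreachable == ["m2"]

    def test_matches_exhaustive_enumeration(self, rng):
        """Min costs and kept paths equal brute force over all simple paths."""
        for trial in range(30):
            n = int(rng.integers(5, 11))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)), directed=True)
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            net = BackgroundNetwork(
                graph=nx.DiGraph(
                    (u, v, {"sign": "activates"}) for u, v in g.edges
                ),
                receptors=frozenset(),
            )
            if net.graph.number_of_edges() == 0:
                continue
            wnet = weight_edges(net)
            source = sorted(net.graph.nodes)[0]
            targets = [v for v in net.graph.nodes
                       if v != source and nx.has_path(net.graph, source, v)]
            if not targets:
                continue
            sub = extract_subnetwork(wnet, source, targets)
            for t in targets:
                cost, path = sub.paths[t]
                expected = brute_force_min_cost(wnet.graph, source, t)
                assert cost == pytest.approx(expected[0], abs=1e-9)
                assert tuple(path) == expected[1]


class TestComputeNas:
    def test_worked_example(self):
        # |P ∩ U| = 10, molecules in P with nfc {1.0, 0.5} -> (2 * 0.75)/10
        universe = [f"g{i}" for i in range(20)]
        P = universe[:10]
        mols = {"g0": 4.0, "g1": 2.0, "g15": 1.0}  # nfc 1.0, 0.5; g15 outside P
        out = compute_nas(P, mols, universe)
        assert out["nas"] == pytest.approx(0.15)
        assert out["k"] == 2 and out["size"] == 10

    def test_no_overlap_zero(self):
        out = compute_nas(["a", "b"], {"x": 1.0}, ["a", "b", "x"])
        assert out["nas"] == 0.0

    def test_upper_bound_one(self):
        mols = {"a": 2.0, "b": 2.0}
        out = compute_nas(["a", "b"], mols, ["a", "b", "c"])
        assert out["nas"] == pytest.approx(1.0)

    def test_rescaling_invariance(self):
        universe = [f"g{i}" for i in range(15)]
        mols = {"g0": 1.2, "g3": -0.7, "g9": 2.4}
        P = universe[:8]
        a = compute_nas(P, mols, universe)["nas"]
        b = compute_nas(P, {g: 7.0 * v for g, v in mols.items()}, universe)["nas"]
        assert a == pytest.approx(b)

    def test_adding_nonmolecule_gene_decreases_nas(self):
        universe = [f"g{i}" for i in range(15)]
        mols = {"g0": 1.0, "g1": 0.5}
        nas_small = compute_nas(universe[:5], mols, universe)["nas"]
        nas_big = compute_nas(universe[:6], mols, universe)["nas"]
        assert nas_big < nas_small

    def test_invariant_to_genes_outside_universe(self):
        universe = [f"g{i}" for i in range(10)]
        P = universe[:5] + ["alien1", "alien2"]
        mols = {"g0": 1.0, "g1": 0.5}
        assert compute_nas(P, mols, universe) == compute_nas(universe[:5], mols, universe)


class TestNasSignificance:
    def test_zero_observed_gives_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        mols = {"g20": 1.0}
        p = nas_significance(universe[:5], mols, universe, n_permutations=100, seed=0)
        assert p == 1.0

    def test_maximal_observed_hits_floor(self):
        universe = [f"g{i}" for i in range(40)]
        P = universe[:3]
        mols = {g: 5.0 for g in P}  # all of P, maximal nfc
        p = nas_significance(P, mols, universe, n_permutations=100, seed=0)
        assert p == pytest.approx(1 / 101)

    def test_universe_smaller_than_molecules(self):
        mols = {f"g{i}": 1.0 for i in range(5)}
        with pytest.raises(ValueError, match="universe"):
            nas_significance(["g0"], mols, ["g0", "g1"], n_permutations=100)


class TestEnrichGenesets:
    def test_exact_p_on_full_overlap(self):
        # 10 genes, set of 5, 5 members, overlap 5: p = 1/C(10,5)
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection(sets={"S": universe[:5]})
        out = enrich_genesets(universe[:5], coll, universe)
        assert out.loc["S", "p_hyper"] == pytest.approx(1 / math.comb(10, 5))

    def test_matches_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(10)]
        members = set(universe[:5])
        P = set(universe[3:8])
        coll = GeneSetCollection(sets={"S": sorted(P)})
        obs = len(members & P)
        count = sum(
            1 for draw in itertools.combinations(universe, 5)
            if len(set(draw) & P) >= obs
        )
        expected = count / math.comb(10, 5)
        out = enrich_genesets(sorted(members), coll, universe)
        assert out.loc["S", "p_hyper"] == pytest.approx(expected)

    def test_single_set_adjustment_identity(self):
        universe = [f"g{i}" for i in range(12)]
        coll = GeneSetCollection(sets={"S": universe[:4]})
        out = enrich_genesets(universe[:3], coll, universe)
        assert out.loc["S", "p_adj"] == out.loc["S", "p_hyper"]

    def test_bh_monotone_in_rank(self, rng):
        universe = [f"g{i}" for i in range(50)]
        sets = {f"S{j}": sorted(rng.choice(universe, size=8, replace=False))
                for j in range(15)}
        coll = GeneSetCollection(sets=sets)
        out = enrich_genesets(universe[:10], coll, universe)
        ordered = out.sort_values("p_hyper")
        assert (ordered["p_adj"].diff().dropna() >= -1e-12).all()
        assert (out["p_adj"] <= 1.0).all()
        assert (out["p_adj"] >= out["p_hyper"] - 1e-12).all()

    def test_empty_universe(self):
        coll = GeneSetCollection(sets={"S": ["a"]})
        with pytest.raises(ValueError):
            enrich_genesets([], coll, [])


class TestRunNasfinder:
    def _scenario(self):
        net = signed_digraph(
            [("r1", "a"), ("a", "m1"), ("a", "m2"), ("r2", "x"), ("x", "y")],
            receptors={"r1", "r2"},
        )
        coll = GeneSetCollection(
            sets={"hit": ["m1", "m2", "y"], "miss": ["x", "y"]}
        )
        mols = {"m1": 3.0, "m2": -2.0}
        return net, coll, mols

    def test_planted_receptor_and_set_win(self):
        net, coll, mols = self._scenario()
        run = run_nasfinder(mols, net, coll, n_permutations=100, seed=1)
        assert run["receptor_ranking"]["receptor"].iloc[0] == "r1"
        assert run["results"]["nas"].idxmax() == "hit"

    def test_disjoint_molecules_all_zero(self):
        net, _, mols = self._scenario()
        coll = GeneSetCollection(sets={"S1": ["x"], "S2": ["y"]})
        run = run_nasfinder(mols, net, coll, n_permutations=100, seed=1)
        assert (run["results"]["nas"] == 0).all()

    def test_seed_determinism(self):
        net, coll, mols = self._scenario()
        r1 = run_nasfinder(mols, net, coll, n_permutations=100, seed=5)
        r2 = run_nasfinder(mols, net, coll, n_permutations=100, seed=5)
        assert r1["results"].equals(r2["results"])
        assert r1["receptor_ranking"].equals(r2["receptor_ranking"])
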