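"""Receptor-anchored network enrichment and the Network Activity Score (NAS).

The engine maps molecules of interest (e.g. context-specific DEGs with
their fold changes) onto a directed background network, weights every edge
by its information cost, finds the receptors best connected to the
molecules, extracts pruned minimum-cost-path subnetworks, and scores
reference gene sets.

Edge weight: the self-information of a uniform random out-step,
``w(u -> v) = log2(outdegree(u))`` bits, so a path's cost is the number of
bits needed to specify it and minimum-cost paths are maximum-probability
random-walk paths.

Receptor score: ``coverage / (1 + mean path cost)`` where coverage is the
fraction of molecules reachable from the receptor and the mean is over
reached molecules' minimum path costs.

NAS for a reference set P on an analysis universe U:
``nas = k * mean_nfc / |P ∩ U|`` with ``k`` the number of molecules in
``P ∩ U`` and ``nfc(g) = |log2fc(g)| / max |log2fc|`` over the molecules
(so nas is invariant to rescaling all fold changes). Significance comes
from a permutation null (random molecule draws from U carrying the observed
nfc values) and a one-sided hypergeometric test with Benjamini-Hochberg
adjustment.

All tie-breaks are lexicographic so outputs are deterministic.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import BackgroundNetwork, GeneSetCollection

__all__ = [
    "WeightedNetwork",
    "ReceptorSubnetwork",
    "map_molecules",
    "weight_edges",
    "score_receptors",
    "extract_subnetwork",
    "compute_nas",
    "nas_significance",
    "enrich_genesets",
    "run_nasfinder",
]


@dataclass
class WeightedNetwork:
    """Background network plus per-edge information cost in bits."""

    net: BackgroundNetwork
    graph: nx.DiGraph  # same topology, edges carry 'weight' (bits)

    @property
    def receptors(self) -> frozenset[str]:
        return self.net.receptors


@dataclass
class ReceptorSubnetwork:
    """Union of minimum-cost paths from one receptor to its covered molecules."""

    receptor: str
    paths: dict[str, tuple[float, tuple[str, ...]]]  # molecule -> (cost, node sequence)
    graph: nx.DiGraph
    receptor_score: float
    unreachable: list[str] = field(default_factory=list)

    @property
    def covered_molecules(self) -> set[str]:
        return set(self.paths)


def map_molecules(
    net: BackgroundNetwork, molecules,
) -> tuple[list[str], list[str]]:
    """Intersect the molecule list with the network's node set.

    Returns (mapped, unmapped); unmapped names are reported, never silently
    dropped. An empty intersection is an error — there is nothing to
    analyze.
    """
    molecules = list(molecules)
    nodes = net.nodes
    mapped = sorted(m for m in molecules if m in nodes)
    unmapped = sorted(m for m in molecules if m not in nodes)
    if not mapped:
        raise ValueError("no molecule of interest maps onto the network")
    return mapped, unmapped


def weight_edges(net: BackgroundNetwork) -> WeightedNetwork:
    """Assign each edge u->v the cost log2(outdegree(u)) bits."""
    graph = nx.DiGraph()
    graph.add_nodes_from(net.graph.nodes)
    for u, v, data in net.graph.edges(data=True):
        w = float(np.log2(net.graph.out_degree(u)))
        graph.add_edge(u, v, weight=w, sign=data.get("sign"))
    return WeightedNetwork(net=net, graph=graph)


def _min_cost_paths(
    graph: nx.DiGraph, source: str
) -> dict[str, tuple[float, tuple[str, ...]]]:
    """Single-source minimum-cost paths with lexicographic tie-breaking.

    Dijkstra on keys (cost, node-sequence): among equal-cost paths the
    lexicographically smallest node sequence wins. Valid because edge
    weights are non-negative and a path's key never sorts below its own
    prefix's key.
    """
    best: dict[str, tuple[float, tuple[str, ...]]] = {}
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (cost, path)
        for succ in graph.successors(node):
            if succ not in best:
                heapq.heappush(heap, (cost + graph.edges[node, succ]["weight"], path + (succ,)))
    return best


def score_receptors(wnet: WeightedNetwork, molecules) -> pd.DataFrame:
    """Rank receptors by coverage / (1 + mean minimum path cost).

    Receptors reaching no molecule score 0 and are excluded from the
    ranking; ties break lexicographically on the receptor name.
    """
    molecules = sorted(set(molecules))
    if not wnet.receptors:
        raise ValueError("network defines no receptors")
    rows = []
    for r in sorted(wnet.receptors):
        paths = _min_cost_paths(wnet.graph, r)
        reached = [m for m in molecules if m in paths and m != r]
        coverage = len(reached) / len(molecules)
        if reached:
            mean_cost = float(np.mean([paths[m][0] for m in reached]))
            score = coverage / (1.0 + mean_cost)
        else:
            mean_cost, score = np.nan, 0.0
        rows.append((r, coverage, mean_cost, score))
    table = pd.DataFrame(rows, columns=["receptor", "coverage", "mean_cost", "score"])
    table = table[table["score"] > 0]
    if table.empty:
        raise ValueError("no receptor reaches any molecule of interest")
    return (
        table.sort_values(["score", "receptor"], ascending=[False, True])
        .reset_index(drop=True)
    )


def extract_subnetwork(wnet: WeightedNetwork, receptor: str, molecules) -> ReceptorSubnetwork:
    """Minimum-cost paths receptor -> each molecule, pruned to their union."""
    molecules = sorted(set(molecules))
    all_paths = _min_cost_paths(wnet.graph, receptor)
    kept: dict[str, tuple[float, tuple[str, ...]]] = {}
    unreachable: list[str] = []
    for m in molecules:
        if m == receptor:
            continue
        if m in all_paths:
            kept[m] = all_paths[m]
        else:
            unreachable.append(m)
    if not kept:
        raise ValueError(f"receptor {receptor!r} reaches no molecule")

    sub = nx.DiGraph()
    for cost, path in kept.values():
        for u, v in zip(path, path[1:]):
            sub.add_edge(u, v, **wnet.graph.edges[u, v])
    reached = [m for m in kept]
    costs = [kept[m][0] for m in reached]
    coverage = len(reached) / len(molecules)
    score = coverage / (1.0 + float(np.mean(costs)))
    return ReceptorSubnetwork(
        receptor=receptor,
        paths=kept,
        graph=sub,
        receptor_score=score,
        unreachable=unreachable,
    )


def _nfc(molecules_with_fc: dict[str, float]) -> dict[str, float]:
    max_fc = max(abs(v) for v in molecules_with_fc.values())
    if max_fc == 0:
        raise ValueError("all molecule fold changes are zero")
    return {g: abs(v) / max_fc for g, v in molecules_with_fc.items()}


def compute_nas(
    P, molecules_with_fc: dict[str, float], universe,
) -> dict | None:
    """NAS score fields for one reference set (None if P misses the universe)."""
    universe = set(universe)
    pset = set(P) & universe
    if not pset:
        warnings.warn("gene set has no member in the analysis universe; skipped", stacklevel=2)
        return None
    nfc = _nfc(molecules_with_fc)
    hits = sorted(set(nfc) & pset)
    k = len(hits)
    mean_nfc = float(np.mean([nfc[g] for g in hits])) if hits else 0.0
    nas = k * mean_nfc / len(pset) if k else 0.0
    return {"k": k, "size": len(pset), "mean_nfc": mean_nfc, "nas": nas}


def nas_significance(
    P,
    molecules_with_fc: dict[str, float],
    universe,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for one set's NAS under random molecule placement.

    The null redraws |molecules| genes uniformly (without replacement) from
    the universe and reassigns the observed nfc values to them;
    p = (1 + #{null NAS >= observed}) / (1 + B).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    universe = sorted(set(universe))
    if len(set(molecules_with_fc)) > len(universe):
        raise ValueError("universe smaller than molecule list")
    obs = compute_nas(P, molecules_with_fc, universe)
    if obs is None:
        return float("nan")
    mols = sorted(set(molecules_with_fc) & set(universe))
    nfc_values = [abs(molecules_with_fc[g]) for g in mols]
    pset = set(P) & set(universe)
    rng = np.random.default_rng(seed)
    universe_arr = np.array(universe)
    exceed = 0
    max_fc = max(nfc_values)
    nfc_norm = np.array(nfc_values) / max_fc
    for _ in range(n_permutations):
        draw = universe_arr[rng.choice(len(universe_arr), size=len(mols), replace=False)]
        in_p = np.fromiter((g in pset for g in draw), dtype=bool)
        k = int(in_p.sum())
        nas_null = k * float(nfc_norm[in_p].mean()) / len(pset) if k else 0.0
        if nas_null >= obs["nas"]:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)


def enrich_genesets(
    member_genes, collection: GeneSetCollection, universe,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of *member_genes* in each set.

    Members and sets are intersected with the universe; p values are
    BH-adjusted across all tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    members = set(member_genes) & universe
    if not set(member_genes) <= universe:
        stray = sorted(set(member_genes) - universe)
        raise ValueError(f"member genes outside the universe: {stray[:10]}")
    N, n = len(universe), len(members)
    rows = []
    for name in collection.names():
        pset = set(collection.sets[name]) & universe
        if not pset:
            warnings.warn(f"set {name!r} has no member in the universe; skipped", stacklevel=2)
            continue
        K = len(pset)
        k = len(members & pset)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, p))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p_hyper"])
    if len(table):
        table["p_adj"] = multipletests(table["p_hyper"], method="fdr_bh")[1]
    else:
        table["p_adj"] = []
    return table.set_index("set")


def run_nasfinder(
    molecules_with_fc: dict[str, float],
    net: BackgroundNetwork,
    collection: GeneSetCollection,
    universe=None,
    top_receptors: int = 3,
    n_permutations: int = 1000,
    seed: int = 0,
    min_set_size: int = 1,
) -> dict:
    """Full receptor-anchored enrichment run.

    Maps molecules, weights edges, ranks receptors, extracts pruned
    subnetworks for the top ``top_receptors`` receptors, and scores every
    reference set (NAS + permutation p + hypergeometric p with BH
    adjustment) using the molecules covered by those subnetworks. The
    analysis universe defaults to the network's node set intersected with
    the genes fold changes are known for — pass ``universe`` (e.g. all
    genes on both the expression matrix and the network) to widen it.

    ``min_set_size`` drops reference sets with fewer than that many genes
    on the analysis universe before scoring: the NAS favors small sets
    (its denominator is the in-universe set size), so near-empty
    intersections produce unstable scores. 1 disables the filter.
    """
    mapped, unmapped = map_molecules(net, molecules_with_fc)
    wnet = weight_edges(net)
    ranking = score_receptors(wnet, mapped)
    top = ranking["receptor"].head(top_receptors).tolist()
    subnetworks = {r: extract_subnetwork(wnet, r, mapped) for r in top}

    covered = sorted(set().union(*(s.covered_molecules for s in subnetworks.values())))
    mols = {g: molecules_with_fc[g] for g in covered}
    if universe is None:
        universe = sorted(net.nodes)
    universe = sorted(set(universe) | set(covered))

    universe_set = set(universe)
    kept_names = [
        name for name in collection.names()
        if len(set(collection.sets[name]) & universe_set) >= min_set_size
    ]
    kept = GeneSetCollection(
        sets={n: collection.sets[n] for n in kept_names},
        descriptions={n: collection.descriptions.get(n, "") for n in kept_names},
    )
    enr = enrich_genesets(covered, kept, universe)
    rows = []
    for i, name in enumerate(kept.names()):
        score = compute_nas(kept.sets[name], mols, universe)
        if score is None:
            continue
        p_perm = nas_significance(
            kept.sets[name], mols, universe,
            n_permutations=n_permutations, seed=seed + i,
        )
        rows.append({"set": name, **score, "p_perm": p_perm})
    results = pd.DataFrame(rows).set_index("set")
    results = results.join(enr[["p_hyper", "p_adj"]], how="left")
    results = results.sort_values(["nas", "set"], ascending=[False, True], kind="stable")
    return {
        "mapped": mapped,
        "unmapped": unmapped,
        "receptor_ranking": ranking,
        "subnetworks": subnetworks,
        "results": results,
    }
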