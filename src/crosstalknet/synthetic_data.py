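"""Synthetic data with known planted structure.

Generates the four kinds of input the pipeline consumes — a treatment
expression matrix, a signed directed background network, a gene-set
collection and a multi-tissue expression panel — together with a
:class:`GroundTruth` manifest of everything that was planted, so each
downstream stage can be tested for recovery without external data.

The default design emulates a combinatorial-treatment microarray study on a
breast-cancer cell line: a mock control plus six treatments (three agents
singly and in combination), three replicates each, with a block of genes
differential exclusively under the triple treatment. The default exclusive
count (71) and down-regulated fraction (43/71) mirror the magnitudes such
studies report; the network's inhibitory edge share defaults to 58/337.

Noise model: each gene draws a baseline log2 level uniformly from
``baseline_mean_range``; replicate values add i.i.d. Gaussian noise of
``noise_sd``; a planted gene x condition effect shifts that condition's mean
by ``±effect_size``. No probe-level artifacts, normalization effects or
batch structure are simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import BackgroundNetwork, ExpressionMatrix, GeneSetCollection

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_network",
    "simulate_genesets",
    "simulate_tissue_panel",
]

#: Default treatment design: mock control plus six single/combination arms.
DEFAULT_CONDITIONS = ("mock", "Doxo", "E2", "TNFa", "Doxo+E2", "Doxo+TNFa", "Doxo+E2+TNFa")

_DEFAULT_DEG_COUNTS = {
    "Doxo": 120,
    "E2": 100,
    "TNFa": 90,
    "Doxo+E2": 110,
    "Doxo+TNFa": 110,
    "Doxo+E2+TNFa": 150,
}

# independent RNG streams per generator so call order never matters
_STREAM = {"expression": 1, "network": 2, "genesets": 3, "tissue": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], seed])


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the emulated design as defaults."""

    n_genes: int = 2000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    noise_sd: float = 0.25
    effect_size: float = 3.0  # above the |log2FC| > 2 calling threshold
    n_degs_per_condition: dict[str, int] | None = None
    n_exclusive_focal: int = 71
    frac_down: float = 43 / 71
    network_size: int = 300
    edges_per_node: int = 2
    inhibitory_fraction: float = 58 / 337
    n_receptors: int = 3
    n_wired_receptors: int = 1
    n_genesets: int = 20
    geneset_size_range: tuple[int, int] = (10, 60)
    n_tissues: int = 30
    n_markers_per_tissue: int = 10
    n_panel_replicates: int = 10  # multi-tissue reference panels are deeply sampled
    seed: int = 0

    @property
    def focal(self) -> str:
        """The focal condition (last label, the full combination treatment)."""
        return self.conditions[-1]

    @property
    def deg_counts(self) -> dict[str, int]:
        if self.n_degs_per_condition is not None:
            return dict(self.n_degs_per_condition)
        counts = {c: _DEFAULT_DEG_COUNTS.get(c, 100) for c in self.conditions if c != "mock"}
        return counts

    def validate(self) -> None:
        counts = [
            self.n_genes,
            self.n_replicates,
            self.network_size,
            self.edges_per_node,
            self.n_receptors,
            self.n_genesets,
            self.n_tissues,
            self.n_markers_per_tissue,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        for name, frac in (("frac_down", self.frac_down),
                           ("inhibitory_fraction", self.inhibitory_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if "mock" not in self.conditions:
            raise ValueError("a 'mock' control condition is required")
        if any(n < 0 for n in self.deg_counts.values()):
            raise ValueError("DEG counts must be non-negative")
        if self.n_exclusive_focal > self.deg_counts.get(self.focal, 0):
            raise ValueError("n_exclusive_focal exceeds the focal condition's DEG count")
        lo, hi = self.geneset_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid geneset_size_range")
        if self.n_wired_receptors > self.n_receptors:
            raise ValueError("n_wired_receptors exceeds n_receptors")


@dataclass
class GroundTruth:
    """Manifest of planted structure; the oracle for recovery tests.

    ``planted_degs`` maps condition -> {gene: signed effect size};
    ``exclusive_degs`` maps condition -> genes planted in that condition
    only; ``receptor_assignments`` maps each wired receptor to its
    downstream module; ``enriched_sets`` names the gene sets built to
    overlap planted modules; ``tissue_markers`` maps tissue -> its
    up-regulated marker genes.
    """

    planted_degs: dict[str, dict[str, float]] = field(default_factory=dict)
    exclusive_degs: dict[str, list[str]] = field(default_factory=dict)
    receptor_assignments: dict[str, list[str]] = field(default_factory=dict)
    enriched_sets: list[str] = field(default_factory=list)
    tissue_markers: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the treatment expression matrix and its ground truth.

    Planted DEG sets are constructed so that exactly ``n_exclusive_focal``
    genes are differential only under the focal condition: non-focal
    conditions draw nested prefixes from a shared pool (so they overlap one
    another), and the focal condition combines fresh exclusive genes with a
    prefix of that same pool.
    """
    config.validate()
    rng = _rng(config.seed, "expression")
    genes = _gene_names(config.n_genes)
    counts = config.deg_counts
    focal = config.focal
    non_focal = [c for c in config.conditions if c not in ("mock", focal)]

    pool_size = max((counts.get(c, 0) for c in non_focal), default=0)
    n_shared_focal = counts.get(focal, 0) - config.n_exclusive_focal
    if n_shared_focal > pool_size:
        raise ValueError(
            "focal non-exclusive DEG count exceeds the union of other conditions' DEGs; "
            "raise another condition's count or n_exclusive_focal"
        )
    n_planted_total = config.n_exclusive_focal + pool_size
    if n_planted_total > config.n_genes:
        raise ValueError("planted DEG counts exceed n_genes")

    chosen = rng.choice(config.n_genes, size=n_planted_total, replace=False)
    exclusive = [genes[i] for i in chosen[: config.n_exclusive_focal]]
    pool = [genes[i] for i in chosen[config.n_exclusive_focal:]]

    # one sign per gene, consistent across conditions
    sign_of = {
        g: (-1.0 if rng.random() < config.frac_down else 1.0)
        for g in exclusive + pool
    }

    planted: dict[str, dict[str, float]] = {}
    for c in non_focal:
        members = pool[: counts.get(c, 0)]
        planted[c] = {g: sign_of[g] * config.effect_size for g in members}
    if focal != "mock":
        members = exclusive + pool[:n_shared_focal]
        planted[focal] = {g: sign_of[g] * config.effect_size for g in members}

    exclusive_degs: dict[str, list[str]] = {}
    for c, table in planted.items():
        others = set().union(*(planted[o].keys() for o in planted if o != c))
        exclusive_degs[c] = sorted(set(table) - others)

    baselines = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    sample_ids, cond_of = [], []
    for c in config.conditions:
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{c}_r{r}")
            cond_of.append(c)
    n_samples = len(sample_ids)

    values = baselines[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    for c, table in planted.items():
        cols = [j for j, cc in enumerate(cond_of) if cc == c]
        for g, eff in table.items():
            values[gene_index[g], cols] += eff

    vdf = pd.DataFrame(values, index=genes, columns=sample_ids)
    design = pd.DataFrame(
        {
            "condition": cond_of,
            "replicate": [s.rsplit("_r", 1)[1] for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    expr = ExpressionMatrix(values=vdf, design=design)
    truth = GroundTruth(
        planted_degs={c: dict(sorted(t.items())) for c, t in planted.items()},
        exclusive_degs=exclusive_degs,
    )
    return expr, truth


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def simulate_network(config: SimulationConfig, truth: GroundTruth) -> BackgroundNetwork:
    """Grow a scale-free signed directed network with receptors wired
    upstream of planted modules.

    A preferential-attachment skeleton is grown first and each edge oriented
    at random; the focal condition's exclusive genes are partitioned among
    the first ``n_wired_receptors`` receptors as their modules, and any
    module gene not already reachable from its receptor gets a direct
    activating edge, so plantedness is guaranteed rather than probabilistic.
    Updates ``truth.receptor_assignments`` in place.
    """
    config.validate()
    rng = _rng(config.seed, "network")
    focal_excl = truth.exclusive_degs.get(config.focal, [])
    receptors = [f"R{i}" for i in range(1, config.n_receptors + 1)]

    n_gene_nodes = config.network_size - config.n_receptors
    if len(focal_excl) > n_gene_nodes:
        raise ValueError("network_size too small to contain the planted module genes")

    all_genes = sorted({g for t in truth.planted_degs.values() for g in t})
    background = [g for g in _gene_names_from_truth(truth, config) if g not in set(focal_excl)]
    fill = [g for g in background if g not in set(all_genes)]
    others = [g for g in all_genes if g not in set(focal_excl)]
    gene_nodes = list(focal_excl)
    for src in (others, fill):
        for g in src:
            if len(gene_nodes) >= n_gene_nodes:
                break
            gene_nodes.append(g)
    if len(gene_nodes) < n_gene_nodes:
        raise ValueError("not enough genes to fill network_size")

    node_names = gene_nodes + receptors
    order = rng.permutation(len(node_names))
    m = min(config.edges_per_node, len(node_names) - 1)
    skeleton = nx.barabasi_albert_graph(len(node_names), m, seed=int(rng.integers(2**31)))
    relabel = {i: node_names[order[i]] for i in skeleton.nodes}

    graph = nx.DiGraph()
    graph.add_nodes_from(node_names)
    for u, v in sorted(skeleton.edges):
        a, b = relabel[u], relabel[v]
        if rng.random() < 0.5:
            a, b = b, a
        sign = "inhibits" if rng.random() < config.inhibitory_fraction else "activates"
        graph.add_edge(a, b, sign=sign)

    # partition the focal module among the wired receptors; rest are decoys
    wired = receptors[: config.n_wired_receptors]
    assignments: dict[str, list[str]] = {r: [] for r in wired}
    for i, g in enumerate(focal_excl):
        assignments[wired[i % len(wired)]].append(g)
    for r, module in assignments.items():
        for g in module:
            if not nx.has_path(graph, r, g):
                graph.add_edge(r, g, sign="activates")
    truth.receptor_assignments = {r: sorted(m) for r, m in assignments.items()}

    return BackgroundNetwork(graph=graph, receptors=frozenset(receptors))


def _gene_names_from_truth(truth: GroundTruth, config: SimulationConfig) -> list[str]:
    return _gene_names(config.n_genes)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def simulate_genesets(config: SimulationConfig, truth: GroundTruth) -> GeneSetCollection:
    """Build a gene-set collection with one enriched set per planted module.

    An enriched set carries at least 70% of its module plus uniform
    background genes; decoy sets are drawn uniformly from the gene universe.
    Enriched set names are recorded in ``truth.enriched_sets``.
    """
    config.validate()
    rng = _rng(config.seed, "genesets")
    genes = _gene_names(config.n_genes)
    lo, hi = config.geneset_size_range

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    enriched_names: list[str] = []
    for r, module in sorted(truth.receptor_assignments.items()):
        if not module:
            continue
        n_core = math.ceil(0.7 * len(module))
        core = list(rng.choice(module, size=n_core, replace=False))
        target = int(rng.integers(max(lo, n_core), hi + 1))
        background = [g for g in genes if g not in set(module)]
        extra = list(rng.choice(background, size=target - n_core, replace=False))
        name = f"SET_{r}_module"
        if not lo <= target <= hi:
            raise ValueError(f"enriched set size {target} outside geneset_size_range")
        sets[name] = sorted(core + extra)
        descriptions[name] = f"planted: overlaps the module wired to receptor {r}"
        enriched_names.append(name)

    n_decoys = config.n_genesets - len(enriched_names)
    for i in range(1, n_decoys + 1):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET_decoy_{i:03d}"
        sets[name] = sorted(rng.choice(genes, size=size, replace=False))
        descriptions[name] = "decoy: uniform draw from the gene universe"

    truth.enriched_sets = enriched_names
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# tissue panel
# ---------------------------------------------------------------------------


def simulate_tissue_panel(
    config: SimulationConfig,
    markers: dict[str, list[str]] | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a multi-tissue panel with planted tissue-specific markers.

    Each of ``n_tissues`` tissues contributes ``n_panel_replicates`` samples
    (deeper than the treatment design, as tissue reference panels are);
    each tissue's marker genes are up-shifted by ``effect_size`` in that
    tissue only. Pass *markers* to plant a chosen tissue -> gene assignment
    (assignments must not overlap across tissues); by default markers are
    drawn disjointly at random.
    """
    config.validate()
    if config.n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = _rng(config.seed, "tissue")
    genes = _gene_names(config.n_genes)
    tissues = [f"Tissue{i:02d}" for i in range(1, config.n_tissues + 1)]

    if markers is None:
        need = config.n_tissues * config.n_markers_per_tissue
        if need > config.n_genes:
            raise ValueError("marker assignments exceed n_genes")
        chosen = rng.choice(config.n_genes, size=need, replace=False)
        markers = {
            t: sorted(genes[i] for i in chosen[k * config.n_markers_per_tissue:
                                               (k + 1) * config.n_markers_per_tissue])
            for k, t in enumerate(tissues)
        }
    else:
        tissues = sorted(set(tissues) | set(markers))
        seen: dict[str, str] = {}
        for t, gl in markers.items():
            for g in gl:
                if g in seen:
                    raise ValueError(f"marker {g!r} assigned to both {seen[g]!r} and {t!r}")
                if g not in set(genes):
                    raise ValueError(f"marker {g!r} not among the panel's genes")
                seen[g] = t

    sample_ids, tissue_of = [], []
    for t in tissues:
        for r in range(1, config.n_panel_replicates + 1):
            sample_ids.append(f"{t}_s{r}")
            tissue_of.append(t)

    baselines = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    values = baselines[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(sample_ids))
    )
    gene_index = {g: i for i, g in enumerate(genes)}
    for t, gl in markers.items():
        cols = [j for j, tt in enumerate(tissue_of) if tt == t]
        for g in gl:
            values[gene_index[g], cols] += config.effect_size

    vdf = pd.DataFrame(values, index=genes, columns=sample_ids)
    design = pd.DataFrame(
        {
            "condition": tissue_of,
            "replicate": [s.rsplit("_s", 1)[1] for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    expr = ExpressionMatrix(values=vdf, design=design)
    truth = GroundTruth(tissue_markers={t: sorted(gl) for t, gl in markers.items()})
    return expr, truth
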