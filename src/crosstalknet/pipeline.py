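"""End-to-end orchestration: simulate/load inputs, run every stage, write a manifest.

``run_all`` executes DEG calling -> CS-DEG extraction -> PLS-DA -> receptor-
anchored NAS -> integrated-network topology -> tissue enrichment in order,
each stage reading only prior-stage outputs, and writes a JSON manifest
recording the package version, every stage parameter, the derived per-stage
seeds and SHA-256 digests of all input files. Identical config means an
identical result bundle.

``make_demo`` emits a desk-scale synthetic scenario (expression matrix for
the 6-treatment + mock design, signed scale-free network with one wired
receptor, gene sets with one planted enriched set, 30-tissue panel whose
first tissue's markers are drawn from the focal exclusive genes) plus a
ready-to-run config.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .csdeg import direction_summary, extract_cs_degs, foldchange_concordance
from .io_formats import (
    read_expression,
    read_gmt,
    read_network,
    write_expression,
    write_gmt,
    write_network,
)
from .nas import run_nasfinder
from .plsda import confidence_ellipse, cross_validate, fit_plsda
from .rankprod import rank_product_test
from .synthetic_data import (
    GroundTruth,
    SimulationConfig,
    simulate_expression,
    simulate_genesets,
    simulate_network,
    simulate_tissue_panel,
)
from .tissue import build_tissue_deg_sets, enrich_query
from .topology import centrality_report, integrate_network

__all__ = ["PipelineConfig", "run_all", "make_demo", "stage_seed"]

_STAGES = ("deg", "csdeg", "plsda", "nas", "topology", "tissue")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed from the global seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass
class PipelineConfig:
    """Paths to every input plus per-stage parameter blocks."""

    expression: str
    design: str
    network: str
    receptors: str
    genesets: str
    panel: str
    panel_design: str
    out_dir: str
    seed: int = 0
    deg: dict = field(default_factory=lambda: {
        "control": "mock", "permutations": 200, "pfp_max": 0.05, "lfc_min": 2.0,
    })
    csdeg: dict = field(default_factory=lambda: {
        "focal": "Doxo+E2+TNFa",
        "direction_aware": False,
        "concordance_doubles": ["Doxo+TNFa", "Doxo+E2"],
    })
    plsda: dict = field(default_factory=lambda: {
        "folds": 5, "repeats": 10, "max_components": 10, "ellipse_level": 0.954,
    })
    nas: dict = field(default_factory=lambda: {
        "top_receptors": 3, "permutations": 500, "min_set_size": 10,
    })
    topology: dict = field(default_factory=lambda: {"directed": True})
    tissue: dict = field(default_factory=lambda: {"p_max": 0.05, "lfc_min": 0.58})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def input_paths(self) -> dict[str, str]:
        return {
            "expression": self.expression,
            "design": self.design,
            "network": self.network,
            "receptors": self.receptors,
            "genesets": self.genesets,
            "panel": self.panel,
            "panel_design": self.panel_design,
        }

    def validate(self) -> None:
        missing = [f"{k}: {v}" for k, v in self.input_paths().items() if not Path(v).is_file()]
        if missing:
            raise FileNotFoundError("missing input files: " + "; ".join(missing))


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the result bundle.

    Returns a dict of in-memory results (deg tables, CS-DEG set, PLS-DA
    model/accuracy, NAS run, topology report, tissue enrichment, manifest).
    Raises with the failing stage's name; partial outputs stay on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in _STAGES}
    results: dict = {}

    expr = read_expression(config.expression, config.design)
    net = read_network(config.network, config.receptors)
    collection = read_gmt(config.genesets)
    panel = read_expression(config.panel, config.panel_design)

    stage = "deg"
    try:
        control = config.deg["control"]
        conditions = [c for c in expr.conditions if c != control]
        deg_tables: dict[str, pd.DataFrame] = {}
        for i, cond in enumerate(conditions):
            deg_tables[cond] = rank_product_test(
                expr, cond, control,
                n_permutations=config.deg["permutations"],
                seed=seeds["deg"] + 2 * i,
                pfp_max=config.deg["pfp_max"],
                lfc_min=config.deg["lfc_min"],
            )
            _write_tsv(deg_tables[cond], out / f"deg_{_slug(cond)}.tsv", "gene")
        results["deg"] = deg_tables

        stage = "csdeg"
        cs = extract_cs_degs(
            deg_tables, config.csdeg["focal"],
            direction_aware=config.csdeg["direction_aware"],
        )
        _write_tsv(cs.genes, out / "cs_degs.tsv", "gene")
        up, down = direction_summary(cs)
        results["csdeg"] = cs
        results["csdeg_directions"] = {"up": up, "down": down}

        # double-vs-triple fold-change concordance, over genes called in
        # the focal or either double contrast
        doubles = [d for d in config.csdeg.get("concordance_doubles", [])
                   if d in deg_tables]
        if len(doubles) == 2:
            focal_t = deg_tables[config.csdeg["focal"]]
            union = sorted(
                set().union(*(
                    set(deg_tables[c].index[deg_tables[c]["direction"] != "none"])
                    for c in (config.csdeg["focal"], *doubles)
                ))
            )
            report = foldchange_concordance(
                focal_t.loc[union, "log2fc"],
                deg_tables[doubles[0]].loc[union, "log2fc"],
                deg_tables[doubles[1]].loc[union, "log2fc"],
                names=(doubles[0], doubles[1]),
            )
            (out / "cs_concordance.json").write_text(
                json.dumps(report, indent=2, sort_keys=True)
            )
            results["concordance"] = report

        stage = "plsda"
        deg_union = sorted(set().union(*(set(t.index[t["direction"] != "none"]) for t in deg_tables.values())))
        treated = [s for s in expr.sample_ids
                   if expr.design.at[s, "condition"] != control]
        X = expr.values.loc[deg_union, treated].T
        labels = [expr.design.at[s, "condition"] for s in treated]
        acc_table, chosen = cross_validate(
            X, labels,
            folds=config.plsda["folds"],
            repeats=config.plsda["repeats"],
            max_components=config.plsda["max_components"],
            seed=seeds["plsda"],
        )
        model = fit_plsda(X, labels, chosen)
        scores = pd.DataFrame(
            model.x_scores[:, : min(2, chosen)],
            index=treated,
            columns=[f"comp{i+1}" for i in range(min(2, chosen))],
        )
        scores["condition"] = labels
        ellipses = {}
        if chosen >= 2:
            for lab in sorted(set(labels)):
                pts = scores.loc[scores["condition"] == lab, ["comp1", "comp2"]].to_numpy()
                if len(pts) >= 3:
                    e = confidence_ellipse(pts, level=config.plsda["ellipse_level"])
                    ellipses[lab] = {
                        "center": e["center"].tolist(),
                        "semi_axes": e["semi_axes"].tolist(),
                        "rotation": e["rotation"],
                        "degenerate": e["degenerate"],
                    }
        _write_tsv(acc_table, out / "plsda_accuracy.tsv", "n_components")
        _write_tsv(scores, out / "plsda_scores.tsv", "sample")
        (out / "plsda_ellipses.json").write_text(json.dumps(ellipses, indent=2, sort_keys=True))
        results["plsda"] = {"accuracy": acc_table, "chosen": chosen,
                            "model": model, "scores": scores, "ellipses": ellipses}

        stage = "nas"
        molecules = {g: float(cs.genes.at[g, "log2fc"]) for g in cs.genes.index}
        universe = sorted(set(expr.gene_ids) & net.nodes)
        nas_run = run_nasfinder(
            molecules, net, collection,
            universe=universe,
            top_receptors=config.nas["top_receptors"],
            n_permutations=config.nas["permutations"],
            seed=seeds["nas"],
            min_set_size=config.nas.get("min_set_size", 10),
        )
        _write_tsv(nas_run["receptor_ranking"].set_index("receptor"),
                   out / "nas_receptors.tsv", "receptor")
        _write_tsv(nas_run["results"], out / "nas_results.tsv", "set")
        for r, sub in nas_run["subnetworks"].items():
            with open(out / f"subnetwork_{_slug(r)}.tsv", "w") as fh:
                for u, v in sorted(sub.graph.edges):
                    fh.write(f"{u}\t{sub.graph.edges[u, v]['sign']}\t{v}\n")
        results["nas"] = nas_run

        stage = "topology"
        top_receptor = nas_run["receptor_ranking"]["receptor"].iloc[0]
        sub_nodes = set(nas_run["subnetworks"][top_receptor].graph.nodes)
        integrated, summary = integrate_network(sub_nodes, net)
        table, fit = centrality_report(integrated, directed=config.topology["directed"])
        _write_tsv(table, out / "topology_nodes.tsv", "node")
        (out / "topology_summary.json").write_text(
            json.dumps({**summary, **fit}, indent=2, sort_keys=True)
        )
        results["topology"] = {"graph": integrated, "summary": summary,
                               "table": table, "fit": fit}

        stage = "tissue"
        tissue_sets = build_tissue_deg_sets(
            panel, p_max=config.tissue["p_max"], lfc_min=config.tissue["lfc_min"]
        )
        query = {g: cs.genes.at[g, "direction"] for g in cs.genes.index
                 if g in set(tissue_sets.universe)}
        enrichment = enrich_query(query, tissue_sets)
        _write_tsv(enrichment, out / "tissue_enrichment.tsv", "tissue")
        results["tissue"] = {"sets": tissue_sets, "enrichment": enrichment}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds,
        "input_digests": {k: _digest(v) for k, v in config.input_paths().items()},
        "counts": {
            "degs_per_condition": {c: int((t["direction"] != "none").sum())
                                   for c, t in results["deg"].items()},
            "cs_degs": len(results["csdeg"]),
            "cs_deg_directions": results["csdeg_directions"],
            "plsda_chosen_components": results["plsda"]["chosen"],
            "integrated_network": results["topology"]["summary"],
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _slug(label: str) -> str:
    return label.replace("+", "_").replace(" ", "")


def make_demo(outdir: str | Path, seed: int = 0,
              sim: SimulationConfig | None = None) -> PipelineConfig:
    """Write a desk-scale synthetic scenario plus a ready config.

    The design mirrors the emulated study: mock + 6 treatments, 71 genes
    exclusive to the triple combination, one receptor wired to the planted
    module, one gene set built to overlap it, and a 30-tissue panel whose
    first tissue carries 20 of the exclusive genes as up-regulated markers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sim is None:
        sim = SimulationConfig(
            n_genes=1200,
            network_size=300,
            n_exclusive_focal=71,
            n_receptors=3,
            n_wired_receptors=1,
            seed=seed,
        )
    expr, truth = simulate_expression(sim)
    net = simulate_network(sim, truth)
    collection = simulate_genesets(sim, truth)

    focal_excl = truth.exclusive_degs[sim.focal]
    focal_markers = sorted(focal_excl)[:20]
    rng = np.random.default_rng([99, seed])
    tissues = [f"Tissue{i:02d}" for i in range(1, sim.n_tissues + 1)]
    candidates = [g for g in expr.gene_ids if g not in set(focal_markers)]
    picks = rng.choice(len(candidates), size=(sim.n_tissues - 1) * sim.n_markers_per_tissue,
                       replace=False)
    markers = {tissues[0]: focal_markers}
    for i, t in enumerate(tissues[1:]):
        lo = i * sim.n_markers_per_tissue
        markers[t] = sorted(candidates[j] for j in picks[lo: lo + sim.n_markers_per_tissue])
    panel, panel_truth = simulate_tissue_panel(sim, markers=markers)
    truth.tissue_markers = panel_truth.tissue_markers

    write_expression(expr, outdir / "expression.tsv", outdir / "design.tsv")
    write_network(net, outdir / "network.tsv", outdir / "receptors.txt")
    write_gmt(collection, outdir / "genesets.gmt")
    write_expression(panel, outdir / "panel.tsv", outdir / "panel_design.tsv")
    truth.to_json(outdir / "truth.json")

    config = PipelineConfig(
        expression=str(outdir / "expression.tsv"),
        design=str(outdir / "design.tsv"),
        network=str(outdir / "network.tsv"),
        receptors=str(outdir / "receptors.txt"),
        genesets=str(outdir / "genesets.gmt"),
        panel=str(outdir / "panel.tsv"),
        panel_design=str(outdir / "panel_design.tsv"),
        out_dir=str(outdir / "results"),
        seed=seed,
    )
    config.csdeg["focal"] = sim.focal
    config.to_yaml(outdir / "config.yaml")
    return config
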