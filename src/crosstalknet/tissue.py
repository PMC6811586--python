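"""Tissue DEG-set construction and query enrichment with directionality.

A multi-tissue expression panel is first zero-mean normalized per gene
across all samples. For each tissue, every gene gets a Welch two-sided
t-test of that tissue's samples against all other samples; logFC is the
tissue mean minus the rest mean on the normalized scale. P values are
Benjamini-Hochberg adjusted jointly across all gene x tissue tests, and a
gene joins a tissue's up or down set when adjusted p <= 0.05 and
|logFC| >= 0.58 (both non-strict).

A query gene list (with per-gene up/down directions) is then tested against
each tissue's full DEG set by a one-sided hypergeometric test, BH-adjusted
across tissues. For each tissue a direction report gives the fraction of
overlapping genes whose query direction matches the tissue-set direction —
this is what exposes a gene set that is down-regulated under treatment but
up-regulated in a normal tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = ["TissueDEGSets", "build_tissue_deg_sets", "enrich_query"]

P_MAX_DEFAULT = 0.05
LFC_MIN_DEFAULT = 0.58


@dataclass
class TissueDEGSets:
    """Per-tissue up/down/full DEG sets plus the full gene x tissue statistics."""

    stats: pd.DataFrame  # columns: gene, tissue, logfc, t, p, p_adj
    up: dict[str, set[str]]
    down: dict[str, set[str]]
    universe: list[str]

    def full(self, tissue: str) -> set[str]:
        return self.up[tissue] | self.down[tissue]

    @property
    def tissues(self) -> list[str]:
        return sorted(self.up)


def build_tissue_deg_sets(
    panel: ExpressionMatrix,
    p_max: float = P_MAX_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
) -> TissueDEGSets:
    """Welch-t tissue-vs-rest DEG sets on the zero-mean normalized panel."""
    tissues = panel.conditions
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    values = panel.values.to_numpy(dtype=float)
    values = values - values.mean(axis=1, keepdims=True)  # zero-mean per gene
    tissue_of = np.array([panel.design.at[s, "condition"] for s in panel.sample_ids])

    usable = []
    for t in tissues:
        if (tissue_of == t).sum() < 2:
            warnings.warn(f"tissue {t!r} has <2 samples; skipped", stacklevel=2)
        else:
            usable.append(t)
    if len(usable) < 2:
        raise ValueError("fewer than 2 tissues with >= 2 samples")

    frames = []
    for t in usable:
        mask = tissue_of == t
        a, b = values[:, mask], values[:, ~mask]
        tstat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        logfc = a.mean(axis=1) - b.mean(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "gene": panel.gene_ids,
                    "tissue": t,
                    "logfc": logfc,
                    "t": tstat,
                    "p": p,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]

    hit = (table["p_adj"] <= p_max) & (table["logfc"].abs() >= lfc_min)
    up: dict[str, set[str]] = {t: set() for t in usable}
    down: dict[str, set[str]] = {t: set() for t in usable}
    for _, row in table[hit].iterrows():
        (up if row["logfc"] > 0 else down)[row["tissue"]].add(row["gene"])
    return TissueDEGSets(stats=table, up=up, down=down, universe=panel.gene_ids)


def enrich_query(
    query_directions: dict[str, str],
    sets: TissueDEGSets,
    universe=None,
    p_max: float = P_MAX_DEFAULT,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a directed query in each tissue's DEG set.

    *query_directions* maps gene -> 'up' | 'down' (the direction observed in
    the querying experiment). Returns one row per tissue with the overlap,
    enrichment p, BH-adjusted p, significance flag, and for the overlap the
    fraction of genes whose query direction matches the tissue direction
    (``frac_same_direction``) and the fraction pointing the opposite way.
    """
    if not query_directions:
        raise ValueError("empty query")
    universe = set(universe) if universe is not None else set(sets.universe)
    query = set(query_directions) & universe
    if not query:
        raise ValueError("no query gene in the universe")
    N, n = len(universe), len(query)
    rows = []
    for t in sets.tissues:
        full = sets.full(t) & universe
        overlap = sorted(query & full)
        K, k = len(full), len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        same = opp = 0
        for g in overlap:
            tissue_dir = "up" if g in sets.up[t] else "down"
            if query_directions[g] == tissue_dir:
                same += 1
            else:
                opp += 1
        rows.append(
            {
                "tissue": t,
                "set_size": K,
                "overlap": k,
                "p_hyper": p,
                "frac_same_direction": same / k if k else np.nan,
                "frac_opposite_direction": opp / k if k else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("tissue")
    table["p_adj"] = multipletests(table["p_hyper"], method="fdr_bh")[1]
    table["significant"] = table["p_adj"] <= p_max
    return table.sort_values(["p_adj", "p_hyper"])
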