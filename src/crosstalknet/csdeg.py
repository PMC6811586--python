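"""Context-specific DEG extraction and double-vs-triple fold-change concordance.

A context-specific DEG (CS-DEG) is a gene called differential in exactly one
of the compared conditions: the focal condition's DEG set minus the union of
every other condition's DEG set. Exclusivity is assessed on the called sets,
irrespective of direction; a direction-aware variant is available via
``direction_aware=True`` (a gene then survives if no other condition calls
it in the same direction).

The concordance analysis regresses the triple-treatment fold changes on the
two double-treatment fold changes by OLS and reports coefficient t tests and
a sequential (type-I) ANOVA, which attributes variance to predictors in the
order given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


__all__ = ["CSDEGSet", "extract_cs_degs", "direction_summary", "foldchange_concordance"]


@dataclass
class CSDEGSet:
    """Genes differential exclusively in the focal condition."""

    focal_condition: str
    genes: pd.DataFrame  # indexed by gene: log2fc, direction (from the focal table)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def members(self) -> set[str]:
        return set(self.genes.index)


def extract_cs_degs(
    deg_tables: dict[str, pd.DataFrame],
    focal: str,
    direction_aware: bool = False,
) -> CSDEGSet:
    """Focal DEGs not called in any other compared condition.

    *deg_tables* maps condition label -> DEG table (as produced by
    :func:`crosstalknet.rankprod.rank_product_test`); at least two
    conditions are required.
    """
    if focal not in deg_tables:
        raise KeyError(f"focal condition {focal!r} not among compared conditions")
    if len(deg_tables) < 2:
        raise ValueError("need at least 2 conditions to assess exclusivity")

    focal_table = deg_tables[focal]
    focal_called = focal_table[focal_table["direction"] != "none"]

    keep = []
    for gene in focal_called.index:
        gdir = focal_called.at[gene, "direction"]
        exclusive = True
        for cond, table in deg_tables.items():
            if cond == focal or gene not in table.index:
                continue
            other_dir = table.at[gene, "direction"]
            if other_dir == "none":
                continue
            if direction_aware and other_dir != gdir:
                continue
            exclusive = False
            break
        if exclusive:
            keep.append(gene)

    return CSDEGSet(
        focal_condition=focal,
        genes=focal_called.loc[keep, ["log2fc", "direction"]],
        provenance=sorted(deg_tables),
    )


def direction_summary(cs: CSDEGSet) -> tuple[int, int]:
    """(up, down) member counts; they sum to the set size."""
    up = int((cs.genes["direction"] == "up").sum())
    down = int((cs.genes["direction"] == "down").sum())
    return up, down


def foldchange_concordance(
    fc_triple: pd.Series | np.ndarray,
    fc_double_1: pd.Series | np.ndarray,
    fc_double_2: pd.Series | np.ndarray,
    names: tuple[str, str] = ("double_1", "double_2"),
) -> dict:
    """OLS of triple-treatment fold changes on the two double-treatment ones.

    Fits ``fc_triple ~ 1 + fc_double_1 + fc_double_2`` and reports
    coefficients, per-coefficient t statistics and p values, sequential
    (type-I) ANOVA F per predictor, and the residual variance. The
    sequential ANOVA attributes sums of squares in the order the predictors
    are given, mirroring an ordered analysis-of-variance model.
    """
    y = np.asarray(fc_triple, dtype=float)
    x1 = np.asarray(fc_double_1, dtype=float)
    x2 = np.asarray(fc_double_2, dtype=float)
    if not (len(y) == len(x1) == len(x2)):
        raise ValueError("fold-change vectors must share a common gene list")
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 observations for 3 parameters plus residual df")

    X = sm.add_constant(np.column_stack([x1, x2]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    fit = sm.OLS(y, X).fit()

    # sequential (type-I) sums of squares by explicit nested refits
    rss = []
    for p in range(1, X.shape[1] + 1):
        sub = sm.OLS(y, X[:, :p]).fit()
        rss.append(float(sub.ssr))
    df_resid = n - X.shape[1]
    mse = rss[-1] / df_resid
    seq_ss = [rss[i] - rss[i + 1] for i in range(len(rss) - 1)]
    seq_f = [ss / mse for ss in seq_ss]

    coef_names = ["intercept", *names]
    return {
        "n": n,
        "coefficients": dict(zip(coef_names, fit.params.tolist())),
        "t_values": dict(zip(coef_names, fit.tvalues.tolist())),
        "p_values": dict(zip(coef_names, fit.pvalues.tolist())),
        "anova_seq_ss": dict(zip(names, seq_ss)),
        "anova_seq_f": dict(zip(names, seq_f)),
        "residual_variance": float(mse),
        "r_squared": float(fit.rsquared),
        "main_component": names[int(np.argmax(seq_f))],
    }
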