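"""Rank-product differential expression with permutation-estimated pfp.

The rank product is a non-parametric statistic for consistent differential
expression: for each treated/control replicate pairing the genes are ranked
by their log ratio, and a gene's statistic is the geometric mean of its
normalized ranks (rank/n) across pairings. Small values mean the gene was
consistently among the most extreme. Significance is expressed as the
percentage of false positives (pfp, an FDR-like quantity) estimated by
permuting gene labels within each ratio column.

The two-class all-pairs construction is used: a treatment with t replicates
against a control with c replicates yields k = t x c ratio columns. Genes
are called differential when pfp < 0.05 and |log2FC| > 2 (both strict),
treatment versus mock.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix

__all__ = [
    "pairwise_log_ratios",
    "rank_product",
    "estimate_pfp",
    "call_degs",
    "rank_product_test",
]

PFP_MAX_DEFAULT = 0.05
LFC_MIN_DEFAULT = 2.0


def pairwise_log_ratios(
    expr: ExpressionMatrix, condition: str, control: str = "mock"
) -> pd.DataFrame:
    """All treated x control replicate-pair log ratios.

    Returns a genes x k DataFrame, k = (#treated replicates) x (#control
    replicates); entry = treated log2 value minus control log2 value.
    """
    treated = expr.condition_values(condition)
    ctrl = expr.condition_values(control)
    if treated.shape[1] == 0 or ctrl.shape[1] == 0:
        raise ValueError(f"no replicates for {condition!r} or {control!r}")
    cols = {}
    for ts in treated.columns:
        for cs in ctrl.columns:
            cols[f"{ts}.vs.{cs}"] = treated[ts].to_numpy() - ctrl[cs].to_numpy()
    return pd.DataFrame(cols, index=expr.values.index)


def _column_ranks(ratios: np.ndarray, direction: str) -> np.ndarray:
    """Per-column ranks, 1 = most extreme in *direction*; ties get average ranks."""
    signed = -ratios if direction == "up" else ratios
    return rankdata(signed, axis=0, method="average")


def _rank_product_single(arr: np.ndarray, direction: str) -> np.ndarray:
    n = arr.shape[0]
    log_ranks = np.log(_column_ranks(arr, direction) / n)
    # sort per gene so the float sum is independent of column order: genes
    # with identical rank multisets get bit-identical statistics
    log_ranks.sort(axis=1)
    return np.exp(np.mean(log_ranks, axis=1))


def rank_product(ratios: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank-product statistics for both directions.

    rp = geometric mean over columns of (rank/n), so rp is in (0, 1]; rank 1
    is the largest ratio for ``rp_up`` and the smallest for ``rp_down``.
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D ratio matrix with >= 2 genes")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite ratios")
    return _rank_product_single(arr, "up"), _rank_product_single(arr, "down")


def estimate_pfp(
    ratios: pd.DataFrame | np.ndarray,
    rp_observed: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    direction: str = "up",
) -> np.ndarray:
    """Permutation estimate of the percentage of false positives.

    For each of B permutations, gene labels are shuffled independently
    within every ratio column and the rank product recomputed. With genes
    ordered by ascending observed rp (rank position r_g), the expected
    false-positive count at rp_g is #{permuted rp <= rp_g} / B and
    pfp(g) = E[FP](g) / r_g, made monotone non-decreasing along the sorted
    order by a cumulative maximum.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100 for a stable pfp estimate")
    arr = np.asarray(ratios, dtype=float)
    rng = np.random.default_rng(seed)
    n, k = arr.shape

    null_rp = np.empty((n_permutations, n))
    for b in range(n_permutations):
        shuffled = np.empty_like(arr)
        for j in range(k):
            shuffled[:, j] = arr[rng.permutation(n), j]
        null_rp[b] = _rank_product_single(shuffled, direction)
    null_sorted = np.sort(null_rp.ravel())

    order = np.argsort(rp_observed, kind="stable")
    rp_sorted = rp_observed[order]
    exp_fp = np.searchsorted(null_sorted, rp_sorted, side="right") / n_permutations
    r = np.arange(1, n + 1)
    pfp_sorted = np.maximum.accumulate(exp_fp / r)

    pfp = np.empty(n)
    pfp[order] = pfp_sorted
    return pfp


def call_degs(
    table: pd.DataFrame,
    pfp_max: float = PFP_MAX_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
) -> pd.DataFrame:
    """Apply the joint pfp / fold-change thresholds (both strict).

    Adds a ``direction`` column: ``up`` iff pfp_up < pfp_max and
    log2fc > lfc_min; ``down`` iff pfp_down < pfp_max and
    log2fc < -lfc_min; otherwise ``none``.
    """
    if pfp_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    out = table.copy()
    up = (out["pfp_up"] < pfp_max) & (out["log2fc"] > lfc_min)
    down = (out["pfp_down"] < pfp_max) & (out["log2fc"] < -lfc_min)
    out["direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return out


def rank_product_test(
    expr: ExpressionMatrix,
    condition: str,
    control: str = "mock",
    n_permutations: int = 1000,
    seed: int = 0,
    pfp_max: float = PFP_MAX_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
) -> pd.DataFrame:
    """Full rank-product DEG table for one treatment-vs-control contrast.

    Returns a DataFrame indexed by gene with columns log2fc, rp_up, rp_down,
    pfp_up, pfp_down, direction. log2fc is the difference of condition means
    on the log2 scale.
    """
    ratios = pairwise_log_ratios(expr, condition, control)
    rp_up, rp_down = rank_product(ratios)
    pfp_up = estimate_pfp(ratios, rp_up, n_permutations, seed=seed, direction="up")
    pfp_down = estimate_pfp(ratios, rp_down, n_permutations, seed=seed + 1, direction="down")
    log2fc = (
        expr.condition_values(condition).mean(axis=1)
        - expr.condition_values(control).mean(axis=1)
    )
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "rp_up": rp_up,
            "rp_down": rp_down,
            "pfp_up": pfp_up,
            "pfp_down": pfp_down,
        },
        index=expr.values.index,
    )
    return call_degs(table, pfp_max=pfp_max, lfc_min=lfc_min)


def deg_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """The called up/down/all gene sets of a DEG table."""
    up = set(table.index[table["direction"] == "up"])
    down = set(table.index[table["direction"] == "down"])
    return {"up": up, "down": down, "all": up | down}
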