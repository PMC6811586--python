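"""Readers and writers for the on-disk formats the pipeline touches.

Three in-memory containers are defined here and used everywhere downstream:

``ExpressionMatrix``
    genes x samples log2 expression plus a sample -> (condition, replicate)
    design table.
``BackgroundNetwork``
    a directed interaction network with signed edges (``activates`` /
    ``inhibits``) and a designated receptor subset; backed by a
    :class:`networkx.DiGraph`.
``GeneSetCollection``
    named gene sets (GMT dialect) with optional descriptions.

All readers validate strictly and raise typed errors naming the offending
row/column; the single documented repair is collapsing duplicate gene rows
by their mean. All writers emit sorted, deterministic output so files are
diffable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BackgroundNetwork",
    "GeneSetCollection",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
]

#: Recognised edge-sign tokens in network edge lists.
EDGE_SIGNS = ("activates", "inhibits")


class FormatError(ValueError):
    """A structural violation in an input file or container."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-level log2 expression with an experimental design.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample IDs as columns.
    design
        DataFrame indexed by sample ID with columns ``condition`` and
        ``replicate``; every sample column of *values* must appear here.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise FormatError(f"samples missing from design: {missing}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = self.values.index[~np.isfinite(arr).all(axis=1)].tolist()
            raise FormatError(f"non-finite expression values for genes: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def conditions(self) -> list[str]:
        """Condition labels in design (first-appearance order)."""
        return self.design["condition"].drop_duplicates().tolist()

    def samples_of(self, condition: str) -> list[str]:
        """Sample IDs belonging to *condition* (design order)."""
        hits = [s for s in self.design.index if self.design.at[s, "condition"] == condition]
        if not hits:
            raise KeyError(f"condition {condition!r} not in design")
        return [s for s in hits if s in self.values.columns]

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.values[self.samples_of(condition)]


@dataclass
class BackgroundNetwork:
    """Directed signed interaction network with designated receptor nodes."""

    graph: nx.DiGraph
    receptors: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.receptors = frozenset(self.receptors)
        stray = self.receptors - set(self.graph.nodes)
        if stray:
            raise FormatError(f"receptors not in node set: {sorted(stray)}")
        loops = [(u, v) for u, v in self.graph.edges if u == v]
        if loops:
            raise FormatError(f"self-loops not allowed: {loops}")
        bad = [
            (u, v, d.get("sign"))
            for u, v, d in self.graph.edges(data=True)
            if d.get("sign") not in EDGE_SIGNS
        ]
        if bad:
            raise FormatError(f"edges with unknown sign: {bad}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def sign_counts(self) -> dict[str, int]:
        """Count of activating and inhibitory edges."""
        counts = {s: 0 for s in EDGE_SIGNS}
        for _, _, d in self.graph.edges(data=True):
            counts[d["sign"]] += 1
        return counts


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        if set(self.sets) != set(other.sets):
            return False
        return all(self.sets[n] == other.sets[n] for n in self.sets) and all(
            self.descriptions.get(n, "") == other.descriptions.get(n, "") for n in self.sets
        )

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample/condition/replicate design TSV.

    Duplicate gene rows are collapsed by their mean with a warning; any other
    structural problem raises :class:`FormatError`.
    """
    path, design_path = Path(path), Path(design_path)
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if values.empty and values.columns.empty:
        raise FormatError(f"{path}: empty expression file")
    non_numeric = values.columns[
        [not np.issubdtype(dt, np.number) for dt in values.dtypes]
    ].tolist()
    if non_numeric:
        raise FormatError(f"{path}: non-numeric values in columns {non_numeric}")
    if values.isna().to_numpy().any():
        bad_rows = values.index[values.isna().any(axis=1)].tolist()
        raise FormatError(f"{path}: missing values in rows {bad_rows}")
    if values.index.duplicated().any():
        dups = sorted(values.index[values.index.duplicated()].unique())
        warnings.warn(f"{path}: collapsing duplicate gene rows by mean: {dups}", stacklevel=2)
        values = values.groupby(level=0, sort=False).mean()

    design = pd.read_csv(design_path, sep="\t", dtype=str)
    required = {"sample", "condition", "replicate"}
    if not required.issubset(design.columns):
        raise FormatError(
            f"{design_path}: design must have columns {sorted(required)}, "
            f"found {design.columns.tolist()}"
        )
    design = design.set_index("sample")
    return ExpressionMatrix(values=values, design=design)


def write_expression(expr: ExpressionMatrix, path: str | Path, design_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    out = expr.design.reset_index()
    out = out.rename(columns={out.columns[0]: "sample"})
    out.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line name, description, then members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


# ---------------------------------------------------------------------------
# signed edge-list network
# ---------------------------------------------------------------------------


def read_network(path: str | Path, receptors_path: str | Path | None = None) -> BackgroundNetwork:
    """Read a signed edge-list TSV (source, interaction, target) and an
    optional one-column receptor file."""
    graph = nx.DiGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            src, sign, dst = fields
            if sign not in EDGE_SIGNS:
                raise FormatError(
                    f"{path}:{lineno}: unknown interaction {sign!r}, expected one of {EDGE_SIGNS}"
                )
            if src == dst:
                raise FormatError(f"{path}:{lineno}: self-loop on {src!r}")
            graph.add_edge(src, dst, sign=sign)
    receptors: set[str] = set()
    if receptors_path is not None:
        with open(receptors_path) as fh:
            receptors = {line.strip() for line in fh if line.strip()}
        stray = receptors - set(graph.nodes)
        if stray:
            raise FormatError(f"{receptors_path}: receptors not in network: {sorted(stray)}")
    return BackgroundNetwork(graph=graph, receptors=frozenset(receptors))


def write_network(
    net: BackgroundNetwork, path: str | Path, receptors_path: str | Path | None = None
) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(net.graph.edges):
            fh.write(f"{u}\t{net.graph.edges[u, v]['sign']}\t{v}\n")
    if receptors_path is not None:
        with open(receptors_path, "w") as fh:
            for r in sorted(net.receptors):
                fh.write(r + "\n")
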