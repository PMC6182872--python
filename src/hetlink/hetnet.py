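"""Heterogeneous protein-lncRNA network: data model, construction and TSV I/O.

The network has two node types (protein, lncRNA) and three edge classes:
protein-protein (PP), lncRNA-lncRNA (LL) and protein-lncRNA (PL).  Edge
weights live in [0, 1]; edges below a similarity threshold (default 0.5)
are dropped when the global network is assembled, and the surviving edges
are merged into one symmetric adjacency matrix over all nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

PROTEIN = "protein"
LNCRNA = "lncRNA"

#: endpoint types required by each edge class, in stored pair order
EDGE_CLASS_TYPES = {
    "PP": (PROTEIN, PROTEIN),
    "LL": (LNCRNA, LNCRNA),
    "PL": (PROTEIN, LNCRNA),
}


class SchemaError(ValueError):
    """An edge or node violates the typed-network schema."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (zero variance)."""


@dataclass
class NodeRegistry:
    """Ordered node universe with a bijection id -> contiguous index."""

    ids: list[str]
    node_type: dict[str, str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise SchemaError("duplicate node identifiers in registry")
        missing = [i for i in self.ids if i not in self.node_type]
        if missing:
            raise SchemaError(f"nodes without a type: {missing[:5]}")
        bad = {t for t in self.node_type.values()} - {PROTEIN, LNCRNA}
        if bad:
            raise SchemaError(f"unknown node types: {sorted(bad)}")
        self.index = {nid: k for k, nid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def indices_of_type(self, node_type: str) -> np.ndarray:
        """Contiguous indices of all nodes of ``node_type``, in id order."""
        return np.array(
            [k for k, nid in enumerate(self.ids) if self.node_type[nid] == node_type],
            dtype=int,
        )


@dataclass
class EdgeSet:
    """Weighted edges of a single class (PP, LL or PL).

    Pairs are stored in class order (PL pairs as (protein, lncRNA));
    duplicate detection is on the unordered pair.
    """

    edge_class: str
    pairs: list[tuple[str, str]]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.edge_class not in EDGE_CLASS_TYPES:
            raise SchemaError(f"unknown edge class {self.edge_class!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.pairs) != len(self.weights):
            raise SchemaError("pairs and weights length mismatch")
        if len(self.weights) and (
            not np.all(np.isfinite(self.weights))
            or self.weights.min() < 0.0
            or self.weights.max() > 1.0
        ):
            raise SchemaError("edge weights must be finite and in [0, 1]")
        seen: set[frozenset[str]] = set()
        for a, b in self.pairs:
            if a == b:
                raise SchemaError(f"self-loop on node {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise SchemaError(f"duplicate edge {a!r}-{b!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class HetNet:
    """Global heterogeneous network: registry + per-class edges + adjacency G.

    ``G`` is symmetric with zero diagonal; by default it is binary
    (entry 1 wherever any surviving edge connects the pair), optionally
    it carries the edge weights.
    """

    registry: NodeRegistry
    edges: dict[str, EdgeSet]
    G: sp.csr_matrix
    weighted: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.registry)

    def protein_indices(self) -> np.ndarray:
        return self.registry.indices_of_type(PROTEIN)

    def lncrna_indices(self) -> np.ndarray:
        return self.registry.indices_of_type(LNCRNA)

    def isolated_nodes(self) -> list[str]:
        degree = np.asarray(self.G.sum(axis=1)).ravel()
        return [nid for nid, k in self.registry.index.items() if degree[k] == 0]

    def typed_adjacency(self, source_type: str, target_type: str) -> np.ndarray:
        """Dense adjacency block between two node types (binary 0/1)."""
        rows = self.registry.indices_of_type(source_type)
        cols = self.registry.indices_of_type(target_type)
        block = self.G[np.ix_(rows, cols)].toarray()
        return (block > 0).astype(float)


def pearson_coexpression(expr_a: Sequence[float], expr_b: Sequence[float]) -> float:
    """Pearson correlation between two expression profiles.

    Raises UndefinedCorrelationError when either profile has zero
    variance, and ValueError on length mismatch or fewer than 3 samples.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite expression values")
    da, db = a - a.mean(), b - b.mean()
    va, vb = float(da @ da), float(db @ db)
    if va == 0.0 or vb == 0.0:
        raise UndefinedCorrelationError("zero variance in an expression profile")
    r = float(da @ db) / np.sqrt(va * vb)
    return float(np.clip(r, -1.0, 1.0))


def integrate_correlations(per_dataset: Iterable[float]) -> float | None:
    """Combine per-dataset correlations into one association weight.

    Only positive correlations contribute; the integrated value is
    ``1 - prod(1 - C_d)`` over the positive C_d.  Returns ``None`` when no
    dataset reports a positive correlation (the pair is discarded: mutual
    exclusion suggests no interaction).
    """
    values = [float(c) for c in per_dataset]
    for c in values:
        if not -1.0 <= c <= 1.0:
            raise ValueError(f"correlation {c} outside [-1, 1]")
    positive = [c for c in values if c > 0.0]
    if not positive:
        return None
    prod = 1.0
    for c in positive:
        prod *= 1.0 - c
    return 1.0 - prod


def coexpression_edges(
    expr: pd.DataFrame,
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    edge_class: str,
) -> EdgeSet:
    """Build a co-expression EdgeSet from an expression matrix.

    ``expr`` is genes x samples (index = gene ids).  All (a, b) pairs with
    positive Pearson correlation become edges weighted by the correlation;
    non-positive correlations are dropped.
    """
    pairs: list[tuple[str, str]] = []
    weights: list[float] = []
    seen: set[frozenset[str]] = set()
    for a in ids_a:
        for b in ids_b:
            if a == b or frozenset((a, b)) in seen:
                continue
            seen.add(frozenset((a, b)))
            try:
                r = pearson_coexpression(expr.loc[a].values, expr.loc[b].values)
            except UndefinedCorrelationError:
                continue
            if r > 0.0:
                pairs.append((a, b))
                weights.append(min(r, 1.0))
    return EdgeSet(edge_class, pairs, np.array(weights, dtype=float))


def _infer_registry(edge_sets: Iterable[EdgeSet]) -> NodeRegistry:
    node_type: dict[str, str] = {}
    ids: list[str] = []
    for es in edge_sets:
        ta, tb = EDGE_CLASS_TYPES[es.edge_class]
        for (a, b) in es.pairs:
            for nid, t in ((a, ta), (b, tb)):
                prev = node_type.get(nid)
                if prev is None:
                    node_type[nid] = t
                    ids.append(nid)
                elif prev != t:
                    raise SchemaError(
                        f"node {nid!r} appears as both {prev} and {t}"
                    )
    return NodeRegistry(ids, node_type)


def build_hetnet(
    edge_sets: Sequence[EdgeSet],
    registry: NodeRegistry | None = None,
    threshold: float | dict[str, float] = 0.5,
    weighted: bool = False,
) -> HetNet:
    """Merge typed edge sets into a global symmetric network.

    Edges with weight strictly below the threshold are removed (the
    threshold may be a single value or a per-class mapping).  Nodes that
    lose all their edges stay in the registry as isolated nodes so that
    indexing is stable.
    """
    if isinstance(threshold, dict):
        thr = {cls: float(threshold.get(cls, 0.5)) for cls in EDGE_CLASS_TYPES}
    else:
        thr = {cls: float(threshold) for cls in EDGE_CLASS_TYPES}
    for cls, t in thr.items():
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold for {cls} outside [0, 1]: {t}")

    # validate endpoint types against an explicit registry before filtering
    if registry is not None:
        for es in edge_sets:
            ta, tb = EDGE_CLASS_TYPES[es.edge_class]
            for a, b in es.pairs:
                for nid, want in ((a, ta), (b, tb)):
                    have = registry.node_type.get(nid)
                    if have is None:
                        raise SchemaError(f"edge endpoint {nid!r} not in registry")
                    if have != want:
                        raise SchemaError(
                            f"{es.edge_class} edge endpoint {nid!r} is {have}, "
                            f"expected {want}"
                        )
    else:
        registry = _infer_registry(edge_sets)

    surviving: dict[str, EdgeSet] = {}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for es in edge_sets:
        keep = es.weights >= thr[es.edge_class]
        kept_pairs = [p for p, k in zip(es.pairs, keep) if k]
        kept_w = es.weights[keep]
        surviving[es.edge_class] = EdgeSet(es.edge_class, kept_pairs, kept_w)
        for (a, b), w in zip(kept_pairs, kept_w):
            i, j = registry.index[a], registry.index[b]
            v = float(w) if weighted else 1.0
            rows.extend((i, j))
            cols.extend((j, i))
            vals.extend((v, v))
    for cls in EDGE_CLASS_TYPES:
        surviving.setdefault(cls, EdgeSet(cls, [], np.array([])))

    n = len(registry)
    G = sp.csr_matrix(
        (np.array(vals), (np.array(rows, dtype=int), np.array(cols, dtype=int))),
        shape=(n, n),
    )
    # duplicate (i,j) entries across classes would sum; collapse to the max
    G.sum_duplicates()
    if not weighted:
        G.data[:] = np.minimum(G.data, 1.0)
    G.setdiag(0)
    G.eliminate_zeros()
    return HetNet(registry, surviving, G, weighted=weighted)


# ---------------------------------------------------------------------------
# TSV I/O


def read_edges(path: str | Path, edge_class: str) -> EdgeSet:
    """Read a 3-column TSV (source, target, weight); '#' lines are comments."""
    pairs: list[tuple[str, str]] = []
    weights: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            a, b, w_str = fields
            try:
                w = float(w_str)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad weight {w_str!r}") from exc
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            pairs.append((a, b))
            weights.append(w)
    return EdgeSet(edge_class, pairs, np.array(weights, dtype=float))


def write_edges(edge_set: EdgeSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# source\ttarget\tweight ({edge_set.edge_class})\n")
        for (a, b), w in zip(edge_set.pairs, edge_set.weights):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_node_table(path: str | Path) -> NodeRegistry:
    """Read a 2-column TSV (id, type)."""
    ids: list[str] = []
    node_type: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            nid, t = fields
            ids.append(nid)
            node_type[nid] = t
    return NodeRegistry(ids, node_type)


def write_node_table(registry: NodeRegistry, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id\ttype\n")
        for nid in registry.ids:
            fh.write(f"{nid}\t{registry.node_type[nid]}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression matrix TSV (rows = genes, first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")
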