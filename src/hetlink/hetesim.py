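"""HeteSim relevance of protein-lncRNA pairs along typed metapaths.

A metapath is a sequence of node types constraining admissible walks,
written as a string over {P, L} that starts at a protein and ends at a
lncRNA (e.g. "PPL" = protein -> protein -> lncRNA).  The catalogue used
for features is every such path with 3 to 5 node symbols: 14 paths in
total (2 + 4 + 8 by length).

The HeteSim score of a pair along a path is the cosine-normalized
meeting probability of two random walkers launched from both endpoints
toward the path's midpoint.  Reachable-probability vectors are products
of row-normalized typed adjacency blocks; paths with an odd number of
edges are split at the middle relation by giving each of its edge
instances a virtual midpoint node (middle-edge decomposition), so that
both walkers meet in a common space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hetnet import HetNet, LNCRNA, PROTEIN, SchemaError

_TYPE_OF = {"P": PROTEIN, "L": LNCRNA}

# Catalogue order of admissible paths, frozen for reproducibility of
# serialized feature vectors and models.
_CANONICAL = {
    2: ["PL"],
    3: ["PLL", "PPL"],
    4: ["PPLL", "PLPL", "PLLL", "PPPL"],
    5: ["PPPPL", "PLPPL", "PPLPL", "PLLPL", "PPPLL", "PLPLL", "PPLLL", "PLLLL"],
}


@dataclass(frozen=True)
class MetaPath:
    """Type sequence from protein to lncRNA, named over the {P, L} alphabet."""

    name: str
    types: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.name) < 2 or set(self.name) - {"P", "L"}:
            raise ValueError(f"bad metapath name {self.name!r}")
        if self.name[0] != "P" or self.name[-1] != "L":
            raise ValueError(
                f"metapath {self.name!r} must start at a protein and end at a lncRNA"
            )
        object.__setattr__(
            self, "types", tuple(_TYPE_OF[c] for c in self.name)
        )

    @property
    def n_nodes(self) -> int:
        return len(self.name)

    @property
    def n_edges(self) -> int:
        return len(self.name) - 1


def enumerate_metapaths(min_nodes: int = 3, max_nodes: int = 5) -> list[MetaPath]:
    """All protein->lncRNA metapaths with node count in [min_nodes, max_nodes].

    Within each length the catalogue order is used; lengths beyond the
    catalogue fall back to lexicographic order of the inner type string.
    There are 2**(k-2) admissible paths of node count k.
    """
    if not 2 <= min_nodes <= max_nodes:
        raise ValueError("need 2 <= min_nodes <= max_nodes")
    out: list[MetaPath] = []
    for k in range(min_nodes, max_nodes + 1):
        if k in _CANONICAL:
            names = _CANONICAL[k]
        else:
            from itertools import product

            names = ["P" + "".join(mid) + "L" for mid in product("PL", repeat=k - 2)]
        out.extend(MetaPath(n) for n in names)
    return out


@dataclass
class TypedAdjacency:
    """Adjacency block between two node types with its row-normalized form."""

    source_type: str
    target_type: str
    A: np.ndarray
    A_norm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if (self.A < 0).any():
            raise ValueError("typed adjacency must be non-negative")
        self.A_norm = normalize_rows(self.A)


def normalize_rows(A: np.ndarray) -> np.ndarray:
    """Row-normalize a non-negative matrix; all-zero rows stay all-zero."""
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("matrix must be non-negative")
    sums = A.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, A / np.where(sums == 0, 1.0, sums), 0.0)
    return out


@dataclass
class ReachabilityMatrix:
    """Product of row-normalized typed adjacencies along a (half-)path."""

    path: MetaPath
    R: np.ndarray


def _norm_adj(net: HetNet, t_src: str, t_dst: str) -> np.ndarray:
    return normalize_rows(net.typed_adjacency(t_src, t_dst))


def reachability(path: MetaPath, net: HetNet) -> ReachabilityMatrix:
    """Reachable-probability matrix: chained row-normalized adjacencies."""
    R: np.ndarray | None = None
    for t_src, t_dst in zip(path.types, path.types[1:]):
        A = _norm_adj(net, t_src, t_dst)
        R = A if R is None else R @ A
    assert R is not None
    return ReachabilityMatrix(path, R)


def _half_path_product(net: HetNet, types: tuple[str, ...]) -> np.ndarray | None:
    """Product of normalized adjacencies along a type sequence, or None if empty."""
    R: np.ndarray | None = None
    for t_src, t_dst in zip(types, types[1:]):
        A = _norm_adj(net, t_src, t_dst)
        R = A if R is None else R @ A
    return R


def meeting_vectors(path: MetaPath, net: HetNet) -> tuple[np.ndarray, np.ndarray]:
    """Left/right reachable-probability matrices into the path's midpoint space.

    Returns (L, R): L has one row per protein, R one row per lncRNA, and
    both share the midpoint column space.  For an even number of edges
    the midpoint space is the middle node type; for an odd number it is
    the set of directed edge instances of the central relation.
    """
    k = path.n_edges
    types = path.types
    n_prot = len(net.protein_indices())
    n_lnc = len(net.lncrna_indices())
    if k % 2 == 0:
        m = k // 2
        left = _half_path_product(net, types[: m + 1])
        # the right walker starts at the lncRNA end and walks backwards
        # to the middle type
        right = _half_path_product(net, tuple(reversed(types[m:])))
        if left is None or right is None:
            raise ValueError("degenerate metapath")
        return left, right
    # odd edge count: middle-edge decomposition
    m = k // 2  # central relation joins types[m] -- types[m+1]
    A_c = net.typed_adjacency(types[m], types[m + 1])
    ii, jj = np.nonzero(A_c)
    n_inst = len(ii)
    n_src = A_c.shape[0]
    n_dst = A_c.shape[1]
    B_left = np.zeros((n_src, n_inst))
    B_right = np.zeros((n_dst, n_inst))
    B_left[ii, np.arange(n_inst)] = 1.0
    B_right[jj, np.arange(n_inst)] = 1.0
    B_left = normalize_rows(B_left)
    B_right = normalize_rows(B_right)
    left_pre = _half_path_product(net, types[: m + 1])
    right_pre = _half_path_product(net, tuple(reversed(types[m + 1 :])))
    left = B_left if left_pre is None else left_pre @ B_left
    right = B_right if right_pre is None else right_pre @ B_right
    return left, right


def _cosine_scores(L: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Pairwise cosine of row vectors; zero where either row has zero norm."""
    if L.shape[1] == 0:
        return np.zeros((L.shape[0], R.shape[0]))
    ln = np.linalg.norm(L, axis=1)
    rn = np.linalg.norm(R, axis=1)
    denom = np.outer(ln, rn)
    raw = L @ R.T
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, raw / np.where(denom == 0, 1.0, denom), 0.0)
    return np.clip(scores, 0.0, 1.0)


def hetesim_matrix(path: MetaPath, net: HetNet) -> np.ndarray:
    """HeteSim scores of every (protein, lncRNA) pair along one path."""
    L, R = meeting_vectors(path, net)
    return _cosine_scores(L, R)


def hetesim_score(path: MetaPath, protein: str, lncrna: str, net: HetNet) -> float:
    """HeteSim relevance of one pair along one metapath, in [0, 1]."""
    reg = net.registry
    if reg.node_type.get(protein) != PROTEIN:
        raise SchemaError(f"{protein!r} is not a protein node")
    if reg.node_type.get(lncrna) != LNCRNA:
        raise SchemaError(f"{lncrna!r} is not a lncRNA node")
    prot_ids = [reg.ids[k] for k in net.protein_indices()]
    lnc_ids = [reg.ids[k] for k in net.lncrna_indices()]
    pi = prot_ids.index(protein)
    li = lnc_ids.index(lncrna)
    L, R = meeting_vectors(path, net)
    return float(_cosine_scores(L[pi : pi + 1], R[li : li + 1])[0, 0])


def _without_direct_edge(net: HetNet, protein: str, lncrna: str) -> HetNet:
    """Copy of the network with one direct PL edge removed from G."""
    i = net.registry.index[protein]
    j = net.registry.index[lncrna]
    G = net.G.tolil(copy=True)
    G[i, j] = 0.0
    G[j, i] = 0.0
    return HetNet(net.registry, net.edges, G.tocsr(), weighted=net.weighted)


@dataclass
class HeteSimFeatures:
    """Per-pair HeteSim score vectors, columns in catalogue path order."""

    pairs: list[tuple[str, str]]
    path_names: list[str]
    scores: np.ndarray  # shape (n_pairs, n_paths)


def hetesim_features(
    pairs: list[tuple[str, str]],
    net: HetNet,
    min_nodes: int = 3,
    max_nodes: int = 5,
    mask_query_edge: bool = False,
) -> HeteSimFeatures:
    """Score every pair along the full metapath catalogue.

    With ``mask_query_edge`` the pair's own direct PL edge (if present in
    the network) is removed before that pair is scored, so a training
    pair cannot see its own label through the network.
    """
    paths = enumerate_metapaths(min_nodes, max_nodes)
    reg = net.registry
    prot_ids = [reg.ids[k] for k in net.protein_indices()]
    lnc_ids = [reg.ids[k] for k in net.lncrna_indices()]
    prot_pos = {nid: k for k, nid in enumerate(prot_ids)}
    lnc_pos = {nid: k for k, nid in enumerate(lnc_ids)}
    for p, l in pairs:
        if reg.node_type.get(p) != PROTEIN:
            raise SchemaError(f"{p!r} is not a protein node")
        if reg.node_type.get(l) != LNCRNA:
            raise SchemaError(f"{l!r} is not a lncRNA node")

    mats = [hetesim_matrix(path, net) for path in paths]
    scores = np.zeros((len(pairs), len(paths)))
    for r, (p, l) in enumerate(pairs):
        pi, li = prot_pos[p], lnc_pos[l]
        if mask_query_edge and net.G[reg.index[p], reg.index[l]] != 0:
            masked = _without_direct_edge(net, p, l)
            for c, path in enumerate(paths):
                scores[r, c] = hetesim_score(path, p, l, masked)
        else:
            for c in range(len(paths)):
                scores[r, c] = mats[c][pi, li]
    return HeteSimFeatures(list(pairs), [p.name for p in paths], scores)
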