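"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's matrix machinery: the Pearson
oracle is the two-pass textbook formula, the restart-walk oracle is a
dense linear solve, and the HeteSim oracle enumerates concrete walk
instances on neighbor lists with explicit per-step probabilities.
"""

from __future__ import annotations

import math

import numpy as np

from hetlink import HetNet, LNCRNA, PROTEIN


def pearson_two_pass(x, y) -> float:
    """Textbook two-pass Pearson correlation."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def rwr_solve(T_dense: np.ndarray, restart_index: int, alpha: float) -> np.ndarray:
    """Closed-form restart-walk fixed point alpha (I - (1-a) T^t)^{-1} e_i."""
    n = T_dense.shape[0]
    p0 = np.zeros(n)
    p0[restart_index] = 1.0
    return alpha * np.linalg.solve(np.eye(n) - (1.0 - alpha) * T_dense.T, p0)


# ---------------------------------------------------------------------------
# HeteSim walk-enumeration oracle


def neighbor_map(net: HetNet) -> dict[str, dict[str, list[str]]]:
    """node -> target type -> neighbor list, built from the raw edge sets."""
    nbrs: dict[str, dict[str, list[str]]] = {
        nid: {PROTEIN: [], LNCRNA: []} for nid in net.registry.ids
    }
    for es in net.edges.values():
        for a, b in es.pairs:
            nbrs[a][net.registry.node_type[b]].append(b)
            nbrs[b][net.registry.node_type[a]].append(a)
    return nbrs


def _walk_distribution(nbrs, start: str, type_seq) -> dict[str, float]:
    """Probability of landing on each node after walking the type sequence.

    At every step the walker picks uniformly among the current node's
    neighbors of the next required type; mass reaching a node with no
    such neighbors is lost.
    """
    dist = {start: 1.0}
    for t_next in type_seq[1:]:
        new: dict[str, float] = {}
        for node, p in dist.items():
            options = nbrs[node][t_next]
            if not options:
                continue
            share = p / len(options)
            for nb in options:
                new[nb] = new.get(nb, 0.0) + share
        dist = new
    return dist


def _cosine(a: dict, b: dict) -> float:
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    if na == 0.0 or nb == 0.0:
        return 0.0
    dot = sum(v * b.get(k, 0.0) for k, v in a.items())
    return dot / (na * nb)


def hetesim_enumeration(net: HetNet, path_name: str, protein: str,
                        lncrna: str) -> float:
    """HeteSim by exhaustive walk enumeration from both path ends."""
    types = [PROTEIN if c == "P" else LNCRNA for c in path_name]
    k = len(types) - 1
    nbrs = neighbor_map(net)
    if k % 2 == 0:
        m = k // 2
        left = _walk_distribution(nbrs, protein, types[: m + 1])
        right = _walk_distribution(nbrs, lncrna, list(reversed(types[m:])))
        return _cosine(left, right)
    # odd edge count: meet on the directed instances of the central relation
    m = k // 2
    left_nodes = _walk_distribution(nbrs, protein, types[: m + 1])
    right_nodes = _walk_distribution(nbrs, lncrna,
                                     list(reversed(types[m + 1:])))
    left_edges: dict[tuple[str, str], float] = {}
    for i, p in left_nodes.items():
        central = nbrs[i][types[m + 1]]
        if not central:
            continue
        share = p / len(central)
        for j in central:
            left_edges[(i, j)] = left_edges.get((i, j), 0.0) + share
    right_edges: dict[tuple[str, str], float] = {}
    for j, p in right_nodes.items():
        central = nbrs[j][types[m]]
        if not central:
            continue
        share = p / len(central)
        for i in central:
            right_edges[(i, j)] = right_edges.get((i, j), 0.0) + share
    return _cosine(left_edges, right_edges)
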