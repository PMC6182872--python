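"""Shared fixtures: tiny hand-built networks and random typed graphs."""

from __future__ import annotations

import numpy as np
import pytest

from hetlink import (
    EdgeSet,
    LNCRNA,
    NodeRegistry,
    PROTEIN,
    SyntheticConfig,
    build_hetnet,
    generate,
)


@pytest.fixture(scope="session")
def small_truth():
    """Small planted-module network shared by read-only tests."""
    return generate(SyntheticConfig(n_proteins=30, n_lncrnas=30, n_modules=3,
                                    seed=7))


@pytest.fixture
def toy_net():
    """Hand-drawn 2-protein / 2-lncRNA network.

    Edges: p0-p1, l0-l1, p0-l0, p1-l0 (all weight 1).
    """
    registry = NodeRegistry(
        ["p0", "p1", "l0", "l1"],
        {"p0": PROTEIN, "p1": PROTEIN, "l0": LNCRNA, "l1": LNCRNA},
    )
    pp = EdgeSet("PP", [("p0", "p1")], np.array([1.0]))
    ll = EdgeSet("LL", [("l0", "l1")], np.array([1.0]))
    pl = EdgeSet("PL", [("p0", "l0"), ("p1", "l0")], np.array([1.0, 1.0]))
    return build_hetnet([pp, ll, pl], registry=registry, threshold=0.0)


def random_typed_net(rng: np.random.Generator, n_prot: int, n_lnc: int,
                     p_edge: float = 0.3):
    """Random heterogeneous network with Bernoulli edges in each class."""
    prot_ids = [f"p{i}" for i in range(n_prot)]
    lnc_ids = [f"l{i}" for i in range(n_lnc)]
    registry = NodeRegistry(
        prot_ids + lnc_ids,
        {**{p: PROTEIN for p in prot_ids}, **{l: LNCRNA for l in lnc_ids}},
    )
    pp_pairs = [
        (prot_ids[i], prot_ids[j])
        for i in range(n_prot) for j in range(i + 1, n_prot)
        if rng.random() < p_edge
    ]
    ll_pairs = [
        (lnc_ids[i], lnc_ids[j])
        for i in range(n_lnc) for j in range(i + 1, n_lnc)
        if rng.random() < p_edge
    ]
    pl_pairs = [
        (p, l) for p in prot_ids for l in lnc_ids if rng.random() < p_edge
    ]
    edge_sets = [
        EdgeSet("PP", pp_pairs, np.ones(len(pp_pairs))),
        EdgeSet("LL", ll_pairs, np.ones(len(ll_pairs))),
        EdgeSet("PL", pl_pairs, np.ones(len(pl_pairs))),
    ]
    return build_hetnet(edge_sets, registry=registry, threshold=0.0)
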