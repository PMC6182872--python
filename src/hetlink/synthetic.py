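"""Seeded synthetic heterogeneous networks with planted interactions.

The generator uses a planted-partition design: proteins and lncRNAs are
assigned to co-functional modules, edges within a module are denser than
edges between modules, and true protein-lncRNA interactions occur only
within modules.  A configurable fraction of the true interactions is
hidden from the network; the hidden pairs are the recoverable ground
truth that a link predictor should rank above random non-interacting
pairs.  Module structure is the minimal generative model under which
both diffusion proximity and metapath relevance carry signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hetnet import EdgeSet, HetNet, LNCRNA, NodeRegistry, PROTEIN, build_hetnet


@dataclass
class SyntheticConfig:
    """Generation parameters.

    ``p_within``/``p_between`` are Bernoulli edge rates for the PP and LL
    layers inside/across modules; ``pl_within`` is the rate at which a
    within-module (protein, lncRNA) pair is a true interaction;
    ``noise_rate`` is the fraction of true interactions hidden from the
    network (these become the positives to recover).  LL co-expression
    weights are drawn from Beta(5, 2) so that the 0.5 edge-weight
    threshold is actually exercised; PP and observed PL edges carry
    weight 1.0 (experimental evidence dominates co-expression).
    """

    n_proteins: int = 200
    n_lncrnas: int = 200
    n_modules: int = 5
    p_within: float = 0.3
    p_between: float = 0.02
    pl_within: float = 0.3
    noise_rate: float = 0.3
    seed: int = 42

    def validate(self) -> None:
        for name in ("p_within", "p_between", "pl_within", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_modules < 1:
            raise ValueError("need at least one module")
        if min(self.n_proteins, self.n_lncrnas) < self.n_modules:
            raise ValueError("fewer nodes than modules on one side")
        if self.p_within <= self.p_between:
            raise ValueError("p_within must exceed p_between for a learnable signal")


@dataclass
class SyntheticTruth:
    """Generated network plus the planted interaction ground truth."""

    net: HetNet
    config: SyntheticConfig
    module_of: dict[str, int]
    true_interactions: list[tuple[str, str]]
    observed_interactions: list[tuple[str, str]]
    hidden_positives: list[tuple[str, str]]


def _block_edges(
    rng: np.random.Generator,
    ids_a: list[str],
    ids_b: list[str],
    modules_a: np.ndarray,
    modules_b: np.ndarray,
    p_within: float,
    p_between: float,
    same_side: bool,
) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(ids_a):
        start = i + 1 if same_side else 0
        for j in range(start, len(ids_b)):
            p = p_within if modules_a[i] == modules_b[j] else p_between
            if rng.random() < p:
                pairs.append((a, ids_b[j]))
    return pairs


def generate(config: SyntheticConfig) -> SyntheticTruth:
    """Draw a synthetic heterogeneous network; deterministic under the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    prot_ids = [f"prot{i:04d}" for i in range(config.n_proteins)]
    lnc_ids = [f"lnc{i:04d}" for i in range(config.n_lncrnas)]
    prot_mod = rng.integers(0, config.n_modules, size=config.n_proteins)
    lnc_mod = rng.integers(0, config.n_modules, size=config.n_lncrnas)
    module_of = {**dict(zip(prot_ids, prot_mod.tolist())),
                 **dict(zip(lnc_ids, lnc_mod.tolist()))}

    pp_pairs = _block_edges(
        rng, prot_ids, prot_ids, prot_mod, prot_mod,
        config.p_within, config.p_between, same_side=True,
    )
    ll_pairs = _block_edges(
        rng, lnc_ids, lnc_ids, lnc_mod, lnc_mod,
        config.p_within, config.p_between, same_side=True,
    )
    pp = EdgeSet("PP", pp_pairs, np.ones(len(pp_pairs)))
    ll = EdgeSet("LL", ll_pairs, rng.beta(5.0, 2.0, size=len(ll_pairs)))

    true_pl: list[tuple[str, str]] = []
    for i, p in enumerate(prot_ids):
        for j, l in enumerate(lnc_ids):
            if prot_mod[i] == lnc_mod[j] and rng.random() < config.pl_within:
                true_pl.append((p, l))

    n_hidden = int(round(config.noise_rate * len(true_pl)))
    hidden_idx = set(
        rng.choice(len(true_pl), size=n_hidden, replace=False).tolist()
    ) if n_hidden else set()
    hidden = [pr for k, pr in enumerate(true_pl) if k in hidden_idx]
    observed = [pr for k, pr in enumerate(true_pl) if k not in hidden_idx]
    pl = EdgeSet("PL", observed, np.ones(len(observed)))

    registry = NodeRegistry(
        prot_ids + lnc_ids,
        {**{p: PROTEIN for p in prot_ids}, **{l: LNCRNA for l in lnc_ids}},
    )
    net = build_hetnet([pp, ll, pl], registry=registry, threshold=0.5)
    return SyntheticTruth(
        net=net,
        config=config,
        module_of=module_of,
        true_interactions=true_pl,
        observed_interactions=observed,
        hidden_positives=hidden,
    )


@dataclass
class LabelledPairSet:
    """Positive and negative (protein, lncRNA) pairs for supervision."""

    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]

    @property
    def ratio(self) -> float:
        return len(self.negatives) / max(len(self.positives), 1)

    def pairs_and_labels(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        pairs = self.positives + self.negatives
        y = np.concatenate(
            [np.ones(len(self.positives), dtype=int),
             np.zeros(len(self.negatives), dtype=int)]
        )
        return pairs, y


def make_benchmark(
    truth: SyntheticTruth,
    ratio: int = 1,
    seed: int = 0,
    test_fraction: float = 0.5,
) -> tuple[LabelledPairSet, LabelledPairSet]:
    """Split hidden positives into train/test and sample matched negatives.

    ``ratio`` is the negatives-per-positive multiplier (1, 2, 5, 10 ...).
    Negatives are drawn uniformly without replacement from all
    (protein, lncRNA) pairs that are not true interactions; train and
    test share no pair.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    hidden = list(truth.hidden_positives)
    if len(hidden) < 2:
        raise ValueError("not enough hidden positives to build a benchmark")
    rng.shuffle(hidden)
    n_test = int(round(test_fraction * len(hidden)))
    test_pos, train_pos = hidden[:n_test], hidden[n_test:]

    reg = truth.net.registry
    prot_ids = [reg.ids[k] for k in truth.net.protein_indices()]
    lnc_ids = [reg.ids[k] for k in truth.net.lncrna_indices()]
    forbidden = set(truth.true_interactions)
    candidates = [
        (p, l) for p in prot_ids for l in lnc_ids if (p, l) not in forbidden
    ]
    n_needed = ratio * (len(train_pos) + len(test_pos))
    if n_needed > len(candidates):
        raise ValueError("not enough non-interacting pairs for requested ratio")
    chosen = rng.choice(len(candidates), size=n_needed, replace=False)
    negatives = [candidates[k] for k in chosen]
    n_train_neg = ratio * len(train_pos)
    train = LabelledPairSet(train_pos, negatives[:n_train_neg])
    test = LabelledPairSet(test_pos, negatives[n_train_neg:])
    return train, test
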