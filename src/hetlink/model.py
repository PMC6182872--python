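"""Pair feature assembly and the gradient-tree-boosting classifier.

Each (protein, lncRNA) pair is described by the concatenation of the
two nodes' diffusion embeddings (n dimensions each) and the pair's
HeteSim score vector over the metapath catalogue (14 entries), giving
2n + 14 features — 1,014 at the default n = 500.  The classifier is a
stagewise additive ensemble of regression trees fit to the logistic
loss log(1 + exp(-y * theta(x))) with labels y in {+1, -1}; external
files use the conventional {1, 0} encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .diffusion import EmbeddingFactorization
from .hetesim import HeteSimFeatures
from .hetnet import NodeRegistry

_PERSIST_VERSION = 1

FEATURE_GROUPS = ("diffusion", "hetesim")


class FeatureSchemaError(ValueError):
    """Feature layout of the input does not match the trained model."""


@dataclass
class FeatureSchema:
    """Frozen layout of the pair feature vector."""

    embedding_dim: int
    path_names: list[str]
    groups: tuple[str, ...] = FEATURE_GROUPS

    @property
    def length(self) -> int:
        n = 0
        if "diffusion" in self.groups:
            n += 2 * self.embedding_dim
        if "hetesim" in self.groups:
            n += len(self.path_names)
        return n


def assemble_features(
    pairs: list[tuple[str, str]],
    registry: NodeRegistry,
    embedding: EmbeddingFactorization | None,
    hetesim: HeteSimFeatures | None,
    groups: tuple[str, ...] = FEATURE_GROUPS,
) -> tuple[np.ndarray, FeatureSchema]:
    """Concatenate [protein embedding | lncRNA embedding | HeteSim scores].

    ``groups`` selects the feature blocks ("diffusion", "hetesim" or
    both) and the pair order of the output matches the input order.
    """
    unknown = set(groups) - set(FEATURE_GROUPS)
    if unknown or not groups:
        raise ValueError(f"bad feature groups {groups!r}")
    blocks: list[np.ndarray] = []
    if "diffusion" in groups:
        if embedding is None:
            raise ValueError("diffusion group requested but no embedding given")
        X = embedding.X
        rows_p, rows_l = [], []
        for p, l in pairs:
            for nid in (p, l):
                if nid not in registry.index:
                    raise KeyError(f"no embedding for node {nid!r}")
            rows_p.append(registry.index[p])
            rows_l.append(registry.index[l])
        blocks.append(X[rows_p])
        blocks.append(X[rows_l])
    if "hetesim" in groups:
        if hetesim is None:
            raise ValueError("hetesim group requested but no scores given")
        pos = {pair: k for k, pair in enumerate(hetesim.pairs)}
        try:
            rows = [pos[pair] for pair in pairs]
        except KeyError as exc:
            raise KeyError(f"no HeteSim scores for pair {exc.args[0]!r}") from exc
        blocks.append(hetesim.scores[rows])
    feats = np.hstack(blocks)
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite feature values")
    schema = FeatureSchema(
        embedding_dim=embedding.n if embedding is not None and "diffusion" in groups else 0,
        path_names=list(hetesim.path_names) if hetesim is not None and "hetesim" in groups else [],
        groups=tuple(groups),
    )
    return feats, schema


@dataclass
class GTBParams:
    """Boosting hyperparameters; unstated ones follow library defaults."""

    n_trees: int = 600
    max_depth: int = 13
    learning_rate: float = 0.1
    subsample: float = 1.0


@dataclass
class GTBModel:
    clf: GradientBoostingClassifier
    schema: FeatureSchema
    params: GTBParams

    def staged_train_losses(self, X: np.ndarray, y01: np.ndarray) -> np.ndarray:
        """Mean logistic loss after each boosting stage (for diagnostics)."""
        y_pm = np.where(np.asarray(y01) > 0, 1.0, -1.0)
        losses = []
        for theta in self.clf.staged_decision_function(X):
            losses.append(float(np.mean(np.logaddexp(0.0, -y_pm * theta.ravel()))))
        return np.array(losses)


def train_gtb(
    X: np.ndarray,
    y: np.ndarray,
    schema: FeatureSchema,
    params: GTBParams | None = None,
    seed: int = 0,
) -> GTBModel:
    """Fit the boosted-tree classifier; reproducible under the seed."""
    params = params or GTBParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[1] != schema.length:
        raise FeatureSchemaError(
            f"feature matrix has {X.shape[1]} columns, schema expects {schema.length}"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    clf = GradientBoostingClassifier(
        loss="log_loss",
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        learning_rate=params.learning_rate,
        subsample=params.subsample,
        random_state=int(seed),
    )
    clf.fit(X, y)
    return GTBModel(clf, schema, params)


def predict(model: GTBModel, X: np.ndarray) -> np.ndarray:
    """Interaction probability per pair (logistic transform of the ensemble)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.schema.length:
        raise FeatureSchemaError(
            f"feature matrix shape {X.shape} does not match schema length "
            f"{model.schema.length}"
        )
    return model.clf.predict_proba(X)[:, 1]


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    schema: FeatureSchema,
    trees_grid: list[int],
    depth_grid: list[int],
    folds: int = 10,
    seed: int = 0,
    learning_rate: float = 0.1,
) -> tuple[GTBParams, list[dict]]:
    """Pick (n_trees, max_depth) by mean CV AUC over a stratified k-fold.

    Ties break toward fewer trees, then shallower trees.  Returns the
    winning parameters and the full table of grid cells.
    """
    if not trees_grid or not depth_grid:
        raise ValueError("empty grid")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    splits = list(skf.split(X, y))
    table: list[dict] = []
    for n_trees, depth in product(sorted(trees_grid), sorted(depth_grid)):
        params = GTBParams(n_trees=n_trees, max_depth=depth,
                           learning_rate=learning_rate)
        aucs = []
        for tr, te in splits:
            model = train_gtb(X[tr], y[tr], schema, params, seed=seed)
            aucs.append(roc_auc_score(y[te], predict(model, X[te])))
        table.append(
            {"n_trees": n_trees, "max_depth": depth,
             "mean_auc": float(np.mean(aucs)), "sd_auc": float(np.std(aucs))}
        )
    best = max(table, key=lambda c: (c["mean_auc"], -c["n_trees"], -c["max_depth"]))
    return GTBParams(n_trees=best["n_trees"], max_depth=best["max_depth"],
                     learning_rate=learning_rate), table


def save_model(model: GTBModel, path: str | Path) -> None:
    """Persist the model with its feature schema for hard schema checks."""
    joblib.dump(
        {
            "version": _PERSIST_VERSION,
            "schema": {
                "embedding_dim": model.schema.embedding_dim,
                "path_names": model.schema.path_names,
                "groups": list(model.schema.groups),
            },
            "params": model.params,
            "clf": model.clf,
        },
        path,
    )


def load_model(path: str | Path) -> GTBModel:
    blob = joblib.load(path)
    if blob.get("version") != _PERSIST_VERSION:
        raise FeatureSchemaError(
            f"unsupported model file version {blob.get('version')!r}"
        )
    s = blob["schema"]
    schema = FeatureSchema(
        embedding_dim=s["embedding_dim"],
        path_names=list(s["path_names"]),
        groups=tuple(s["groups"]),
    )
    return GTBModel(blob["clf"], schema, blob["params"])
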