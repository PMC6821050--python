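"""Boosted-ensemble classifier over the six-feature vectors.

Training follows the AdaBoost scheme: a sequence of depth-limited decision
trees in which examples misclassified by earlier trees are upweighted for
later ones, and the stage-weighted ensemble margin is mapped through a
logistic transform into a confidence score in [0, 1]. Defaults are 50
boosting rounds of depth-3 trees.

Feature importance is measured by out-of-sample permutation: the mean drop
in holdout AUROC when one feature column is shuffled, clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

from .io import FEATURE_ORDER

_MODEL_FORMAT_VERSION = 1


@dataclass
class TrainedModel:
    """A fitted boosting ensemble plus the metadata needed to apply it."""

    clf: AdaBoostClassifier
    feature_order: tuple[str, ...]
    n_trees: int
    max_depth: int
    learning_rate: float
    seed: int
    n_pos: int
    n_neg: int

    @property
    def stage_weights(self) -> np.ndarray:
        return self.clf.estimator_weights_[: len(self.clf.estimators_)]


@dataclass
class ImportanceResult:
    """Per-feature permutation importance on held-out examples.

    Two scales are reported. ``importance`` is the mean decrease in holdout
    AUROC of the whole ensemble when the feature's column is permuted
    (clipped at 0). ``relative`` is the per-weak-learner statistic: each
    tree's holdout-accuracy decrease under permutation, averaged over
    permutations, then mean/std across the ensemble's trees, clipped at 0
    and normalized to sum to 1. The per-tree scale credits features that
    many trees rely on consistently even when the rest of the ensemble can
    compensate, and is the scale on which relative contributions of
    redundant features are comparable.
    """

    importance: dict[str, float]
    relative: dict[str, float]
    method: str = "oob_permutation"
    base_auroc: float = float("nan")


def _as_matrix(
    features, feature_order: tuple[str, ...] | None
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        if feature_order is not None:
            order = tuple(feature_order)
        elif all(c in features.columns for c in FEATURE_ORDER):
            order = FEATURE_ORDER
        else:
            raise ValueError(
                "DataFrame lacks the canonical feature columns; pass feature_order"
            )
        return features.loc[:, list(order)].to_numpy(dtype=float), order
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-dimensional")
    if feature_order is None:
        if X.shape[1] == len(FEATURE_ORDER):
            order = FEATURE_ORDER
        else:
            order = tuple(f"f{i}" for i in range(X.shape[1]))
    else:
        order = tuple(feature_order)
    return X, order


def train(
    features,
    labels,
    feature_order: tuple[str, ...] | None = None,
    n_trees: int = 50,
    max_depth: int = 2,
    learning_rate: float = 1.0,
    seed: int = 0,
) -> TrainedModel:
    """Fit the boosting ensemble on labeled feature vectors.

    ``features`` may be a DataFrame carrying the feature columns or a plain
    matrix; ``labels`` are 0/1. Deterministic under ``seed``.
    """
    X, order = _as_matrix(features, feature_order)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels differ in length")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite feature values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    clf = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=max_depth, random_state=seed),
        n_estimators=n_trees,
        learning_rate=learning_rate,
        random_state=seed,
    )
    clf.fit(X, y)
    return TrainedModel(
        clf=clf,
        feature_order=order,
        n_trees=n_trees,
        max_depth=max_depth,
        learning_rate=learning_rate,
        seed=seed,
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
    )


def predict(model: TrainedModel, features) -> np.ndarray:
    """Confidence scores in [0, 1]; higher = more likely interacting.

    The score is a monotone (logistic-style) transform of the stage-weighted
    ensemble margin, so it preserves the ranking of the raw boosting output.
    """
    X, order = _as_matrix(features, model.feature_order)
    if X.shape[1] != len(model.feature_order):
        raise ValueError(
            f"expected {len(model.feature_order)} features "
            f"({', '.join(model.feature_order)}), got {X.shape[1]}"
        )
    if order != tuple(model.feature_order):
        raise ValueError(f"feature order mismatch: {order} vs {model.feature_order}")
    scores = model.clf.predict_proba(X)[:, 1]
    return np.clip(scores, 0.0, 1.0)


def oob_permutation_importance(
    model: TrainedModel,
    features,
    labels,
    seed: int = 0,
    n_permutations: int = 10,
) -> ImportanceResult:
    """Permutation importance on held-out examples.

    For each feature, the column is shuffled ``n_permutations`` times. The
    ``importance`` scale is the mean decrease in whole-ensemble holdout AUROC
    relative to the intact table, clipped at 0. The ``relative`` scale is
    computed per weak learner (mean holdout-accuracy decrease across the
    ensemble's trees divided by its std, clipped at 0) and normalized to sum
    to 1. ``features``/``labels`` must be examples the model was not trained
    on.
    """
    from .evaluate import auroc  # local import to avoid a cycle

    X, order = _as_matrix(features, model.feature_order)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    base = auroc(predict(model, X), y)
    estimators = model.clf.estimators_
    tree_base_acc = np.array([(est.predict(X) == y).mean() for est in estimators])

    importance: dict[str, float] = {}
    per_tree: dict[str, float] = {}
    for j, name in enumerate(order):
        drops = np.empty(n_permutations)
        tree_drops = np.zeros((len(estimators), n_permutations))
        for k in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[k] = base - auroc(predict(model, Xp), y)
            for t, est in enumerate(estimators):
                tree_drops[t, k] = tree_base_acc[t] - (est.predict(Xp) == y).mean()
        importance[name] = max(0.0, float(drops.mean()))
        mean_by_tree = tree_drops.mean(axis=1)
        sd = mean_by_tree.std(ddof=1) if len(estimators) > 1 else 0.0
        per_tree[name] = max(0.0, float(mean_by_tree.mean() / sd)) if sd > 0 else 0.0

    total = sum(per_tree.values())
    relative = {k: (v / total if total > 0 else 0.0) for k, v in per_tree.items()}
    return ImportanceResult(
        importance=importance, relative=relative, base_auroc=float(base)
    )


def save_model(model: TrainedModel, path) -> None:
    """Serialize to a single versioned file."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "clf": model.clf,
        "feature_order": list(model.feature_order),
        "n_trees": model.n_trees,
        "max_depth": model.max_depth,
        "learning_rate": model.learning_rate,
        "seed": model.seed,
        "n_pos": model.n_pos,
        "n_neg": model.n_neg,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version}")
    return TrainedModel(
        clf=payload["clf"],
        feature_order=tuple(payload["feature_order"]),
        n_trees=payload["n_trees"],
        max_depth=payload["max_depth"],
        learning_rate=payload["learning_rate"],
        seed=payload["seed"],
        n_pos=payload["n_pos"],
        n_neg=payload["n_neg"],
    )
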