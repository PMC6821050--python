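"""ROC / precision-recall evaluation and the testing protocols.

AUROC equals the Mann-Whitney U statistic normalized by n_pos * n_neg (tied
scores contribute 1/2). AUPR is the step-wise area under the precision-recall
curve with no linear interpolation between points, so a random scorer
converges to the class prevalence. Two protocols are provided: *self-test*
(seeded stratified half-split of one dataset) and *cross-sample test* (train
on one dataset's balanced sample, score every labeled pair of another).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import train_test_split

from . import model as model_mod
from .io import FEATURE_ORDER

#: Order in which features are accumulated in the ablation protocol
#: (correlation and expression features first, distance last).
ABLATION_ORDER = ("EGC", "GS", "EWS", "GWS", "WEEC", "DIS")


@dataclass
class EvalResult:
    auroc: float
    aupr: float
    n_pos: int
    n_neg: int
    protocol: str
    roc_points: list[tuple[float, float]] = field(default_factory=list, repr=False)
    pr_points: list[tuple[float, float]] = field(default_factory=list, repr=False)
    features_used: tuple[str, ...] = FEATURE_ORDER


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auroc(scores, labels) -> float:
    """Area under the ROC curve (midrank tie convention)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Step-wise area under the precision-recall curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def evaluate_scores(scores, labels, protocol: str, features_used=FEATURE_ORDER) -> EvalResult:
    """Bundle AUROC/AUPR and the underlying curves for one scored set."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return EvalResult(
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
        protocol=protocol,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        pr_points=list(zip(recall.tolist(), precision.tolist())),
        features_used=tuple(features_used),
    )


def _split_xy(dataset: pd.DataFrame, features: tuple[str, ...]):
    missing = [c for c in (*features, "label") if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    return dataset.loc[:, list(features)], dataset["label"].to_numpy(dtype=int)


def half_split(dataset: pd.DataFrame, seed: int) -> np.ndarray:
    """Boolean training mask for a stratified half-split.

    When the table carries a ``gene_id`` column the split is grouped by gene:
    all pairs of one gene land on the same side, assigned greedily (in
    seeded random gene order) to keep the positive counts of the halves
    balanced. Grouping matters at small sample sizes — a plain row split
    puts the same gene's exact expression value on both sides, and a tree
    can memorize gene identity instead of learning signal. Without a
    ``gene_id`` column the split is a plain label-stratified row split.
    """
    y = dataset["label"].to_numpy(dtype=int)
    if "gene_id" not in dataset.columns:
        idx_tr, _ = train_test_split(
            np.arange(len(y)), test_size=0.5, stratify=y, random_state=seed
        )
        mask = np.zeros(len(y), dtype=bool)
        mask[idx_tr] = True
        return mask
    rng = np.random.default_rng(seed)
    genes = dataset["gene_id"].to_numpy()
    unique = np.array(sorted(set(genes)))
    rng.shuffle(unique)
    pos_count = {0: 0, 1: 0}
    tot_count = {0: 0, 1: 0}
    side_of: dict[str, int] = {}
    pos_per_gene = pd.Series(y, index=genes).groupby(level=0).sum()
    n_per_gene = pd.Series(1, index=genes).groupby(level=0).sum()
    for g in unique:
        p = int(pos_per_gene[g])
        if pos_count[0] != pos_count[1]:
            side = 0 if pos_count[0] < pos_count[1] else 1
        else:
            side = 0 if tot_count[0] <= tot_count[1] else 1
        side_of[g] = side
        pos_count[side] += p
        tot_count[side] += int(n_per_gene[g])
    return np.array([side_of[g] == 0 for g in genes])


def self_test(
    dataset: pd.DataFrame,
    seed: int = 0,
    features: tuple[str, ...] = FEATURE_ORDER,
    **model_kwargs,
) -> EvalResult:
    """Half of the data for training, the other half for testing.

    The split is stratified by label and grouped by gene (see
    ``half_split``), and reproducible under ``seed``.
    """
    X, y = _split_xy(dataset, features)
    if min(np.bincount(y, minlength=2)) < 4:
        raise ValueError("too few examples per class for a stratified half-split")
    mask = half_split(dataset, seed)
    y_tr, y_te = y[mask], y[~mask]
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError("half-split left a single class on one side")
    fitted = model_mod.train(X[mask], y_tr, feature_order=features, seed=seed, **model_kwargs)
    scores = model_mod.predict(fitted, X[~mask])
    result = evaluate_scores(scores, y_te, protocol="self_test", features_used=features)
    return result


def cross_sample_test(
    train_dataset: pd.DataFrame,
    test_dataset: pd.DataFrame,
    seed: int = 0,
    features: tuple[str, ...] = FEATURE_ORDER,
    balance_train: bool = True,
    **model_kwargs,
) -> EvalResult:
    """Train on one sample, evaluate every labeled pair of another.

    With ``balance_train`` (the training protocol) the model is fitted on the
    balanced draw (half the positives + equal negatives) of the training
    dataset; the test dataset is scored in full.
    """
    from .pairs import balance_training_set

    for col in FEATURE_ORDER:
        if col in features and (col not in train_dataset.columns or col not in test_dataset.columns):
            raise ValueError(f"feature column {col} missing from one dataset")
    train_df = train_dataset
    if balance_train:
        train_df, _ = balance_training_set(train_dataset, seed=seed)
    X_tr, y_tr = _split_xy(train_df, features)
    X_te, y_te = _split_xy(test_dataset, features)
    fitted = model_mod.train(X_tr, y_tr, feature_order=features, seed=seed, **model_kwargs)
    scores = model_mod.predict(fitted, X_te)
    return evaluate_scores(scores, y_te, protocol="cross_sample", features_used=features)


def feature_ablation(
    dataset: pd.DataFrame,
    seed: int = 0,
    order: tuple[str, ...] = ABLATION_ORDER,
    **model_kwargs,
) -> list[EvalResult]:
    """Self-test performance on nested cumulative feature subsets.

    Features are added one at a time in ``order`` (sizes 1..6 by default),
    all evaluated on the same seeded stratified half-split.
    """
    X_all, y = _split_xy(dataset, tuple(order))
    mask = half_split(dataset, seed)
    results = []
    for k in range(1, len(order) + 1):
        subset = tuple(order[:k])
        X = X_all.loc[:, list(subset)]
        fitted = model_mod.train(
            X[mask], y[mask], feature_order=subset, seed=seed, **model_kwargs
        )
        scores = model_mod.predict(fitted, X[~mask])
        results.append(
            evaluate_scores(scores, y[~mask], protocol="self_test", features_used=subset)
        )
    return results


def result_to_dict(result: EvalResult, include_curves: bool = False) -> dict:
    """JSON-friendly summary of an EvalResult."""
    out = {
        "auroc": result.auroc,
        "aupr": result.aupr,
        "n_pos": result.n_pos,
        "n_neg": result.n_neg,
        "protocol": result.protocol,
        "features_used": list(result.features_used),
    }
    if include_curves:
        out["roc_points"] = result.roc_points
        out["pr_points"] = result.pr_points
    return out
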