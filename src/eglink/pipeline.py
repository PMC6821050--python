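"""High-level wiring: dataset -> labeled, filtered, feature-annotated tables.

These helpers chain candidate-pair enumeration, anchor-overlap labeling, the
training filters (evidence support >= 0.5, target gene FPKM > 0) and feature
computation, and are shared by the CLI, the examples and the tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import compute_feature_table
from .pairs import filter_training_pairs
from .simulate import SyntheticDataset


def labeled_pairs(dataset: SyntheticDataset, apply_filters: bool = True) -> pd.DataFrame:
    """The dataset's labeled candidate pairs, optionally after the training filters."""
    pairs = dataset.truth
    if apply_filters:
        pairs = filter_training_pairs(
            pairs, dataset.enhancer_support, dataset.expression_table()
        )
    return pairs


def balanced_subset(
    pairs: pd.DataFrame, seed: int, n_per_class: int | None = None
) -> pd.DataFrame:
    """All positives (or ``n_per_class`` of them) plus an equal random negative draw."""
    rng = np.random.default_rng(seed)
    pos = pairs[pairs["label"] == 1]
    neg = pairs[pairs["label"] == 0]
    n = len(pos) if n_per_class is None else min(n_per_class, len(pos))
    if len(neg) < n:
        raise ValueError(f"insufficient negatives: need {n}, got {len(neg)}")
    pos_idx = rng.choice(pos.index.to_numpy(), size=n, replace=False)
    neg_idx = rng.choice(neg.index.to_numpy(), size=n, replace=False)
    keep = np.sort(np.concatenate([pos_idx, neg_idx]))
    return pairs.loc[keep].reset_index(drop=True)


def prepare_dataset(
    dataset: SyntheticDataset,
    seed: int = 0,
    balanced: bool = True,
    n_per_class: int | None = None,
    apply_filters: bool = True,
    log_expression: bool = False,
) -> pd.DataFrame:
    """Labeled feature table for a synthetic dataset's focal cell type.

    With ``balanced`` (the evaluation protocol) the table holds all positives
    plus an equal-size random draw of negatives; otherwise every labeled
    candidate pair. Features are computed only for the retained pairs.
    """
    pairs = labeled_pairs(dataset, apply_filters=apply_filters)
    if balanced:
        pairs = balanced_subset(pairs, seed=seed, n_per_class=n_per_class)
    table = compute_feature_table(
        pairs.drop(columns=["DIS"]),
        dataset.enhancers,
        dataset.genes,
        dataset.cell_types,
        max_dist=dataset.config.max_dist,
        log_expression=log_expression,
    )
    return table
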