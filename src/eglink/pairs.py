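"""Candidate enhancer-gene pair construction, labeling and sampling.

Candidate pairs are all (enhancer, gene) combinations on one chromosome whose
enhancer midpoint lies within 1 Mbp of the gene TSS. A pair is labeled
positive when some chromatin loop of the same cell type has one anchor
overlapping the enhancer and the other anchor overlapping the gene's promoter
(>= 1 bp on each anchor, either anchor assignment); every other candidate is
negative. Training draws are balanced: half of the positives plus an equal
number of negatives.

Pair tables are pandas DataFrames with columns ``enhancer_id``, ``gene_id``,
``cell_type``, ``chrom`` and ``DIS`` (plus ``label`` once labeled: 1 positive,
0 negative).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .core import Enhancer, Gene, GenomicInterval, InteractionRecord

MAX_DIST_DEFAULT = 1_000_000
PROMOTER_UPSTREAM = 5_000
PROMOTER_DOWNSTREAM = 500


def derive_promoter(gene: Gene) -> GenomicInterval:
    """Promoter = 5 kbp upstream to 0.5 kbp downstream of the TSS (strand-aware).

    Clipped at position 0 near the chromosome start.
    """
    if gene.strand == "+":
        start, end = gene.tss - PROMOTER_UPSTREAM, gene.tss + PROMOTER_DOWNSTREAM
    else:
        start, end = gene.tss - PROMOTER_DOWNSTREAM, gene.tss + PROMOTER_UPSTREAM
    return GenomicInterval(gene.chrom, max(0, start), end)


def ensure_promoters(genes: list[Gene]) -> None:
    """Fill in ``gene.promoter`` for any gene that does not have one yet."""
    for gene in genes:
        if gene.promoter is None:
            gene.promoter = derive_promoter(gene)


def build_candidate_pairs(
    enhancers: list[Enhancer],
    genes: list[Gene],
    cell_type: str,
    max_dist: int = MAX_DIST_DEFAULT,
) -> pd.DataFrame:
    """Enumerate all same-chromosome pairs with midpoint-to-TSS distance <= max_dist.

    The distance recorded is the DIS feature: |enhancer midpoint - TSS|.
    """
    by_chrom: dict[str, list[Enhancer]] = defaultdict(list)
    for enh in enhancers:
        by_chrom[enh.interval.chrom].append(enh)

    rows: list[tuple[str, str, str, str, int]] = []
    for chrom, chrom_enh in by_chrom.items():
        mids = np.array([e.interval.midpoint for e in chrom_enh])
        order = np.argsort(mids, kind="stable")
        mids = mids[order]
        ids = [chrom_enh[i].id for i in order]
        for gene in genes:
            if gene.chrom != chrom:
                continue
            lo = np.searchsorted(mids, gene.tss - max_dist, side="left")
            hi = np.searchsorted(mids, gene.tss + max_dist, side="right")
            for k in range(lo, hi):
                rows.append((ids[k], gene.id, cell_type, chrom, abs(int(mids[k]) - gene.tss)))
    df = pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "cell_type", "chrom", "DIS"])
    return df.sort_values(["chrom", "gene_id", "enhancer_id"], kind="mergesort").reset_index(drop=True)


def label_pairs(
    pairs: pd.DataFrame,
    enhancers: list[Enhancer],
    genes: list[Gene],
    interactions: list[InteractionRecord],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Label candidate pairs against loop anchors.

    Positive iff some interaction of the pair's cell type has the enhancer
    overlapping one anchor and the promoter overlapping the other (each by at
    least ``min_overlap`` bp, trying both anchor assignments). Labels are
    per-cell-type: loops from other cell types never affect a pair.
    """
    ensure_promoters(genes)
    enh_by_id = {e.id: e for e in enhancers}
    gene_by_id = {g.id: g for g in genes}

    positive: set[tuple[str, str, str]] = set()
    for rec in interactions:
        enh_hits_1 = [
            e.id for e in enhancers if e.interval.overlap_length(rec.anchor1) >= min_overlap
        ]
        enh_hits_2 = [
            e.id for e in enhancers if e.interval.overlap_length(rec.anchor2) >= min_overlap
        ]
        prom_hits_1 = [
            g.id for g in genes if g.promoter.overlap_length(rec.anchor1) >= min_overlap
        ]
        prom_hits_2 = [
            g.id for g in genes if g.promoter.overlap_length(rec.anchor2) >= min_overlap
        ]
        for eid in enh_hits_1:
            for gid in prom_hits_2:
                positive.add((eid, gid, rec.cell_type))
        for eid in enh_hits_2:
            for gid in prom_hits_1:
                positive.add((eid, gid, rec.cell_type))

    unknown = set(pairs["enhancer_id"]) - set(enh_by_id)
    if unknown:
        raise KeyError(f"pairs reference unknown enhancers: {sorted(unknown)[:5]}")
    unknown = set(pairs["gene_id"]) - set(gene_by_id)
    if unknown:
        raise KeyError(f"pairs reference unknown genes: {sorted(unknown)[:5]}")

    labeled = pairs.copy()
    keys = list(zip(labeled["enhancer_id"], labeled["gene_id"], labeled["cell_type"]))
    labeled["label"] = np.fromiter((int(k in positive) for k in keys), dtype=int, count=len(keys))
    return labeled


def filter_training_pairs(
    pairs: pd.DataFrame,
    enhancer_support: dict[str, float],
    expression: dict[str, dict[str, float]],
    min_support: float = 0.5,
    min_fpkm_exclusive: float = 0.0,
) -> pd.DataFrame:
    """Apply the training filters: evidence support and expressed target gene.

    Keeps pairs whose enhancer is supported by >= ``min_support`` of the
    evidence tracks and whose gene has FPKM > ``min_fpkm_exclusive`` in the
    pair's cell type ("the potential target genes are expressed").
    """
    missing = set(pairs["enhancer_id"]) - set(enhancer_support)
    if missing:
        raise KeyError(f"no support fraction for enhancers: {sorted(missing)[:5]}")

    support = pairs["enhancer_id"].map(enhancer_support)
    fpkm = np.array(
        [expression[g][c] for g, c in zip(pairs["gene_id"], pairs["cell_type"])]
    )
    keep = (support >= min_support).to_numpy() & (fpkm > min_fpkm_exclusive)
    return pairs.loc[keep].reset_index(drop=True)


def balance_training_set(
    pairs: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the balanced training sample: floor(P/2) positives + equal negatives.

    Everything not drawn forms the holdout. Sampling is reproducible under
    ``seed``.
    """
    if "label" not in pairs.columns:
        raise ValueError("pairs must be labeled before balancing")
    rng = np.random.default_rng(seed)
    pos_idx = pairs.index[pairs["label"] == 1].to_numpy()
    neg_idx = pairs.index[pairs["label"] == 0].to_numpy()
    n_train_pos = len(pos_idx) // 2
    if n_train_pos < 1:
        raise ValueError(f"need at least 2 positives, got {len(pos_idx)}")
    if len(neg_idx) < n_train_pos:
        raise ValueError(
            f"insufficient negatives: need {n_train_pos}, got {len(neg_idx)}"
        )
    train_pos = rng.choice(pos_idx, size=n_train_pos, replace=False)
    train_neg = rng.choice(neg_idx, size=n_train_pos, replace=False)
    train_idx = np.sort(np.concatenate([train_pos, train_neg]))
    holdout_idx = np.setdiff1d(pairs.index.to_numpy(), train_idx)
    return (
        pairs.loc[train_idx].reset_index(drop=True),
        pairs.loc[holdout_idx].reset_index(drop=True),
    )


def subsample_unbalanced(
    pairs: pd.DataFrame, neg_per_pos: int, seed: int
) -> pd.DataFrame:
    """Build an evaluation set with a fixed negative:positive ratio.

    Keeps all positives and draws ``neg_per_pos`` negatives per positive
    (without replacement); used for the unbalanced 1:5 evaluation variant.
    """
    rng = np.random.default_rng(seed)
    pos = pairs[pairs["label"] == 1]
    neg = pairs[pairs["label"] == 0]
    n_neg = neg_per_pos * len(pos)
    if len(neg) < n_neg:
        raise ValueError(f"insufficient negatives: need {n_neg}, got {len(neg)}")
    neg_idx = rng.choice(neg.index.to_numpy(), size=n_neg, replace=False)
    out = pd.concat([pos, pairs.loc[np.sort(neg_idx)]])
    return out.reset_index(drop=True)
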