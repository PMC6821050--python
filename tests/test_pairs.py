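import numpy as np
import pandas as pd
import pytest

import eglink as eg
from eglink.core import Enhancer, Gene, GenomicInterval, InteractionRecord
from eglink.pairs import (
    balance_training_set,
    build_candidate_pairs,
    derive_promoter,
    filter_training_pairs,
    label_pairs,
    subsample_unbalanced,
)
from .conftest import make_enhancer, make_gene


class TestDerivePromoter:
    @pytest.mark.parametrize(
        "tss,strand,expected",
        [
            (10_000, "+", (5_000, 10_500)),
            (10_000, "-", (9_500, 15_000)),
            (3_000, "+", (0, 3_500)),  # clipped at the chromosome start
        ],
    )
    def test_promoter_spans_5kb_upstream_500bp_downstream(self, tss, strand, expected):
        gene = make_gene("G", "chr1", tss, strand)
        promoter = derive_promoter(gene)
        assert (promoter.start, promoter.end) == expected


class TestBuildCandidatePairs:
    def test_distance_uses_enhancer_midpoint(self):
        enh = [make_enhancer("E1", "chr1", 20_000, 20_500, {"A": 1.0})]
        genes = [make_gene("G1", "chr1", 10_000)]
        pairs = build_candidate_pairs(enh, genes, "A")
        assert len(pairs) == 1
        assert pairs.loc[0, "DIS"] == 10_250

    def test_pairs_beyond_window_excluded(self):
        enh = [make_enhancer("E1", "chr1", 2_000_000, 2_001_000, {"A": 1.0})]
        genes = [make_gene("G1", "chr1", 0)]
        assert build_candidate_pairs(enh, genes, "A").empty

    def test_all_in_range_enumeration_matches_brute_force(self):
        # 3 enhancers x 4 genes, everything within the window
        enh = [
            make_enhancer(f"E{i}", "chr1", 100_000 * i + 50_000, 100_000 * i + 51_000, {"A": 1.0})
            for i in range(3)
        ]
        genes = [make_gene(f"G{j}", "chr1", 120_000 * j + 60_000) for j in range(4)]
        pairs = build_candidate_pairs(enh, genes, "A")
        brute = {
            (e.id, g.id)
            for e in enh
            for g in genes
            if abs(e.interval.midpoint - g.tss) <= 1_000_000
        }
        assert len(brute) == 12
        assert set(zip(pairs["enhancer_id"], pairs["gene_id"])) == brute

    def test_no_duplicate_pairs(self, default_dataset):
        pairs = default_dataset.truth
        assert not pairs.duplicated(["enhancer_id", "gene_id", "cell_type"]).any()

    def test_distance_never_exceeds_window(self, default_dataset):
        assert (default_dataset.truth["DIS"] <= 1_000_000).all()
        assert (default_dataset.truth["DIS"] >= 0).all()


def _loop(chrom, s1, e1, s2, e2, cell="A"):
    return InteractionRecord(
        GenomicInterval(chrom, s1, e1), GenomicInterval(chrom, s2, e2), cell, "synthetic"
    )


class TestLabelPairs:
    def setup_method(self):
        self.enh = [make_enhancer("E1", "chr1", 20_000, 21_000, {"A": 1.0})]
        self.genes = [make_gene("G1", "chr1", 100_000, "+")]
        self.pairs = build_candidate_pairs(self.enh, self.genes, "A")

    def test_enhancer_and_promoter_on_opposite_anchors_is_positive(self):
        loops = [_loop("chr1", 19_000, 22_000, 94_000, 101_000)]
        labeled = label_pairs(self.pairs, self.enh, self.genes, loops)
        assert labeled["label"].tolist() == [1]

    def test_swapped_anchor_assignment_also_positive(self):
        loops = [_loop("chr1", 94_000, 101_000, 19_000, 22_000)]
        labeled = label_pairs(self.pairs, self.enh, self.genes, loops)
        assert labeled["label"].tolist() == [1]

    def test_single_anchor_overlap_is_negative(self):
        loops = [_loop("chr1", 19_000, 22_000, 500_000, 505_000)]
        labeled = label_pairs(self.pairs, self.enh, self.genes, loops)
        assert labeled["label"].tolist() == [0]

    def test_other_cell_type_loop_does_not_label(self):
        loops = [_loop("chr1", 19_000, 22_000, 94_000, 101_000, cell="B")]
        labeled = label_pairs(self.pairs, self.enh, self.genes, loops)
        assert labeled["label"].tolist() == [0]

    def test_agrees_with_brute_force_oracle_on_random_fixture(self):
        rng = np.random.default_rng(42)
        enh = [
            make_enhancer(f"E{i}", "chr1", int(s), int(s) + 800, {"A": 1.0})
            for i, s in enumerate(rng.integers(0, 2_000_000, size=40))
        ]
        genes = [
            make_gene(f"G{j}", "chr1", int(t), rng.choice(["+", "-"]))
            for j, t in enumerate(rng.integers(10_000, 2_000_000, size=25))
        ]
        loops = []
        for _ in range(30):
            a, b = rng.integers(0, 2_000_000, size=2)
            loops.append(_loop("chr1", int(a), int(a) + 5_000, int(b), int(b) + 5_000))
        pairs = build_candidate_pairs(enh, genes, "A")
        labeled = label_pairs(pairs, enh, genes, loops)

        # brute-force double loop over pairs x interactions
        from eglink.pairs import ensure_promoters

        ensure_promoters(genes)
        by_id_e = {e.id: e for e in enh}
        by_id_g = {g.id: g for g in genes}
        expected = []
        for eid, gid in zip(labeled["enhancer_id"], labeled["gene_id"]):
            e, g = by_id_e[eid], by_id_g[gid]
            hit = any(
                (e.interval.overlap_length(r.anchor1) >= 1 and g.promoter.overlap_length(r.anchor2) >= 1)
                or (e.interval.overlap_length(r.anchor2) >= 1 and g.promoter.overlap_length(r.anchor1) >= 1)
                for r in loops
            )
            expected.append(int(hit))
        assert labeled["label"].tolist() == expected
        assert sum(expected) > 0  # the fixture actually exercises positives

    def test_every_labeled_pair_is_positive_xor_negative(self, default_dataset):
        labels = default_dataset.truth["label"]
        assert set(labels.unique()) <= {0, 1}
        assert (labels == 1).sum() + (labels == 0).sum() == len(labels)


class TestFilterTrainingPairs:
    def _pairs(self):
        return pd.DataFrame(
            {
                "enhancer_id": ["E1", "E2", "E3"],
                "gene_id": ["G1", "G1", "G2"],
                "cell_type": ["A", "A", "A"],
                "DIS": [1000, 2000, 3000],
            }
        )

    def test_support_and_expression_filters(self):
        support = {"E1": 0.6, "E2": 0.4, "E3": 0.9}
        expr = {"G1": {"A": 2.0}, "G2": {"A": 0.0}}
        kept = filter_training_pairs(self._pairs(), support, expr)
        # E2 dropped (support < 0.5), E3 dropped (FPKM == 0)
        assert kept["enhancer_id"].tolist() == ["E1"]

    def test_missing_support_entry_is_error(self):
        with pytest.raises(KeyError, match="E2"):
            filter_training_pairs(self._pairs(), {"E1": 1.0, "E3": 1.0}, {"G1": {"A": 1.0}, "G2": {"A": 1.0}})


class TestBalanceTrainingSet:
    def _labeled(self, n_pos, n_neg):
        return pd.DataFrame(
            {
                "enhancer_id": [f"E{i}" for i in range(n_pos + n_neg)],
                "gene_id": "G",
                "cell_type": "A",
                "DIS": 1,
                "label": [1] * n_pos + [0] * n_neg,
            }
        )

    def test_half_positives_and_equal_negatives(self):
        train, holdout = balance_training_set(self._labeled(100, 1000), seed=0)
        assert (train["label"] == 1).sum() == 50
        assert (train["label"] == 0).sum() == 50
        assert (holdout["label"] == 1).sum() == 50
        assert (holdout["label"] == 0).sum() == 950

    def test_same_seed_reproduces_selection(self):
        df = self._labeled(40, 400)
        t1, h1 = balance_training_set(df, seed=7)
        t2, h2 = balance_training_set(df, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_insufficient_negatives_error_states_counts(self):
        with pytest.raises(ValueError, match="5"):
            balance_training_set(self._labeled(10, 3), seed=0)


class TestSubsampleUnbalanced:
    def test_one_to_five_ratio(self):
        df = pd.DataFrame({"label": [1] * 20 + [0] * 500, "x": range(520)})
        out = subsample_unbalanced(df, neg_per_pos=5, seed=3)
        assert (out["label"] == 1).sum() == 20
        assert (out["label"] == 0).sum() == 100
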