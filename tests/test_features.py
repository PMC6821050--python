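import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import eglink as eg
from eglink.core import GenomicInterval
from eglink.features import (
    FEATURE_ORDER,
    WindowContext,
    build_window,
    compute_dis,
    compute_egc,
    compute_ews,
    compute_feature_table,
    compute_gs,
    compute_gws,
    compute_weec,
    pearson,
)
from .conftest import make_enhancer, make_gene


def pearson_oracle(x, y):
    """Deviation-product formula, written independently of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return 0.0 if den == 0 else num / den


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # hand arithmetic
        ],
    )
    def test_hand_cases_exact(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gives_zero_not_nan(self):
        assert pearson([5, 5, 5], [1, 2, 3]) == 0.0

    @pytest.mark.parametrize("x,y", [([1, 2], [1, 2]), ([1, 2, 3], [1, 2])])
    def test_short_or_mismatched_input_rejected(self, x, y):
        with pytest.raises(ValueError):
            pearson(x, y)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_independent_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        assert pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)


class TestEgcGsDis:
    def test_proportional_profiles_give_unit_correlation(self):
        cells = [f"C{i}" for i in range(10)]
        act = {c: float(i + 1) for i, c in enumerate(cells)}
        expr = {c: 2.0 * (i + 1) for i, c in enumerate(cells)}
        enh = make_enhancer("E", "chr1", 0, 100, act)
        gene = make_gene("G", "chr1", 5_000, expression=expr)
        assert compute_egc(enh, gene, cells) == pytest.approx(1.0)

    def test_constant_activity_gives_zero(self):
        cells = ["A", "B", "C"]
        enh = make_enhancer("E", "chr1", 0, 100, {c: 3.0 for c in cells})
        gene = make_gene("G", "chr1", 5_000, expression={"A": 1, "B": 2, "C": 3})
        assert compute_egc(enh, gene, cells) == 0.0

    def test_missing_cell_type_is_error(self):
        enh = make_enhancer("E", "chr1", 0, 100, {"A": 1.0, "B": 2.0})
        gene = make_gene("G", "chr1", 5_000, expression={"A": 1, "B": 2, "C": 3})
        with pytest.raises(KeyError):
            compute_egc(enh, gene, ["A", "B", "C"])

    def test_planted_pairs_recover_target_correlation(self):
        """Co-regulated planted pairs correlate near the configured rho."""
        ds = eg.generate(eg.SimulationConfig(seed=7))
        enh = {e.id: e for e in ds.enhancers}
        genes = {g.id: g for g in ds.genes}
        rs = [
            pearson_oracle(
                [enh[a].activity[c] for c in ds.cell_types],
                [genes[b].expression[c] for c in ds.cell_types],
            )
            for (a, b), coupled in zip(ds.planted_pairs, ds.planted_coupled)
            if coupled
        ]
        assert np.mean(rs) == pytest.approx(0.8, abs=0.15)

    def test_gs_returns_fpkm_unchanged(self):
        gene = make_gene("G", "chr1", 5_000, expression={"A": 4.743, "B": 0.0})
        assert compute_gs(gene, "A") == 4.743
        assert compute_gs(gene, "B") == 0.0
        with pytest.raises(KeyError):
            compute_gs(gene, "Z")

    def test_dis_examples(self):
        enh = make_enhancer("E", "chr1", 20_000, 20_500, {"A": 1.0})
        gene = make_gene("G", "chr1", 10_000)
        assert compute_dis(enh, gene) == 10_250
        at_tss = make_enhancer("E2", "chr1", 9_750, 10_250, {"A": 1.0})
        assert compute_dis(at_tss, gene) == 0
        other = make_gene("G2", "chr2", 10_000)
        with pytest.raises(ValueError):
            compute_dis(enh, other)

    def test_dis_matches_arithmetic_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            s = int(rng.integers(0, 10**7))
            ln = int(rng.integers(1, 5_000))
            tss = int(rng.integers(0, 10**7))
            enh = make_enhancer("E", "chr1", s, s + ln, {"A": 1.0})
            gene = make_gene("G", "chr1", tss)
            assert compute_dis(enh, gene) == abs((s + ln // 2) - tss)


class TestWindow:
    def _pair(self):
        enh = make_enhancer("E", "chr1", 20_000, 21_000, {"A": 1.0})
        gene = make_gene("G", "chr1", 100_000, "+", expression={"A": 1.0})
        return enh, gene

    def test_empty_window_between_elements(self):
        enh, gene = self._pair()
        ctx = build_window(enh, gene, [enh], [gene], "A")
        # window runs from the enhancer's inner edge to the promoter's inner edge
        assert ctx.window == GenomicInterval("chr1", 21_000, 95_000)
        assert ctx.l_window == 74_000
        assert ctx.contained_enhancers == []
        assert ctx.contained_genes == []

    def test_fully_contained_enhancer_counts_full_length(self):
        enh, gene = self._pair()
        inner = make_enhancer("E2", "chr1", 50_000, 50_400, {"A": 2.5})
        ctx = build_window(enh, gene, [enh, inner], [gene], "A")
        assert ctx.contained_enhancers == [(2.5, 400)]

    def test_partial_overlap_is_clipped(self):
        enh, gene = self._pair()
        edge = make_enhancer("E3", "chr1", 94_500, 95_500, {"A": 1.0})
        ctx = build_window(enh, gene, [enh, edge], [gene], "A")
        (sig, clip) = ctx.contained_enhancers[0]
        # interval-intersection oracle
        assert clip == min(95_500, 95_000) - max(94_500, 21_000) == 500

    def test_overlapping_elements_get_length_floor(self):
        enh = make_enhancer("E", "chr1", 94_000, 96_000, {"A": 1.0})
        gene = make_gene("G", "chr1", 100_000, "+", expression={"A": 1.0})
        ctx = build_window(enh, gene, [enh], [gene], "A")
        assert ctx.l_window == 1
        assert compute_ews(ctx) == 0.0


class TestWindowSignals:
    def test_ews_hand_case(self):
        ctx = WindowContext(None, 1_000, contained_enhancers=[(2.0, 100), (1.0, 200)])
        assert compute_ews(ctx) == pytest.approx(0.4, abs=1e-12)

    def test_ews_empty_and_identity(self):
        assert compute_ews(WindowContext(None, 500)) == 0.0
        full = WindowContext(None, 500, contained_enhancers=[(1.0, 500)])
        assert compute_ews(full) == pytest.approx(1.0)

    def test_gws_hand_case(self):
        ctx = WindowContext(None, 10_000, contained_genes=[(5.0, 2_000)])
        assert compute_gws(ctx) == pytest.approx(1.0, abs=1e-12)

    def test_gws_counts_only_genes_inside_window(self):
        enh = make_enhancer("E", "chr1", 20_000, 21_000, {"A": 1.0})
        gene = make_gene("G", "chr1", 200_000, "+", expression={"A": 1.0})
        inside = make_gene(
            "Gi", "chr1", 100_000, "+",
            body=GenomicInterval("chr1", 100_000, 120_000), expression={"A": 3.0},
        )
        outside = make_gene(
            "Go", "chr1", 500_000, "+",
            body=GenomicInterval("chr1", 500_000, 520_000), expression={"A": 9.0},
        )
        ctx = build_window(enh, gene, [enh], [gene, inside, outside], "A")
        assert ctx.contained_genes == [(3.0, 20_000)]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_ews_invariant_to_splitting_a_contained_enhancer(self, seed):
        """Splitting one element into two abutting halves conserves sum(e*L)."""
        rng = np.random.default_rng(seed)
        l_window = int(rng.integers(1_000, 100_000))
        sig = float(rng.uniform(0, 10))
        length = int(rng.integers(2, 900))
        cut = int(rng.integers(1, length))
        whole = WindowContext(None, l_window, contained_enhancers=[(sig, length)])
        halves = WindowContext(
            None, l_window, contained_enhancers=[(sig, cut), (sig, length - cut)]
        )
        assert compute_ews(whole) == pytest.approx(compute_ews(halves), abs=1e-12)


class TestWeec:
    def test_identical_profiles_give_unit_weec(self):
        cells = ["A", "B", "C"]
        act = {"A": 1.0, "B": 2.0, "C": 3.0}
        enh = [make_enhancer(f"E{i}", "chr1", 10_000 * i, 10_000 * i + 500, act) for i in range(3)]
        gene = make_gene("G", "chr1", 15_000, expression={c: 1.0 for c in cells})
        assert compute_weec(gene, enh, cells, enh[0]) == pytest.approx(1.0)

    def test_no_neighbors_defined_as_zero(self):
        cells = ["A", "B", "C"]
        enh = make_enhancer("E", "chr1", 0, 500, {"A": 1.0, "B": 2.0, "C": 3.0})
        gene = make_gene("G", "chr1", 15_000)
        assert compute_weec(gene, [enh], cells, enh) == 0.0

    def test_matches_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(23)
        cells = [f"C{i}" for i in range(8)]
        enh = []
        for i in range(5):
            scores = dict(zip(cells, rng.uniform(0, 10, size=len(cells))))
            enh.append(make_enhancer(f"E{i}", "chr1", 50_000 * i, 50_000 * i + 600, scores))
        gene = make_gene("G", "chr1", 120_000)
        focal = enh[2]
        expected = np.mean(
            [
                pearson_oracle(
                    [focal.activity[c] for c in cells], [o.activity[c] for c in cells]
                )
                for o in enh
                if o.id != focal.id
            ]
        )
        assert compute_weec(gene, enh, cells, focal) == pytest.approx(expected, abs=1e-12)


class TestFeatureTable:
    def test_composition_matches_individual_operations(self, tiny_panel):
        cells, enhancers, genes = tiny_panel
        pairs = eg.build_candidate_pairs(enhancers, genes, "A")
        table = compute_feature_table(pairs, enhancers, genes, cells)
        by_id_e = {e.id: e for e in enhancers}
        by_id_g = {g.id: g for g in genes}
        for _, row in table.iterrows():
            e, g = by_id_e[row.enhancer_id], by_id_g[row.gene_id]
            assert row.EGC == pytest.approx(compute_egc(e, g, cells), abs=1e-12)
            assert row.GS == compute_gs(g, "A")
            assert row.DIS == compute_dis(e, g)
            ctx = build_window(e, g, enhancers, genes, "A")
            assert row.EWS == pytest.approx(compute_ews(ctx), abs=1e-12)
            assert row.GWS == pytest.approx(compute_gws(ctx), abs=1e-12)
            assert row.WEEC == pytest.approx(compute_weec(g, enhancers, cells, e), abs=1e-12)

    def test_repeated_runs_are_bitwise_identical(self, default_dataset):
        pairs = default_dataset.truth.head(200).drop(columns=["DIS"])
        t1 = compute_feature_table(pairs, default_dataset.enhancers, default_dataset.genes, default_dataset.cell_types)
        t2 = compute_feature_table(pairs, default_dataset.enhancers, default_dataset.genes, default_dataset.cell_types)
        for col in FEATURE_ORDER:
            assert (t1[col].to_numpy() == t2[col].to_numpy()).all()

    def test_feature_order_contract(self):
        assert FEATURE_ORDER == ("EGC", "GS", "DIS", "EWS", "GWS", "WEEC")

    def test_unresolvable_id_is_named_in_error(self, tiny_panel):
        cells, enhancers, genes = tiny_panel
        pairs = pd.DataFrame(
            {"enhancer_id": ["EX"], "gene_id": ["G1"], "cell_type": ["A"]}
        )
        with pytest.raises(KeyError, match="EX"):
            compute_feature_table(pairs, enhancers, genes, cells)

    def test_ranges_and_finiteness(self, default_table):
        t = default_table
        assert t["EGC"].between(-1, 1).all()
        assert t["WEEC"].between(-1, 1).all()
        for col in ("GS", "DIS", "EWS", "GWS"):
            assert (t[col] >= 0).all()
        assert np.isfinite(t[list(FEATURE_ORDER)].to_numpy()).all()
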