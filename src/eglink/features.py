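"""The six predictive features for a candidate enhancer-gene pair.

Given an enhancer e with activity scores across n tissue/cell types and a
gene g with FPKM expression across the same panel, the features are:

* **EGC** — Pearson correlation r(e, g) between the enhancer's activity
  vector and the gene's expression vector across the full cell-type panel.
* **GS**  — the gene's FPKM in the focal cell type.
* **DIS** — |enhancer midpoint - TSS| in bp.
* **EWS** — enhancer window signal: sum_i(e_i * L_ei) / L_window over the
  other enhancers lying in the window between the pair's enhancer and
  promoter (activity in the focal cell type, lengths clipped to the window).
* **GWS** — gene window signal: sum_i(g_i * L_gi) / L_window over the other
  genes in that window (FPKM in the focal cell type, gene-body lengths
  clipped to the window).
* **WEEC** — weight of enhancer-enhancer correlation: the mean Pearson
  correlation of the focal enhancer's activity vector with each of the other
  enhancers within 1 Mbp of the gene's TSS.

Conventions chosen where the definitions leave room: the window runs from
the enhancer edge nearest the promoter to the promoter edge nearest the
enhancer; elements partially overlapping the window are counted with their
clipped length; the focal enhancer and focal gene are excluded from their own
window; a zero-variance vector contributes Pearson r = 0; abutting elements
get a 1 bp window-length floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Enhancer, Gene, GenomicInterval
from .io import FEATURE_ORDER
from .pairs import MAX_DIST_DEFAULT, ensure_promoters

__all__ = [
    "FEATURE_ORDER",
    "WindowContext",
    "pearson",
    "compute_egc",
    "compute_gs",
    "compute_dis",
    "build_window",
    "compute_ews",
    "compute_gws",
    "compute_weec",
    "compute_feature_table",
]


def pearson(x, y) -> float:
    """Pearson correlation; r = 0 for zero-variance input instead of NaN.

    Requires equal lengths of at least 3 (a correlation over one or two cell
    types carries no information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0.0:
        return 0.0
    return float((dx * dy).sum() / denom)


def compute_egc(enhancer: Enhancer, gene: Gene, cell_types: list[str]) -> float:
    """Activity-expression correlation across the full cell-type panel."""
    try:
        x = [enhancer.activity[c] for c in cell_types]
    except KeyError as exc:
        raise KeyError(f"enhancer {enhancer.id} has no activity for cell type {exc}") from exc
    try:
        y = [gene.expression[c] for c in cell_types]
    except KeyError as exc:
        raise KeyError(f"gene {gene.id} has no expression for cell type {exc}") from exc
    return pearson(x, y)


def compute_gs(gene: Gene, cell_type: str) -> float:
    """The gene's FPKM in the focal cell type, unchanged."""
    try:
        return gene.expression[cell_type]
    except KeyError as exc:
        raise KeyError(f"gene {gene.id} has no expression for cell type {exc}") from exc


def compute_dis(enhancer: Enhancer, gene: Gene) -> int:
    """|enhancer midpoint - TSS|; midpoint = start + floor(length/2)."""
    if enhancer.interval.chrom != gene.chrom:
        raise ValueError(
            f"{enhancer.id} ({enhancer.interval.chrom}) and {gene.id} ({gene.chrom}) "
            "are on different chromosomes"
        )
    return abs(enhancer.interval.midpoint - gene.tss)


@dataclass
class WindowContext:
    """The genomic window between a pair's enhancer and promoter.

    ``contained_enhancers`` / ``contained_genes`` hold (signal, clipped length)
    tuples for the elements overlapping the window, excluding the focal pair's
    own enhancer and gene.
    """

    window: GenomicInterval | None
    l_window: int
    contained_enhancers: list[tuple[float, int]] = field(default_factory=list)
    contained_genes: list[tuple[float, int]] = field(default_factory=list)


def _window_span(enhancer: Enhancer, promoter: GenomicInterval) -> tuple[int, int]:
    """Inner-edge to inner-edge span; empty (0-length) when elements touch/overlap."""
    if enhancer.interval.end <= promoter.start:
        return enhancer.interval.end, promoter.start
    if promoter.end <= enhancer.interval.start:
        return promoter.end, enhancer.interval.start
    return enhancer.interval.start, enhancer.interval.start  # overlapping elements


def build_window(
    enhancer: Enhancer,
    gene: Gene,
    all_enhancers: list[Enhancer],
    all_genes: list[Gene],
    cell_type: str,
) -> WindowContext:
    """Collect the elements between the pair's enhancer and promoter.

    Elements partially overlapping the window contribute their clipped length;
    the focal enhancer and gene are excluded so a pair cannot inflate its own
    window signal. Abutting or overlapping enhancer/promoter yields an empty
    window with the 1 bp length floor.
    """
    if enhancer.interval.chrom != gene.chrom:
        raise ValueError("enhancer and gene must share a chromosome")
    ensure_promoters([gene])
    w0, w1 = _window_span(enhancer, gene.promoter)
    if w1 <= w0:
        return WindowContext(window=None, l_window=1)
    window = GenomicInterval(gene.chrom, w0, w1)
    contained_enh = []
    for other in all_enhancers:
        if other.id == enhancer.id:
            continue
        clip = other.interval.overlap_length(window)
        if clip > 0:
            contained_enh.append((other.activity[cell_type], clip))
    contained_gen = []
    for other in all_genes:
        if other.id == gene.id:
            continue
        clip = other.body.overlap_length(window)
        if clip > 0:
            contained_gen.append((other.expression[cell_type], clip))
    return WindowContext(window, window.length, contained_enh, contained_gen)


def compute_ews(ctx: WindowContext) -> float:
    """Enhancer window signal: sum_i(e_i * L_ei) / L_window (0 if none)."""
    return sum(sig * length for sig, length in ctx.contained_enhancers) / ctx.l_window


def compute_gws(ctx: WindowContext) -> float:
    """Gene window signal: sum_i(g_i * L_gi) / L_window (0 if none)."""
    return sum(sig * length for sig, length in ctx.contained_genes) / ctx.l_window


def compute_weec(
    gene: Gene,
    all_enhancers: list[Enhancer],
    cell_types: list[str],
    focal_enhancer: Enhancer,
    max_dist: int = MAX_DIST_DEFAULT,
) -> float:
    """Mean correlation of the focal enhancer with the gene's other neighbors.

    The neighborhood is every enhancer whose midpoint is within ``max_dist``
    of the gene's TSS (the same 1 Mbp rule that defines candidate pairs),
    anchored on the gene. With no neighbor besides the focal enhancer the
    value is defined as 0.
    """
    focal = np.array([focal_enhancer.activity[c] for c in cell_types], dtype=float)
    total = 0.0
    m = 1  # the focal enhancer itself
    for other in all_enhancers:
        if other.id == focal_enhancer.id or other.interval.chrom != gene.chrom:
            continue
        if abs(other.interval.midpoint - gene.tss) > max_dist:
            continue
        m += 1
        total += pearson(focal, [other.activity[c] for c in cell_types])
    if m == 1:
        return 0.0
    return total / (m - 1)


# ---------------------------------------------------------------------------
# Vectorized table computation


def _standardized_rows(matrix: np.ndarray) -> np.ndarray:
    """Rows scaled to zero mean, unit norm; zero-variance rows become zero rows.

    With this scaling ``rows_a @ rows_b.T`` is the Pearson correlation and the
    r = 0 convention for flat vectors falls out automatically.
    """
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, centered / norms, 0.0)
    return out


class _FeatureIndex:
    """Precomputed arrays shared by all pairs of one feature-table call."""

    def __init__(
        self,
        enhancers: list[Enhancer],
        genes: list[Gene],
        cell_types: list[str],
        log_expression: bool,
    ):
        self.cell_types = list(cell_types)
        if len(self.cell_types) < 3:
            raise ValueError("need at least 3 cell types for correlation features")
        ensure_promoters(genes)
        self.enh = {e.id: e for e in enhancers}
        self.gene = {g.id: g for g in genes}

        self.activity = np.array(
            [[e.activity[c] for c in self.cell_types] for e in enhancers]
        )
        self.expression = np.array(
            [[g.expression[c] for c in self.cell_types] for g in genes]
        )
        corr_expr = np.log1p(self.expression) if log_expression else self.expression
        self.act_z = _standardized_rows(self.activity)
        self.expr_z = _standardized_rows(corr_expr)
        self.enh_row = {e.id: i for i, e in enumerate(enhancers)}
        self.gene_row = {g.id: i for i, g in enumerate(genes)}
        self.cell_col = {c: i for i, c in enumerate(self.cell_types)}

        # per-chromosome enhancer geometry, sorted by start
        self.enh_geom: dict[str, dict[str, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, e in enumerate(enhancers):
            by_chrom.setdefault(e.interval.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            idx = np.array(idx)
            starts = np.array([enhancers[i].interval.start for i in idx])
            order = np.argsort(starts, kind="stable")
            idx = idx[order]
            self.enh_geom[chrom] = {
                "row": idx,
                "start": starts[order],
                "end": np.array([enhancers[i].interval.end for i in idx]),
                "mid": np.array([enhancers[i].interval.midpoint for i in idx]),
                "max_len": max(enhancers[i].interval.length for i in idx),
            }
        # per-chromosome gene-body geometry, sorted by start
        self.gene_geom: dict[str, dict[str, np.ndarray]] = {}
        gby: dict[str, list[int]] = {}
        for i, g in enumerate(genes):
            gby.setdefault(g.chrom, []).append(i)
        for chrom, idx in gby.items():
            idx = np.array(idx)
            starts = np.array([genes[i].body.start for i in idx])
            order = np.argsort(starts, kind="stable")
            idx = idx[order]
            self.gene_geom[chrom] = {
                "row": idx,
                "start": starts[order],
                "end": np.array([genes[i].body.end for i in idx]),
                "max_len": max(genes[i].body.length for i in idx),
            }
        # WEEC neighborhood cache: per (gene row, max_dist) the neighbor rows
        # and the summed standardized activity over the neighborhood
        self._weec_cache: dict[tuple[int, int], tuple[int, np.ndarray]] = {}

    def overlapping(self, geom: dict[str, np.ndarray], w0: int, w1: int):
        """Indices (into geom arrays) of elements overlapping [w0, w1) + clip lengths."""
        lo = np.searchsorted(geom["start"], w0 - geom["max_len"], side="left")
        hi = np.searchsorted(geom["start"], w1, side="left")
        sl = slice(lo, hi)
        starts, ends = geom["start"][sl], geom["end"][sl]
        clip = np.minimum(ends, w1) - np.maximum(starts, w0)
        mask = clip > 0
        return geom["row"][sl][mask], clip[mask]

    def weec_neighborhood(self, gene_row: int, tss: int, chrom: str, max_dist: int):
        key = (gene_row, max_dist)
        cached = self._weec_cache.get(key)
        if cached is not None:
            return cached
        geom = self.enh_geom.get(chrom)
        if geom is None:
            result = (0, np.zeros(len(self.cell_types)))
        else:
            mid_order = np.argsort(geom["mid"], kind="stable")
            mids = geom["mid"][mid_order]
            rows = geom["row"][mid_order]
            lo = np.searchsorted(mids, tss - max_dist, side="left")
            hi = np.searchsorted(mids, tss + max_dist, side="right")
            rows = rows[lo:hi]
            result = (len(rows), self.act_z[rows].sum(axis=0))
        self._weec_cache[key] = result
        return result


def compute_feature_table(
    pairs: pd.DataFrame,
    enhancers: list[Enhancer],
    genes: list[Gene],
    cell_types: list[str],
    max_dist: int = MAX_DIST_DEFAULT,
    log_expression: bool = False,
) -> pd.DataFrame:
    """Compute all six features for every candidate pair.

    Returns a copy of ``pairs`` with the feature columns (EGC, GS, DIS, EWS,
    GWS, WEEC) plus the coordinate columns needed by the prediction writer.
    Deterministic given its inputs. ``log_expression`` applies log1p to the
    expression matrix before the EGC correlation (off by default).
    """
    idx = _FeatureIndex(enhancers, genes, cell_types, log_expression)
    n = len(pairs)
    n_cells = len(idx.cell_types)

    egc = np.empty(n)
    gs = np.empty(n)
    dis = np.empty(n, dtype=int)
    ews = np.empty(n)
    gws = np.empty(n)
    weec = np.empty(n)
    enh_start = np.empty(n, dtype=int)
    enh_end = np.empty(n, dtype=int)
    tss_col = np.empty(n, dtype=int)
    chrom_col: list[str] = []

    for i, (eid, gid, cell) in enumerate(
        zip(pairs["enhancer_id"], pairs["gene_id"], pairs["cell_type"])
    ):
        enh = idx.enh.get(eid)
        if enh is None:
            raise KeyError(f"unresolvable enhancer id {eid!r}")
        gene = idx.gene.get(gid)
        if gene is None:
            raise KeyError(f"unresolvable gene id {gid!r}")
        if cell not in idx.cell_col:
            raise KeyError(f"unknown cell type {cell!r}")
        er, gr, cc = idx.enh_row[eid], idx.gene_row[gid], idx.cell_col[cell]

        egc[i] = float(idx.act_z[er] @ idx.expr_z[gr])
        gs[i] = idx.expression[gr, cc]
        dis[i] = abs(enh.interval.midpoint - gene.tss)
        chrom_col.append(gene.chrom)
        enh_start[i], enh_end[i] = enh.interval.start, enh.interval.end
        tss_col[i] = gene.tss

        w0, w1 = _window_span(enh, gene.promoter)
        if w1 <= w0:
            ews[i] = 0.0
            gws[i] = 0.0
        else:
            l_window = w1 - w0
            rows, clips = idx.overlapping(idx.enh_geom[gene.chrom], w0, w1)
            mask = rows != er
            ews[i] = float(idx.activity[rows[mask], cc] @ clips[mask]) / l_window
            ggeom = idx.gene_geom.get(gene.chrom)
            if ggeom is None:
                gws[i] = 0.0
            else:
                grows, gclips = idx.overlapping(ggeom, w0, w1)
                gmask = grows != gr
                gws[i] = float(idx.expression[grows[gmask], cc] @ gclips[gmask]) / l_window

        m, z_sum = idx.weec_neighborhood(gr, gene.tss, gene.chrom, max_dist)
        if m <= 1:
            weec[i] = 0.0
        else:
            self_r = float(idx.act_z[er] @ idx.act_z[er])  # 1, or 0 for a flat vector
            weec[i] = (float(idx.act_z[er] @ z_sum) - self_r) / (m - 1)

    out = pairs.copy()
    out["chrom"] = chrom_col
    out["enh_start"] = enh_start
    out["enh_end"] = enh_end
    out["tss"] = tss_col
    out["EGC"] = egc
    out["GS"] = gs
    out["DIS"] = dis
    out["EWS"] = ews
    out["GWS"] = gws
    out["WEEC"] = weec
    bad = out[list(FEATURE_ORDER)].to_numpy()
    if not np.all(np.isfinite(bad)):
        raise ValueError("non-finite feature value computed")
    return out
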