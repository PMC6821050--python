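"""Seeded synthetic multi-cell-type datasets with planted regulatory structure.

The generator emulates, on one chromosome, the contrasts that make candidate
enhancer-gene pairs separable: interacting pairs share a latent per-cell-type
factor (so enhancer activity and gene expression correlate at a target
Pearson rho), sit at short genomic distances drawn from a heavy-tailed decay,
involve more highly expressed genes, and come in small co-regulating enhancer
clusters whose members correlate with each other. Interacting genes are
preferentially chosen as close pairs of adjacent genes, so the window between
a planted pair tends to contain other active enhancers and genes — the
mechanism behind the window-signal contrasts. Non-interacting candidates
arise from geometry alone. Ground-truth loops are emitted as BEDPE anchors
(+/- 2.5 kb around enhancer midpoint and TSS), and truth labels are the
anchor-overlap labels those loops induce.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import io as io_mod
from .core import Enhancer, Gene, GenomicInterval, InteractionRecord
from .pairs import build_candidate_pairs, ensure_promoters, label_pairs


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study. Defaults are the standard conditions."""

    n_cell_types: int = 20
    n_genes: int = 200
    n_enhancers: int = 800
    chrom_length: int = 50_000_000
    chrom: str = "chr1"
    frac_interacting: float = 0.1
    planted_correlation: float = 0.8
    #: scale (bp) of the distance decay for planted pairs (the median of a
    #: heavy-tailed lognormal, so classes overlap in distance as real loop
    #: catalogs do); None draws positive-pair distances uniformly over the
    #: candidate window
    distance_decay_scale: float | None = 50_000.0
    #: log-sd of the planted-distance lognormal (tail heaviness)
    distance_tail_sigma: float = 1.1
    background_correlation: float = 0.0
    activity_noise_sd: float = 1.0
    expression_noise_sd: float = 0.1
    cluster_size: int = 3
    anchor_halfwidth: int = 2_500
    enhancer_length: int = 1_000
    max_dist: int = 1_000_000
    # signal levels (arbitrary activity units / FPKM)
    background_activity_mean: float = 2.0
    active_activity_mean: float = 8.0
    activity_gain: float = 1.5
    background_expression_median: float = 0.5
    active_expression_median: float = 5.0
    expression_sigma_background: float = 1.2
    expression_sigma_active: float = 0.8
    expression_cell_sd: float = 0.25
    #: probability that an active gene's expression boost, and independently
    #: its cluster's activity boost, is shrunk toward background (weakly
    #: active loci; they keep their loops)
    weak_locus_fraction: float = 0.3
    #: shrinkage factor applied to the boost of a weak locus
    weak_boost: float = 0.25
    #: weight of the shared per-cluster factor in the activity residual:
    #: cluster mates co-vary beyond what the gene factor induces
    cluster_coherence: float = 0.8
    #: probability that an active gene's clusters have their measured
    #: activity decoupled from the gene's latent factor (activity-proxy
    #: failure: the loops are real but the synthesized signal does not track
    #: the gene; the cluster still co-varies internally)
    decoupled_fraction: float = 0.08
    #: copula weight tying the per-locus signal channels (expression level,
    #: activity level, proxy coupling, distance) to one shared locus-quality
    #: latent: a hard locus tends to be dark in several channels at once
    channel_correlation: float = 0.5
    #: bystander genes within this distance of an active locus sit in its
    #: "compartment" and get a mild expression boost (gene-dense active
    #: neighborhoods), feeding the gene-window signal of planted pairs
    compartment_halfwidth: int = 150_000
    compartment_expression_median: float = 2.0
    #: correlation between the latent factors of the two genes of an active
    #: locus (co-regulated domains); creates correlated-but-not-looped
    #: cross pairs and couples the neighboring clusters
    locus_coregulation: float = 0.5
    #: admissible TSS gap (bp) between the two genes of an active locus
    locus_gap_range: tuple[int, int] = (10_000, 40_000)
    #: probability that a cluster enhancer lands on its gene's partner side,
    #: putting the partner gene and its cluster inside the pair's window
    partner_side_bias: float = 0.85
    gene_length_range: tuple[int, int] = (20_000, 200_000)
    support_tracks: int = 10
    support_rate: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_interacting <= 1.0:
            raise ValueError("frac_interacting must be in [0, 1]")
        if not -1.0 <= self.planted_correlation <= 1.0:
            raise ValueError("planted_correlation must be in [-1, 1]")
        if min(self.n_cell_types, self.n_genes, self.n_enhancers) < 1:
            raise ValueError("counts must be >= 1")

    def cell_types(self) -> list[str]:
        return [f"CT{i + 1:02d}" for i in range(self.n_cell_types)]


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with loops but no planted signal.

    Interacting pairs keep their labels but share no latent factor
    (correlation 0), have no activity or expression boost, and sit at
    distances drawn uniformly over the candidate window — so every feature is
    uninformative and a classifier should score at chance.
    """
    params = dict(
        planted_correlation=0.0,
        distance_decay_scale=None,
        active_activity_mean=2.0,
        active_expression_median=0.5,
        expression_sigma_active=1.2,
        compartment_expression_median=0.5,
        cluster_coherence=0.0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class SyntheticDataset:
    enhancers: list[Enhancer]
    genes: list[Gene]
    interactions: list[InteractionRecord]
    enhancer_support: dict[str, float]
    cell_types: list[str]
    config: SimulationConfig
    #: candidate pairs for the focal cell type with anchor-overlap truth labels
    truth: pd.DataFrame
    #: ids of the planted (enhancer, gene) interactions
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    #: parallel to planted_pairs: False where the enhancer's activity proxy
    #: was decoupled from the gene's latent factor
    planted_coupled: list[bool] = field(default_factory=list)

    @property
    def focal_cell_type(self) -> str:
        return self.cell_types[0]

    def expression_table(self) -> dict[str, dict[str, float]]:
        return {g.id: dict(g.expression) for g in self.genes}


def _clip0(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator):
    margin = cfg.gene_length_range[1] + 10_000
    tss = np.sort(
        rng.integers(margin, cfg.chrom_length - margin, size=cfg.n_genes)
    )
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=cfg.n_genes)
    return tss, strands, lengths


def _select_active_loci(
    cfg: SimulationConfig, rng: np.random.Generator, tss: np.ndarray, n_active: int
) -> tuple[list[int], np.ndarray]:
    """Pick interacting genes, preferring close pairs of adjacent genes.

    Active regulatory loci are gene-dense: choosing neighbors within the
    configured gap range puts other active genes inside positive-pair
    windows. The minimum gap keeps one gene's promoter clear of its
    neighbor's loop anchors. Returns the chosen gene indices and a partner
    array (-1 for unpaired genes).
    """
    lo_gap, hi_gap = cfg.locus_gap_range
    gaps = np.diff(tss)
    eligible = [i for i in range(len(gaps)) if lo_gap <= gaps[i] <= hi_gap]
    rng.shuffle(eligible)
    chosen: list[int] = []
    partner = np.full(len(tss), -1, dtype=int)
    used = np.zeros(len(tss), dtype=bool)
    for i in eligible:
        if len(chosen) >= n_active - 1:
            break
        if used[i] or used[i + 1]:
            continue
        chosen.extend([i, i + 1])
        partner[i], partner[i + 1] = i + 1, i
        used[i] = used[i + 1] = True
    # top up with isolated singles if close pairs ran out
    while len(chosen) < n_active:
        i = int(rng.integers(0, len(tss)))
        if used[i]:
            continue
        if any(abs(tss[i] - tss[j]) < lo_gap for j in chosen):
            continue
        chosen.append(i)
        used[i] = True
    return chosen[:n_active], partner


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset. Byte-identical output for identical configs."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cells = cfg.cell_types()
    n_c = cfg.n_cell_types

    mean_gene_len = sum(cfg.gene_length_range) / 2
    footprint = cfg.n_enhancers * cfg.enhancer_length + cfg.n_genes * mean_gene_len
    if footprint > 0.8 * cfg.chrom_length:
        raise ValueError(
            f"elements do not fit: footprint {footprint} bp on a "
            f"{cfg.chrom_length} bp chromosome"
        )

    tss, strands, gene_lengths = _place_genes(cfg, rng)

    n_interacting = int(round(cfg.frac_interacting * cfg.n_enhancers))
    n_active_genes = -(-n_interacting // cfg.cluster_size) if n_interacting else 0
    if n_active_genes:
        active_idx, partner = _select_active_loci(cfg, rng, tss, n_active_genes)
    else:
        active_idx, partner = [], np.full(cfg.n_genes, -1, dtype=int)
    is_active_gene = np.zeros(cfg.n_genes, dtype=bool)
    is_active_gene[active_idx] = True

    # latent per-cell factor for every gene; active enhancers couple to it
    z = rng.standard_normal((cfg.n_genes, n_c))
    # co-regulated locus domains: partners share correlated latents
    cr = cfg.locus_coregulation
    if cr > 0:
        for a in active_idx:
            b = partner[a]
            if b >= 0 and a < b:
                z[b] = cr * z[a] + np.sqrt(1.0 - cr * cr) * z[b]

    # Per-locus signal-channel visibility. One locus-quality latent feeds a
    # Gaussian copula over the channels (expression level, activity level,
    # proxy coupling, distance): a hard locus tends to go dark in several
    # channels at once, so some true pairs are recoverable only through the
    # channels that remain.
    n_act = len(active_idx)
    w_ch = cfg.channel_correlation
    t_locus = rng.standard_normal(n_act)  # high = poor-quality locus

    def _dark_flags(p: float) -> np.ndarray:
        if p <= 0:
            return np.zeros(n_act, dtype=bool)
        s = np.sqrt(w_ch) * t_locus + np.sqrt(1.0 - w_ch) * rng.standard_normal(n_act)
        return s > norm.ppf(1.0 - p)

    weak_expr_flag = _dark_flags(cfg.weak_locus_fraction)
    weak_act_flag = _dark_flags(cfg.weak_locus_fraction)
    decoupled_flag = _dark_flags(cfg.decoupled_fraction)
    s_dist = np.sqrt(w_ch) * t_locus + np.sqrt(1.0 - w_ch) * rng.standard_normal(n_act)

    expr_boost = np.ones(cfg.n_genes)
    act_boost = np.ones(cfg.n_genes)
    decoupled = np.zeros(cfg.n_genes, dtype=bool)
    dist_scale = np.zeros(cfg.n_genes)
    for k, g in enumerate(active_idx):
        if weak_expr_flag[k]:
            expr_boost[g] = cfg.weak_boost
        if weak_act_flag[k]:
            act_boost[g] = cfg.weak_boost
        decoupled[g] = decoupled_flag[k]
        if cfg.distance_decay_scale is not None:
            dist_scale[g] = cfg.distance_decay_scale * np.exp(
                cfg.distance_tail_sigma * s_dist[k]
            )

    # bystander genes inside an active compartment get a mild boost
    in_compartment = np.zeros(cfg.n_genes, dtype=bool)
    for a in active_idx:
        near = np.abs(tss - tss[a]) <= cfg.compartment_halfwidth
        in_compartment |= near
    in_compartment &= ~is_active_gene

    # expression: FPKM[g, k] = base_g * max(0, 1 + cell_sd * (z + noise))
    log_bg = np.log(cfg.background_expression_median)
    log_act = np.log(cfg.active_expression_median)
    log_median = np.where(
        is_active_gene,
        log_bg + expr_boost * (log_act - log_bg),
        np.where(in_compartment, np.log(cfg.compartment_expression_median), log_bg),
    )
    sigma = np.where(
        is_active_gene, cfg.expression_sigma_active, cfg.expression_sigma_background
    )
    log_base = log_median + sigma * rng.standard_normal(cfg.n_genes)
    base = np.exp(log_base)
    expr_noise = cfg.expression_noise_sd * rng.standard_normal((cfg.n_genes, n_c))
    expression = base[:, None] * _clip0(1.0 + cfg.expression_cell_sd * (z + expr_noise))

    # enhancer placement + activity
    rho = cfg.planted_correlation
    mids = np.empty(cfg.n_enhancers, dtype=int)
    activity = np.empty((cfg.n_enhancers, n_c))
    target_gene = np.full(cfg.n_enhancers, -1, dtype=int)

    lo_pos = cfg.enhancer_length
    hi_pos = cfg.chrom_length - cfg.enhancer_length
    u = cfg.cluster_coherence
    resid_scale = np.sqrt(max(0.0, 1.0 - rho * rho))
    e = 0
    for g in active_idx:
        cluster_factor = rng.standard_normal(n_c)  # shared by this gene's cluster
        for _ in range(cfg.cluster_size):
            if e >= n_interacting:
                break
            if cfg.distance_decay_scale is None:
                d = rng.uniform(1_000, cfg.max_dist)
            else:
                # the cluster shares its locus's distance scale
                d = dist_scale[g] * np.exp(0.25 * rng.standard_normal())
                d = min(max(d, 1_000), cfg.max_dist - cfg.enhancer_length)
            p = partner[g]
            if p >= 0 and rng.random() < cfg.partner_side_bias:
                side = 1 if tss[p] > tss[g] else -1
            else:
                side = rng.choice([-1, 1])
            mids[e] = int(np.clip(tss[g] + side * d, lo_pos, hi_pos))
            eps = rng.standard_normal(n_c)
            # residual shared with cluster mates: co-activity beyond the
            # gene factor, preserving the own-gene correlation at rho
            resid = u * cluster_factor + np.sqrt(max(0.0, 1.0 - u * u)) * eps
            if decoupled[g]:
                # activity proxy fails to track the gene factor but still
                # co-varies with the cluster
                mix = resid
            else:
                mix = rho * z[g] + resid_scale * resid
            mean_e = cfg.background_activity_mean + act_boost[g] * (
                cfg.active_activity_mean - cfg.background_activity_mean
            )
            activity[e] = _clip0(mean_e + cfg.activity_gain * mix)
            target_gene[e] = g
            e += 1
    n_background = cfg.n_enhancers - e
    mids[e:] = rng.integers(lo_pos, hi_pos, size=n_background)
    bc = cfg.background_correlation
    shared = rng.standard_normal(n_c)  # chromosome-wide batch factor
    noise = rng.standard_normal((n_background, n_c))
    mix_bg = np.sqrt(bc) * shared[None, :] + np.sqrt(1.0 - bc) * noise
    activity[e:] = _clip0(
        cfg.background_activity_mean + cfg.activity_noise_sd * mix_bg
    )

    support_raw = rng.binomial(cfg.support_tracks, cfg.support_rate, size=cfg.n_enhancers)

    # assemble domain objects; ids follow genomic order
    order = np.argsort(mids, kind="stable")
    half = cfg.enhancer_length // 2
    enhancers: list[Enhancer] = []
    support: dict[str, float] = {}
    planted: list[tuple[str, str]] = []
    planted_coupled: list[bool] = []
    id_of = {}
    for rank, j in enumerate(order):
        eid = f"E{rank + 1:05d}"
        id_of[j] = eid
        start = int(mids[j]) - half
        enhancers.append(
            Enhancer(
                eid,
                GenomicInterval(cfg.chrom, start, start + cfg.enhancer_length),
                dict(zip(cells, activity[j].tolist())),
            )
        )
        support[eid] = support_raw[j] / cfg.support_tracks

    genes: list[Gene] = []
    for i in range(cfg.n_genes):
        gid = f"G{i + 1:04d}"
        if strands[i] == "+":
            body = GenomicInterval(cfg.chrom, int(tss[i]), int(tss[i] + gene_lengths[i]))
        else:
            body = GenomicInterval(cfg.chrom, int(tss[i] - gene_lengths[i]), int(tss[i]))
        genes.append(
            Gene(
                gid,
                cfg.chrom,
                int(tss[i]),
                str(strands[i]),
                body,
                expression=dict(zip(cells, expression[i].tolist())),
            )
        )
    ensure_promoters(genes)

    focal = cells[0]
    interactions: list[InteractionRecord] = []
    hw = cfg.anchor_halfwidth
    for j in range(cfg.n_enhancers):
        g = target_gene[j]
        if g < 0:
            continue
        a1 = GenomicInterval(
            cfg.chrom, max(0, int(mids[j]) - hw), int(mids[j]) + hw
        )
        a2 = GenomicInterval(cfg.chrom, max(0, int(tss[g]) - hw), int(tss[g]) + hw)
        interactions.append(InteractionRecord(a1, a2, focal, source="synthetic"))
        planted.append((id_of[j], f"G{g + 1:04d}"))
        planted_coupled.append(not decoupled[g])

    pairs = build_candidate_pairs(enhancers, genes, focal, max_dist=cfg.max_dist)
    truth = label_pairs(pairs, enhancers, genes, interactions)

    return SyntheticDataset(
        enhancers=enhancers,
        genes=genes,
        interactions=interactions,
        enhancer_support=support,
        cell_types=cells,
        config=cfg,
        truth=truth,
        planted_pairs=planted,
        planted_coupled=planted_coupled,
    )


def export(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact formats the readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "enhancers": directory / "enhancers.bed",
        "expression": directory / "expression.tsv",
        "genes": directory / "genes.bed",
        "interactions": directory / "interactions.bedpe",
        "truth": directory / "truth_labels.tsv",
        "support": directory / "enhancer_support.tsv",
        "config": directory / "config.yaml",
    }
    io_mod.write_enhancer_bed(dataset.enhancers, paths["enhancers"], dataset.cell_types)
    io_mod.write_expression_table(
        dataset.expression_table(), paths["expression"], dataset.cell_types
    )
    io_mod.write_gene_annotation(dataset.genes, paths["genes"])
    io_mod.write_bedpe(dataset.interactions, paths["interactions"])
    dataset.truth.loc[:, ["enhancer_id", "gene_id", "cell_type", "DIS", "label"]].to_csv(
        paths["truth"], sep="\t", index=False
    )
    with open(paths["support"], "w") as fh:
        fh.write("enhancer_id\tsupport\n")
        for eid in sorted(dataset.enhancer_support):
            fh.write(f"{eid}\t{dataset.enhancer_support[eid]!r}\n")
    import yaml

    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(dataset.config).items()
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return paths
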