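# Methods

## Problem and pipeline

Enhancers regulate genes over large genomic distances, often skipping the
nearest gene. Given (i) an enhancer annotation with a per-cell-type activity
score (a synthesized signal intensity standing in for enhancer activity) and
(ii) a gene-expression matrix (FPKM) over the same cell-type panel, the
package enumerates every candidate enhancer–gene pair within 1 Mbp, labels
candidates against chromatin loops (ChIA-PET/Hi-C-style BEDPE anchors) in
the training cell type, computes six features per pair, trains a boosted
tree ensemble, and emits per-pair interaction confidences in [0, 1] for any
cell type with activity and expression data.

All coordinates are 0-based, half-open. The promoter is the strand-aware
interval from 5 kbp upstream to 0.5 kbp downstream of the TSS, clipped at
position 0. Pair distance (the DIS feature) is |enhancer midpoint − TSS|,
midpoint = start + ⌊length/2⌋; the midpoint convention makes DIS insensitive
to enhancer length.

## The six features

For enhancer *e*, gene *g*, focal cell type *c*, over a panel of *n* cell
types:

* **EGC** = Pearson r(activity(e), expression(g)) across the full panel —
  not only the focal cell. Tissue specificity enters through the other
  features; the correlation uses every cell type's information.
* **GS** = FPKM of *g* in *c*, unchanged.
* **DIS** = |midpoint(e) − TSS(g)| in bp.
* **EWS** = Σᵢ eᵢ·L(eᵢ) / L(window): activity-weighted length of the *other*
  enhancers lying in the window between the pair's elements, per window bp.
* **GWS** = Σᵢ gᵢ·L(gᵢ) / L(window): the same for intervening gene bodies,
  weighted by focal-cell FPKM.
* **WEEC** = mean Pearson r between *e* and each other enhancer whose
  midpoint lies within 1 Mbp of *g*'s TSS (gene-anchored neighborhood,
  matching the candidate-window rule); defined as 0 when no neighbor exists.

Window conventions (the definitions leave these open; chosen once and
fixed): the window runs from the enhancer edge nearest the promoter to the
promoter edge nearest the enhancer; elements partially overlapping the
window count with their clipped length; the focal pair's own enhancer and
gene are excluded, so a pair cannot inflate its own window signal; abutting
or overlapping elements get a 1 bp window-length floor to avoid division by
zero. A zero-variance vector has Pearson r defined as 0 rather than NaN —
an inactive enhancer contributes no correlation signal and NaN would poison
the feature table. Correlations require a panel of at least 3 cell types.
Expression may optionally be log1p-transformed before the EGC correlation
(`log_expression`, off by default — the raw-scale correlation is the
documented definition and the transform is exposed only as a sensitivity
knob).

## Labels and training sample

A candidate pair is positive iff some intra-chromosomal loop of the same
cell type overlaps the enhancer with one anchor and the promoter with the
other (≥ 1 bp on each side, both anchor assignments tried); every other
candidate is negative. The alternative, stricter reading — "neither element
touches any anchor" — is not used; the ≥1 bp threshold is a config knob
(`min_overlap`). Loops from other cell types never affect a pair. Training
pairs additionally require the enhancer to be supported by ≥ 50% of the
evidence tracks and the target gene to be expressed (FPKM > 0) in the focal
cell type; "expressed" is implemented exactly as FPKM > 0, not a separate
threshold. The balanced training draw takes ⌊P/2⌋ random positives and an
equal number of random negatives; the rest is holdout. An unbalanced
evaluation variant (all positives : 5× negatives) is produced by a separate
seeded subsampling utility and never alters training.

## Model

AdaBoost (SAMME) over depth-limited decision trees: 50 boosting rounds,
learning rate 1.0, depth-2 trees by default. Scores are the ensemble's
class-probability output — a monotone logistic-style transform of the
stage-weighted margin — with no additional calibration fitting. Depth,
round count and learning rate are configuration. Depth 2 rather than 3 is
deliberate: at the desk-scale study conditions (~90 positives, balanced
training ~90+90), depth-3 trees reach zero training error and boosting
terminates after a handful of rounds, collapsing the ensemble to something
close to a single tree; depth-2 learners keep all 50 rounds active. With
thousands of training pairs, deeper trees are a reasonable setting and a
single config change.

## Evaluation protocols

AUROC is the rank statistic (Mann–Whitney U normalized by n₊·n₋, midrank
tie handling); AUPR is the step-wise area under the precision–recall curve
with no linear interpolation, so a random scorer converges to class
prevalence. Both are checked in the test suite against brute-force
pair-concordance and step-sum oracles.

*Self-test*: a seeded half-split, stratified by label and **grouped by
gene** — every pair of one gene lands on the same side, genes assigned
greedily in seeded random order to balance the halves' positive counts.
Grouping matters at a few hundred pairs: in a plain row split the same
gene's exact FPKM value appears on both sides and a tree can memorize gene
identity instead of signal; with grouping, a generator configured with *no*
planted signal scores at chance (verified over 20 replicate draws), while a
plain split scores visibly above it. A residual few hundredths above 0.5
remain from neighboring pairs sharing window content — spatial structure no
pair-level split can remove.

*Cross-sample test*: train on one dataset's balanced draw, score every
labeled pair of another dataset. *Feature ablation*: nested cumulative
subsets in the order EGC, GS, EWS, GWS, WEEC, DIS, all on one shared split.

## Permutation feature importance

Importance is measured out-of-sample: the model is trained on one draw's
balanced table and features are permuted on held-out data (by default an
independent draw at the same conditions). Two scales are reported, because
they answer different questions:

* `importance` — mean decrease in whole-ensemble holdout AUROC over k
  permutations of one column (k = 10 default), clipped at 0. This measures
  *irreplaceable* contribution: with six partially redundant features the
  rest of the ensemble compensates, and a genuinely used feature can score
  near zero. It is the right scale for detecting an inert feature (a
  pure-noise column scores ≈ 0 here).
* `relative` — a per-weak-learner statistic: each tree's holdout-accuracy
  decrease under permutation, averaged over permutations, then mean/std
  across the ensemble's trees, clipped at 0 and normalized to sum to 1.
  Features that many trees rely on consistently score high even when the
  ensemble as a whole could compensate, which makes the relative
  contributions of redundant features comparable. Because a single
  (train-draw, holdout-draw) estimate wobbles by a few hundredths, the
  acceptance check averages it over 5 replicate draw pairs.

## The synthetic generator

The generator emulates, on one chromosome, the joint structure that makes
candidate pairs separable, with every contrast planted explicitly so each
feature is informative but none is sufficient:

* **Geometry.** Gene TSSs uniform on a 50 Mbp chromosome; bodies 20–200 kb
  (≈ 40% genomic coverage, so windows usually overlap gene bodies);
  enhancers 1 kb. Interacting genes (10% of enhancers / cluster size 3 →
  ~27 genes) are preferentially chosen as *close pairs* of adjacent genes
  (TSS gap 10–40 kb): active regulatory loci are gene-dense, and the
  partner gene plus its cluster inside a positive pair's window is what
  gives EWS/GWS their contrast. Gene *positions* stay uniform; only the
  choice of which genes are active is spatially biased.
* **Latent factors.** Every gene has an i.i.d. per-cell-type standard
  normal factor z_g; the two genes of an active locus share correlated
  factors (locus co-regulation 0.5), which creates correlated-but-not-looped
  cross pairs — hard negatives at short range. Expression is
  FPKM(g,k) = base_g · max(0, 1 + 0.25·(z_g(k) + 0.1·noise)) with log-normal
  per-gene baselines (median 5 for active, 0.5 for background, 2 for
  bystanders within 150 kb of an active locus — "compartment" genes; σ =
  0.8/1.2). Activity of a planted enhancer is
  max(0, mean + 1.5·(ρ·z_g + √(1−ρ²)·resid)) with ρ = 0.8, mean 8 (active)
  vs 2 (background); the residual is shared within a cluster (coherence
  0.8), so cluster mates co-vary beyond what the gene factor induces —
  this is what WEEC reads.
* **Distances.** Planted distances are log-normal with median 50 kb and
  log-sd 1.1 — a heavy tail, so positive and negative distance
  distributions overlap as real loop catalogs do and distance alone cannot
  separate the classes. The cluster shares its locus's distance scale.
* **Locus-quality channels.** Each active locus draws dark/bright flags for
  its expression level, activity level and proxy coupling (probabilities
  0.3, 0.3, 0.08) plus its distance scale, tied by a Gaussian copula
  (weight 0.5) to one locus-quality latent: a poor locus tends to be dark
  in several channels at once, so some true pairs are recoverable only
  through whichever channels remain — the mechanism that forces the model
  to use all six features. "Decoupled" loci model activity-proxy failure:
  the loops are real, the cluster still co-varies internally (WEEC
  survives), but the gene-factor coupling is gone (EGC dies). The mean
  activity–expression correlation over all planted pairs stays within 0.1
  of ρ.
* **Labels.** Loops are emitted as ±2.5 kb anchors around enhancer midpoint
  and TSS (the resolution of high-quality Hi-C); truth labels are exactly
  the anchor-overlap labels those loops induce, including incidental
  positives from elements that happen to overlap an anchor.
* **Null variant** (`null_config`): correlation 0, all means equal to
  background, cluster coherence 0, compartments off, positive distances
  uniform over the window — loops and labels exist but carry no feature
  signal, so a correct pipeline scores at chance.

What the generator does **not** emulate: multiple chromosomes (all features
are intra-chromosomal), inter-chromosomal or artifact loops, PET-count or
read-depth noise, mappability structure, dependence between cell types
(cells are exchangeable draws), or realistic enhancer-length and
gene-density distributions beyond the ranges above. Passing tests therefore
show that the pipeline recovers *this* kind of planted structure from
matrices with the right marginal statistics — not that it matches any
particular experimental dataset.

## Problem sizes and determinism

Tests and the acceptance script run at the default conditions (20 cell
types, 800 enhancers, 200 genes, ~6,400 candidate pairs, ~90 positives per
draw). The feature-direction check samples 500 pairs per class from a
proportionally scaled draw (7× elements and chromosome length, identical
densities). The null check averages 20 replicate draws; the importance
profile averages 5 replicate draw pairs. Everything is driven by explicit
seeds: identical configuration and seed give byte-identical exported files,
identical stage weights, and byte-identical prediction TSVs (floats are
written with round-tripping repr).

## Known limitations

* Feature values depend on annotation completeness: EWS/GWS read the
  *provided* enhancer and gene sets, and WEEC needs several neighbors per
  gene to be meaningful.
* EGC and WEEC are panel-wide: a pair whose locus is active only outside
  the focal cell type can correlate strongly yet not interact there; the
  focal-cell features (GS, EWS, GWS) are what the model has to resolve
  this, and the generator plants such decoys deliberately.
* The AUPR of a full candidate table is bounded by its prevalence (~1.4%
  positives at defaults); compare AUPR only at matched prevalence.
* At desk scale the balanced training set is small (~180 rows); model
  variance across draws is a few hundredths of AUROC, and importance
  estimates need replicate averaging (as done in the acceptance script).
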