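"""Compute the six pair features on a small hand-built locus.

Two enhancers and two genes on one chromosome, three cell types. Shows each
feature operation individually and what its value says about the candidate
pair (E1, G1).
"""

from eglink import (
    Enhancer,
    Gene,
    GenomicInterval,
    build_window,
    compute_dis,
    compute_egc,
    compute_ews,
    compute_gs,
    compute_gws,
    compute_weec,
    derive_promoter,
)

cells = ["liver", "lung", "heart"]

# E1's activity tracks G1's expression across the panel; E2 is flat.
e1 = Enhancer("E1", GenomicInterval("chr1", 20_000, 21_000),
              {"liver": 2.0, "lung": 4.0, "heart": 6.0})
e2 = Enhancer("E2", GenomicInterval("chr1", 60_000, 61_000),
              {"liver": 1.0, "lung": 1.0, "heart": 1.0})
g1 = Gene("G1", "chr1", 100_000, "+", GenomicInterval("chr1", 100_000, 130_000),
          expression={"liver": 1.0, "lung": 2.0, "heart": 3.0})
g2 = Gene("G2", "chr1", 70_000, "+", GenomicInterval("chr1", 70_000, 90_000),
          expression={"liver": 5.0, "lung": 5.5, "heart": 6.0})

enhancers, genes = [e1, e2], [g1, g2]
g1.promoter = derive_promoter(g1)
g2.promoter = derive_promoter(g2)

print(f"promoter of G1 (+ strand, TSS {g1.tss:,}): "
      f"[{g1.promoter.start:,}, {g1.promoter.end:,})  (5 kb upstream, 0.5 kb downstream)")

egc = compute_egc(e1, g1, cells)
print(f"EGC  = {egc:+.3f}   activity-expression Pearson r across the panel "
      "(+1 here: E1 tracks G1 perfectly)")

gs = compute_gs(g1, "liver")
print(f"GS   = {gs:.3f}   G1's FPKM in the focal cell type (liver)")

dis = compute_dis(e1, g1)
print(f"DIS  = {dis:,} bp   |enhancer midpoint - TSS|")

ctx = build_window(e1, g1, enhancers, genes, "liver")
print(f"window between E1 and G1's promoter: [{ctx.window.start:,}, {ctx.window.end:,}), "
      f"{ctx.l_window:,} bp")
print(f"EWS  = {compute_ews(ctx):.5f}   other enhancers' signal x length / window length "
      "(E2 lies inside)")
print(f"GWS  = {compute_gws(ctx):.5f}   intervening gene expression x body length / window "
      "(G2's body is clipped to the window)")

weec = compute_weec(g1, enhancers, cells, e1)
print(f"WEEC = {weec:+.3f}   mean correlation of E1 with G1's other nearby enhancers "
      "(E2 is flat, so r = 0 by convention)")
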