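# seqconverge

Tools for asking a specific question of bulk RNA-seq from two cell
types under crossed stimulations: **how far do the cell types converge
toward a shared gene-expression program, and which regulators plausibly
drive the convergent genes?** The motivating setting is adipocytes and
macrophages treated with nothing (NS), interferon-β (IFNB),
lipopolysaccharide (LPS), or both — a design in which adipocytes can
reveal a "dormant" macrophage-like inflammatory program under the
combined stimulus.

The package provides, as a plain Python library plus a thin CLI:

1. **Expression processing** — RPKM, a floor at 1, per-sample
   median-of-ratios normalization factors, normalization, log2
   baselining to the per-gene median, and an expression filter
   (raw RPKM > 3 in all samples of at least one condition).
2. **Differential expression** — per-gene two-way fixed-effects ANOVA
   (treatment × cell type, with interaction), Benjamini–Hochberg FDR,
   and a linear fold-change gate (q < 0.05 and FC > 1.5 vs NS).
3. **Convergence statistics** — shared-DE percentages per condition,
   overlap of top-expressed gene lists, PCA of samples, and distances
   between cell-type centroids.
4. **Promoter/peak enrichment** — strand-aware promoter windows
   around each TSS ((−1000,+500), (−1000,+1000), (−2000,+1));
   the *observed overlap* of an input promoter set with a peak dataset
   is the number of input regions sharing ≥ 1 base with any peak, and
   its significance comes from an empirical null of 2000 redraws of
   equally many random promoters, summarized as
   Z = (obs − mean)/sd and a one-sided normal P.
5. **A synthetic-study generator** — negative-binomial counts
   (mean μ_gs = 2^(base + effects) · len_g/10³ · scale_s, variance
   μ(1 + αμ)), TSS annotations, and peak libraries with planted
   enrichment, so every stage is testable against known ground truth.

## Worked example

`examples/04_convergence.py` simulates the full study (2000 genes,
2 cell types × 4 treatments × 3 replicates, seed 1), runs the
processing chain and DE calling, and prints:

```
condition  size_a  size_b  intersection  jaccard_pct
 baseline     200     200             0          0.0
     IFNB     179     192           105         39.5
      LPS     187     184           107         40.5
 IFNB_LPS     529     499           396         62.7
centroid distance (PC1/PC2 plane)        NS: 69.2
centroid distance (PC1/PC2 plane)  IFNB_LPS: 64.8
```

Reading: the two cell types' top-expressed programs are disjoint at
baseline (0 of 200 shared); each single agent already produces ~40%
shared DE genes; the combined treatment gives the largest shared
percentage (62.7%, driven by the planted dormant program) and pulls the
cell-type centroids closer together (64.8 < 69.2). `jaccard_pct` is
100·|A∩B|/|A∪B|; a sum-based convention 100·|A∩B|/(|A|+|B|) is also
computed in the full table.

`examples/05_promoter_enrichment.py` shows the enrichment test ranking
a planted TF dataset first with Z ≈ 15 while unenriched datasets sit
near Z = 0. The other examples cover simulation, the expression chain,
and DE calling; each is a short narrative script that prints what it
computes.

The same stages are available as CLI subcommands
(`seqconverge simulate | quantify | diffexp | converge | enrich`),
each writing tab-separated tables plus a log of config, seed and
version.

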