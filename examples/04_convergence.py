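"""Quantify how the two cell types converge under treatment.

Shared-DE percentages per condition, overlap of top-expressed lists at
baseline, and the distance between cell-type centroids in PCA space.
"""

import seqconverge as sc

cfg = sc.SimulationConfig(rng_seed=1)
counts, _ = sc.simulate_expression(cfg)
res = sc.quantify_pipeline(counts)
de = sc.run_differential_expression(
    res["baselined"].values, res["normalized"].values, counts.metadata,
    genes=res["kept_genes"])

tops = tuple(
    set(sc.top_expressed(res["normalized"].values, counts.metadata, ct,
                         n=200))
    for ct in cfg.cell_types
)
table = sc.condition_overlap_table(de.gene_sets(), baseline_sets=tops)
print(table[["condition", "size_a", "size_b", "intersection",
             "jaccard_pct"]].round(1).to_string(index=False))

coords, explained = sc.pca_samples(res["baselined"].values,
                                   gene_subset=res["kept_genes"])
for cond in ("NS", "IFNB_LPS"):
    d = sc.centroid_distance(coords, counts.metadata, cond)
    print(f"centroid distance (PC1/PC2 plane) {cond:>9}: "
          f"{d['distance_plane']:.1f}")
print("\nThe combined treatment has the highest shared-DE percentage "
      "and the smallest cross-cell-type distance: the planted "
      "convergence, recovered.")
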