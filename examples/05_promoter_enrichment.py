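"""Rank peak datasets by enrichment in a gene set's promoters.

Promoter windows (here -1000/+500 around each TSS, strand-aware) of an
input gene set are overlapped with each peak dataset; significance
comes from 2000 redraws of equally many random promoters.
"""

import seqconverge as sc
from seqconverge.enrichment import PromoterWindowDef

cfg = sc.SimulationConfig(rng_seed=1)
ann = sc.simulate_annotation(cfg)
targets = list(ann.gene_ids[:100])

peaks, truth = sc.simulate_peak_library(
    ann, n_datasets=10,
    enriched={"tf_planted": (targets, 0.8)}, p_bg=0.1, rng_seed=1,
)
result = sc.enrich_library(
    targets, ann, peaks, windows=[PromoterWindowDef(1000, 500)],
    n_iter=2000, seed=1,
)
cols = ["dataset", "observed", "null_mean", "null_sd", "z", "p", "q"]
print(result.table[cols].head(5).round(4).to_string(index=False))
print("\n'tf_planted' hits ~80% of the input promoters against a ~10% "
      "background, so its observed overlap sits far above the null "
      "mean — a large Z and a vanishing P. Unenriched datasets hover "
      "near Z = 0.")
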