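# Methods

## Scope and data model

The pipeline starts from a gene-level count matrix (genes × samples)
with gene lengths and per-sample metadata (cell type, treatment,
replicate); read alignment and read-level quantification are upstream
of it. All genomic coordinates, in memory and on disk, are 0-based
half-open (BED convention); a TSS is the 0-based position of the first
transcribed base. Expression matrices carry an explicit processing
state (`raw → thresholded → normalized → baselined`) and operations
refuse matrices in the wrong state, so the chain cannot be silently
reordered.

## Expression processing

**RPKM.** rpkm_gs = count_gs / ((len_g/10³)(total_s/10⁶)) with total_s
the sample's column sum. A variant with the per-million division
disabled (reads per kilobase) is exposed because RPKM by construction
cancels any per-sample depth difference: the sample total scales with
the depth, so a planted library scale factor is invisible to
median-of-ratios on RPKM, and recovery of planted factors must be
assessed on the depth-unnormalized values.

**Threshold at 1.** Values are floored at 1 RPKM. Flooring (rather than
discarding sub-threshold genes) is the default because it prevents
near-zero values from dominating ratios and keeps the gene universe
stable; a `discard` mode drops genes below the floor in any sample, and
a `skip` mode leaves values untouched (downstream baselining then
rejects zeros). Flooring is idempotent.

**Normalization factors.** Median-of-ratios: each gene's values are
divided by that gene's geometric mean across samples, and a sample's NF
is the within-sample median of these ratios; values are then divided by
their sample's NF. Genes with a zero in any sample are excluded from
the median (the geometric mean through zero is degenerate); after
flooring none remain, so the exclusion matters only when thresholding
is disabled. Medians with an even count are the mean of the two central
order statistics. Exact small-sample algebra worth knowing: scaling one
sample's values by c multiplies its NF by c^((n−1)/n) and every other
NF by c^(−1/n) — pairwise NF *ratios* scale by exactly c, and with
2000 genes the planted-factor recovery error is ~1–2%.

**Baselining.** log2, then per-gene centering at the median across all
samples. Per-gene centering (rather than a single global-median shift)
is chosen because it is what makes sample-space PCA and heat-map-style
comparisons of the resulting values meaningful: each gene's values
become log2 distances from that gene's typical expression.

**Expression filter.** A gene is "reasonably expressed" iff its *raw*
RPKM exceeds 3 in 100% of the samples of at least one (cell type,
treatment) condition; the inequality is strict, and the filter uses
pre-normalization values. Raising the cutoff can only shrink the kept
set.

## Differential expression

Per-gene two-way fixed-effects ANOVA with factors treatment and cell
type. Every gene shares one design matrix, so the fit is vectorized
across genes via QR decompositions of the shared designs; term tests
are model comparisons (Type II sums of squares: each main effect is
tested as its increment over the other main effect; the interaction as
its increment over the additive model), all against the full-model
residual mean square. For balanced designs this coincides with the
classical decomposition; unbalanced designs are handled by the same
comparisons. The implementation is checked per-gene against
statsmodels' `anova_lm` to 1e-8.

The interaction is retained when the residual df with it is ≥ 4;
below that an additive model is fitted with a logged warning (n = 2
per cell in a 2×4 design keeps the interaction: residual df = 8).
Genes with zero residual variance get p = 1 for every term. The
p-value passed to BH is the treatment-term p by default (conditions
within/across cell types), with the full-model omnibus p available via
`omnibus="full"`; the choice is recorded on the result object.

BH is the step-up rule q_(i) = min_{j≥i} p_(j)·n/j capped at 1,
applied across genes per contrast family and cross-checked against
statsmodels. Fold changes are linear-scale ratios of group means on
*normalized* (not baselined/log) values, reported as max(r, 1/r) ≥ 1
with a direction sign; a gene is DE in (cell type, treatment) iff
q < 0.05 and FC > 1.5, both strict.

## Convergence statistics

Shared-gene percentages are computed under two conventions — Jaccard
(100·|A∩B|/|A∪B|, the primary one) and sum-based
(100·|A∩B|/(|A|+|B|)) — because the literature's bracketed
percentages rarely state their denominator; for the only fully
checkable worked case (two 2500-gene lists sharing 35 genes) both round
to 0.7%. Top-expressed lists rank genes by mean normalized RPKM in the
untreated condition, ties broken lexicographically for determinism.
PCA is run on baselined values of filtered genes (already centered per
gene up to the median/mean difference; means are re-centered, no
variance scaling), via SVD; each component's sign is fixed by making
its largest-magnitude gene loading positive. Centroid distances
between cell types are reported on a designated component (default
PC2) and on the PC1/PC2 plane.

## Promoter/peak enrichment

Promoter windows around TSS t: plus strand [t−up, t+down); minus
strand the mirror image [t−down+1, t+up+1); clamped to the chromosome.
The observed overlap of an input set with a peak dataset counts input
regions sharing ≥ 1 base with ≥ 1 peak (once each), computed by
binary search over per-chromosome merged peaks and verified exactly
against an all-pairs oracle.

The null redraws, 2000 times, as many promoters as the input has,
uniformly **without replacement** from the full annotation's windows
(all windows under one definition share a length, so size- and
length-matching coincide); input promoters are not excluded from the
sampling universe. Because the overlap count is a sum of per-window
indicators, per-window hit flags are precomputed once with the same
overlap routine and summed per draw — distributionally identical to
re-counting each drawn set, and what makes 2000 iterations × large
libraries cheap. The null sd uses the n−1 denominator.
Z = (obs − mean)/sd with a one-sided upper-tail normal P (the test is
used to rank enriched regulators; a two-sided option exists). A
degenerate null (sd = 0) yields z = 0, p = 0.5 at the mean, otherwise
±∞ with p floored at 1e-300 (enrichment) or 1 (depletion) and a flag.
Per-dataset seeds are derived by hashing (master seed, dataset id,
window label), so results are independent of library order. BH is
applied across datasets within each window definition — no
multiplicity correction is standard for this test, so raw p is kept
alongside. Under the null the one-sided p < 0.05 rate measures ~0.05
(band [0.03, 0.08] over 500 trials, reflecting the normal
approximation of a discrete count).

## Synthetic-study generator

The generator emulates a 2 cell types × 4 treatments (NS baseline,
two single agents, their combination) × n replicates design.
Counts are negative-binomial with mean
μ_gs = 2^(base + effects) · len_g/10³ · scale_s and variance
μ(1 + αμ); α = 0 falls back to Poisson. Gene lengths are uniform on
[500, 10000] bp so that RPKM is approximately length-free. Defaults:
2000 genes, n = 3 replicates (a two-way ANOVA with n = 2 is legal but
fragile; `SimulationConfig.study_like()` gives the n = 2 design),
dispersion 0.05, base mean 2⁵ reads per kilobase.

Planted programs (disjoint; log2 effects):

* **cell-type programs** (200 genes each, +3): constitutive identity
  genes; they keep the baseline top-expressed lists of the two cell
  types nearly disjoint.
* **shared single-agent programs** (100 genes per agent, +2): induced
  in both cell types by that agent and under the combination. Real
  interferon- and LPS-response genes are largely shared between cell
  types, and without a shared component single agents could not raise
  the cross-cell-type overlap at all.
* **cell-type-specific single-agent programs** (50 genes per cell type
  per agent, +2): induced in one cell type only, under the agent and
  the combination; these keep single-agent DE overlap well below the
  combined-treatment overlap.
* **dormant-convergence program** (150 genes): constitutively active
  (+3) in macrophages, silent in adipocytes; under the combined
  treatment both cell types reach the same high level (+3+2.5 over the
  adipocyte baseline, +2.5 over the macrophage one). Treatment effects
  are zero for both cell types outside the combination. The asymmetric
  baseline is essential: if both cell types were induced equally from
  equal baselines, convergence would change no between-cell-type
  distance and be invisible to the centroid statistic; with it, the
  combined condition closes a 3-log2 gap on 150 genes, which outweighs
  the distance added by the cell-type-specific responses, so the
  centroid distance demonstrably shrinks.

Annotations place one TSS per gene uniformly with 5 kb clearance from
chromosome ends (4 × 2 Mb chromosomes by default), strands fair coin
flips. Peak libraries give each gene's promoter a TSS-centered peak
with probability p_fg (targets) or p_bg (others), plus uniform decoy
peaks kept > 3 kb from any TSS.

**What the generator does not emulate:** per-gene baseline
heterogeneity (every background gene shares one base mean, so the
expression filter only bites on datasets that actually contain
low-expressed genes), count outliers and batch effects, realistic peak
width/shape and signal strength, correlated genes, and chromosomal
structure. Passing tests therefore demonstrate the statistics'
correctness and calibration under their own assumptions, not
robustness to everything real data can do.

## Problem sizes and numerics

End-to-end checks run at the study's own scale: 2000-gene matrices,
2000-iteration nulls, 500 calibration trials, 50 enrichment-recovery
runs, 100 convergence replicates, 5000-gene ANOVA/BH calibrations.
Zero-residual-variance detection uses a 1e-12 tolerance on the residual
mean square; QR rank uses a relative 1e-10 cutoff; all RNG streams are
`numpy.random.default_rng` seeded explicitly, with sub-streams derived
by seed-sequence spawning or hashing so that results are reproducible
and order-independent.

## Known limitations

* Fold changes require a positive baseline mean, guaranteed only after
  thresholding; with thresholding disabled, genes silent at baseline
  are rejected rather than assigned an infinite FC.
* The enrichment P relies on the normal approximation to the resampled
  overlap distribution; for very small universes or extreme hit rates
  the discrete null makes the tail P conservative or anticonservative,
  which the calibration band quantifies but does not remove.
* The ANOVA assumes homoscedastic Gaussian log-expression within
  groups; no empirical-Bayes dispersion shrinkage is attempted, so
  power at n = 2 is limited and the `study_like` preset should be read
  accordingly.
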