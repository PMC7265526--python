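"""Expression quantification chain.

RPKM -> threshold at 1 -> median-of-ratios normalization factors ->
normalization -> log2 baselining, plus the "reasonably expressed" gene
filter applied to raw RPKM.

The processing state of a matrix is explicit and transitions are only
allowed in the order raw -> thresholded -> normalized -> baselined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "ExpressionMatrix",
    "compute_rpkm",
    "threshold_rpkm",
    "normalization_factors",
    "apply_normalization",
    "baseline_to_median",
    "expression_filter",
    "quantify_pipeline",
]

_STATES = ("raw", "thresholded", "normalized", "baselined")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit processing state.

    ``values`` are RPKM-scale reals until ``baselined``, after which they
    are median-centered log2 values (``log_base`` is then 2).
    ``normalization_factors`` is populated once the state reaches
    ``normalized``.
    """

    values: pd.DataFrame
    state: str = "raw"
    normalization_factors: pd.Series | None = None
    log_base: int | None = None

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state != "baselined" and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values in a {self.state} matrix")
        if self.normalization_factors is not None:
            nf = self.normalization_factors
            if (nf <= 0).any():
                raise ValueError("normalization factors must be positive")

    def _require_state(self, expected: str) -> None:
        if self.state != expected:
            raise ValueError(
                f"operation requires a {expected!r} matrix, got {self.state!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def compute_rpkm(counts: CountMatrix, per_million: bool = True) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads.

    rpkm[g, s] = count[g, s] / ((length_g / 1e3) * (total_s / 1e6))
    where total_s is the column sum of raw counts.

    With ``per_million=False`` the per-sample depth division is skipped,
    yielding reads per kilobase (RPK); this keeps per-sample scale
    differences visible to the median-of-ratios estimator, which RPKM by
    construction cancels.
    """
    totals = counts.counts.sum(axis=0)
    if per_million and (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    per_kb = counts.counts.div(counts.lengths / 1e3, axis=0)
    if per_million:
        per_kb = per_kb.div(totals / 1e6, axis=1)
    return ExpressionMatrix(values=per_kb.astype(float), state="raw")


def threshold_rpkm(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Floor every value at ``floor`` (default 1). Idempotent."""
    m._require_state("raw")
    return ExpressionMatrix(values=m.values.clip(lower=floor), state="thresholded")


def normalization_factors(m: ExpressionMatrix) -> pd.Series:
    """Per-sample median-of-ratios normalization factors.

    Each gene's values are divided by that gene's geometric mean across
    samples; a sample's NF is the within-sample median of these ratios.
    Genes with a zero in any sample are excluded (the geometric mean
    through zero is degenerate) — after flooring at 1 none remain.
    """
    m._require_state("thresholded")
    vals = m.values
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute NFs")
    eligible = (vals > 0).all(axis=1)
    if not eligible.any():
        raise ValueError("no gene is positive in every sample")
    v = vals.loc[eligible]
    log_gm = np.log(v).mean(axis=1)
    ratios = v.div(np.exp(log_gm), axis=0)
    nf = ratios.median(axis=0)
    nf.name = "nf"
    return nf


def apply_normalization(m: ExpressionMatrix, nf: pd.Series) -> ExpressionMatrix:
    """Divide each sample's values by its normalization factor."""
    m._require_state("thresholded")
    if len(nf) != m.values.shape[1]:
        raise ValueError(
            f"NF length {len(nf)} does not match sample count {m.values.shape[1]}"
        )
    nf = nf.reindex(m.values.columns)
    if nf.isna().any():
        raise ValueError("NF index does not match sample ids")
    return ExpressionMatrix(
        values=m.values.div(nf, axis=1),
        state="normalized",
        normalization_factors=nf.copy(),
    )


def baseline_to_median(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform, then center each gene at its median across samples."""
    m._require_state("normalized")
    vals = m.values.to_numpy()
    if (vals <= 0).any():
        raise ValueError("cannot baseline non-positive normalized values")
    logv = np.log2(m.values)
    centered = logv.sub(logv.median(axis=1), axis=0)
    return ExpressionMatrix(
        values=centered,
        state="baselined",
        normalization_factors=m.normalization_factors,
        log_base=2,
    )


def expression_filter(
    raw: ExpressionMatrix,
    metadata: pd.DataFrame,
    cutoff: float = 3.0,
) -> pd.Index:
    """Genes with raw RPKM strictly above ``cutoff`` in 100% of the
    samples of at least one (cell_type, treatment) condition."""
    raw._require_state("raw")
    if metadata.empty:
        raise ValueError("empty sample metadata")
    keep = pd.Series(False, index=raw.values.index)
    for _, grp in metadata.groupby(["cell_type", "treatment"], observed=True):
        cols = [s for s in grp.index if s in raw.values.columns]
        if not cols:
            raise ValueError("condition with no sample columns in the matrix")
        keep |= (raw.values[cols] > cutoff).all(axis=1)
    return raw.values.index[keep]


def quantify_pipeline(
    counts: CountMatrix,
    floor: float = 1.0,
    filter_cutoff: float = 3.0,
    threshold_mode: str = "floor",
):
    """Run the full chain; returns a dict of every intermediate state.

    ``threshold_mode`` selects how the threshold at 1 is applied:
    ``"floor"`` clips values up to ``floor`` (default), ``"discard"``
    drops genes that fall below ``floor`` in any sample, ``"skip"``
    leaves values untouched (downstream baselining then rejects zeros).

    Keys: ``raw``, ``thresholded``, ``normalized``, ``baselined``,
    ``nf`` (Series), ``kept_genes`` (Index of filter survivors).
    """
    raw = compute_rpkm(counts)
    if threshold_mode == "floor":
        thr = threshold_rpkm(raw, floor=floor)
    elif threshold_mode == "discard":
        keep = (raw.values >= floor).all(axis=1)
        thr = ExpressionMatrix(values=raw.values.loc[keep], state="thresholded")
    elif threshold_mode == "skip":
        thr = ExpressionMatrix(values=raw.values.copy(), state="thresholded")
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    nf = normalization_factors(thr)
    norm = apply_normalization(thr, nf)
    baselined = baseline_to_median(norm)
    kept = expression_filter(raw, counts.metadata, cutoff=filter_cutoff)
    return {
        "raw": raw,
        "thresholded": thr,
        "normalized": norm,
        "baselined": baselined,
        "nf": nf,
        "kept_genes": kept,
    }
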