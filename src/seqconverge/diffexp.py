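"""Per-gene two-way ANOVA, BH FDR control, and fold-change-gated DE calls.

Every gene shares the same design matrix, so the ANOVA is computed for
all genes at once via model comparisons (Type II sums of squares):
each term's sum of squares is the drop in residual sum of squares when
the term is added to the model containing the other main effects, and
the interaction is tested against the full model. Unbalanced designs
are handled the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEResult",
    "two_way_anova",
    "bh_fdr",
    "fold_changes",
    "call_differential",
    "run_differential_expression",
]

logger = logging.getLogger(__name__)

_ZERO_RESID_TOL = 1e-12


def _dummies(labels: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = sorted(pd.unique(labels))
    return np.column_stack(
        [(labels == lv).to_numpy(float) for lv in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(labels), 0))


def _rss(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares of every row of Y regressed on X, and
    the model's rank."""
    Q, R = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())))
    proj = Y @ Q  # genes x rank
    fitted_ss = (proj**2).sum(axis=1)
    total = (Y**2).sum(axis=1)
    return np.maximum(total - fitted_ss, 0.0), rank


def two_way_anova(
    values: pd.DataFrame,
    design: pd.DataFrame,
    interaction: str = "auto",
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA (treatment x cell type) per gene.

    ``values`` is genes x samples (log2 baselined expression);
    ``design`` is indexed by sample id with ``cell_type`` and
    ``treatment`` columns. ``interaction`` is ``"auto"`` (keep the
    interaction when the residual df with it is >= 4, else drop it with
    a warning), ``"always"`` or ``"never"``.

    Returns a frame with F and p per term (``treatment``,
    ``cell_type``, ``interaction``) plus the full-model omnibus test
    (``model``). Genes with zero residual variance get p = 1.
    """
    design = design.loc[list(values.columns)]
    tr, ct = design["treatment"], design["cell_type"]
    if tr.nunique() < 2 or ct.nunique() < 2:
        raise ValueError("both factors need at least 2 levels")

    n = len(design)
    ones = np.ones((n, 1))
    Dt, Dc = _dummies(tr), _dummies(ct)
    inter_cols = (Dt[:, :, None] * Dc[:, None, :]).reshape(n, -1)

    X_add = np.hstack([ones, Dt, Dc])
    X_full = np.hstack([X_add, inter_cols])
    _, rank_full = _rss(np.zeros((1, n)), X_full)
    df_res_full = n - rank_full
    use_interaction = interaction == "always" or (
        interaction == "auto" and df_res_full >= 4
    )
    if interaction == "always" and df_res_full < 1:
        raise ValueError(
            "fewer than 1 residual df with the interaction term; drop the "
            "interaction or add replicates"
        )
    if interaction == "auto" and df_res_full < 4:
        logger.warning(
            "residual df with interaction = %d < 4; fitting additive model",
            df_res_full,
        )

    Y = values.to_numpy(dtype=float)
    X_model = X_full if use_interaction else X_add
    rss_model, rank_model = _rss(Y, X_model)
    df_res = n - rank_model
    if df_res < 1:
        raise ValueError(
            "no residual degrees of freedom; drop the interaction term or "
            "add replicates"
        )
    s2 = rss_model / df_res

    comparisons = {
        "treatment": np.hstack([ones, Dc]),       # add treatment to cell_type
        "cell_type": np.hstack([ones, Dt]),       # add cell_type to treatment
    }
    out = pd.DataFrame(index=values.index)
    degenerate = s2 <= _ZERO_RESID_TOL
    rss_base, rank_base = _rss(Y, X_add)
    for term, X_red in comparisons.items():
        rss_red, rank_red = _rss(Y, np.ascontiguousarray(X_red))
        df_term = rank_base - rank_red
        ss_term = np.maximum(rss_red - rss_base, 0.0)
        F = (ss_term / df_term) / np.where(degenerate, np.nan, s2)
        p = stats.f.sf(F, df_term, df_res)
        F = np.where(degenerate, np.nan, F)
        p = np.where(degenerate, 1.0, p)
        out[f"F_{term}"], out[f"p_{term}"] = F, p

    if use_interaction:
        df_int = rank_model - rank_base
        ss_int = np.maximum(rss_base - rss_model, 0.0)
        F = (ss_int / df_int) / np.where(degenerate, np.nan, s2)
        p = stats.f.sf(F, df_int, df_res)
        out["F_interaction"] = np.where(degenerate, np.nan, F)
        out["p_interaction"] = np.where(degenerate, 1.0, p)
    else:
        out["F_interaction"] = np.nan
        out["p_interaction"] = np.nan

    rss_null, _ = _rss(Y, ones)
    df_model = rank_model - 1
    ss_model = np.maximum(rss_null - rss_model, 0.0)
    F = (ss_model / df_model) / np.where(degenerate, np.nan, s2)
    p = stats.f.sf(F, df_model, df_res)
    out["F_model"] = np.where(degenerate, np.nan, F)
    out["p_model"] = np.where(degenerate, 1.0, p)
    out.attrs["interaction_fitted"] = use_interaction
    out.attrs["df_residual"] = int(df_res)
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def fold_changes(
    values: pd.DataFrame,
    design: pd.DataFrame,
    baseline: str = "NS",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Linear fold changes of each (cell type, treatment) vs the
    cell type's baseline condition.

    ``values`` must be on the linear (normalized RPKM) scale. Returns
    ``(fc, direction)`` frames with MultiIndex columns
    (cell_type, treatment): fc = max(r, 1/r) >= 1 where r is the ratio
    of group means; direction is +1 (up), -1 (down) or 0 (r == 1).
    """
    design = design.loc[list(values.columns)]
    cell_types = sorted(design["cell_type"].unique())
    treatments = [t for t in design["treatment"].unique() if t != baseline]
    group_means: dict[tuple[str, str], pd.Series] = {}
    for (ct, tr), grp in design.groupby(["cell_type", "treatment"], observed=True):
        group_means[(ct, tr)] = values[list(grp.index)].mean(axis=1)
    fc_cols, dir_cols, keys = [], [], []
    for ct in cell_types:
        if (ct, baseline) not in group_means:
            raise ValueError(f"no {baseline!r} samples for cell type {ct!r}")
        base = group_means[(ct, baseline)]
        if (base <= 0).any():
            raise ValueError("non-positive baseline mean; threshold first")
        for tr in treatments:
            if (ct, tr) not in group_means:
                continue
            r = group_means[(ct, tr)] / base
            fc_cols.append(np.maximum(r, 1.0 / r))
            dir_cols.append(np.sign(r - 1.0))
            keys.append((ct, tr))
    cols = pd.MultiIndex.from_tuples(keys, names=["cell_type", "treatment"])
    fc = pd.concat(fc_cols, axis=1)
    fc.columns = cols
    direction = pd.concat(dir_cols, axis=1)
    direction.columns = cols
    return fc, direction


@dataclass
class DEResult:
    """Differential-expression results for one study.

    ``anova`` holds per-gene F/p per term; ``q`` is the BH-adjusted
    omnibus p; ``fold_change``/``direction`` are per-(cell type,
    treatment) contrasts vs baseline; ``calls`` is the boolean DE
    matrix at (``q_cut``, ``fc_cut``).
    """

    anova: pd.DataFrame
    q: pd.Series
    fold_change: pd.DataFrame
    direction: pd.DataFrame
    calls: pd.DataFrame
    q_cut: float = 0.05
    fc_cut: float = 1.5
    omnibus: str = "treatment"

    def gene_sets(self) -> dict[tuple[str, str], set[str]]:
        """DE gene sets keyed by (cell_type, treatment)."""
        return {
            key: set(self.calls.index[self.calls[key]])
            for key in self.calls.columns
        }

    def to_frame(self) -> pd.DataFrame:
        wide = self.anova.copy()
        wide.insert(0, "gene_id", wide.index)
        wide["q"] = self.q
        for ct, tr in self.fold_change.columns:
            wide[f"fc_{ct}_{tr}"] = self.fold_change[(ct, tr)]
            wide[f"dir_{ct}_{tr}"] = self.direction[(ct, tr)]
            wide[f"de_{ct}_{tr}"] = self.calls[(ct, tr)]
        return wide.reset_index(drop=True)


def call_differential(
    q: pd.Series,
    fold_change: pd.DataFrame,
    q_cut: float = 0.05,
    fc_cut: float = 1.5,
) -> pd.DataFrame:
    """Boolean DE calls: q < q_cut (strict) AND fc > fc_cut (strict),
    per (cell_type, treatment) contrast."""
    sig = q < q_cut
    return fold_change.gt(fc_cut).mul(sig, axis=0).astype(bool)


def run_differential_expression(
    baselined: pd.DataFrame,
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    genes: pd.Index | None = None,
    omnibus: str = "treatment",
    q_cut: float = 0.05,
    fc_cut: float = 1.5,
    baseline: str = "NS",
    interaction: str = "auto",
) -> DEResult:
    """ANOVA + BH + fold changes + calls on the filtered gene set.

    ``omnibus`` chooses the p-value fed to BH: ``"treatment"`` (the
    treatment-term p; comparisons across conditions) or ``"full"``
    (the whole-model p; any term may drive significance).
    """
    if genes is not None:
        baselined = baselined.loc[baselined.index.intersection(genes)]
        normalized = normalized.loc[baselined.index]
    anova = two_way_anova(baselined, design, interaction=interaction)
    if omnibus == "treatment":
        p = anova["p_treatment"]
    elif omnibus == "full":
        p = anova["p_model"]
    else:
        raise ValueError("omnibus must be 'treatment' or 'full'")
    q = pd.Series(bh_fdr(p.to_numpy()), index=anova.index, name="q")
    fc, direction = fold_changes(normalized, design, baseline=baseline)
    calls = call_differential(q, fc, q_cut=q_cut, fc_cut=fc_cut)
    return DEResult(
        anova=anova, q=q, fold_change=fc, direction=direction, calls=calls,
        q_cut=q_cut, fc_cut=fc_cut, omnibus=omnibus,
    )
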