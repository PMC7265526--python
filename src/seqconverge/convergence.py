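"""Cell-type convergence statistics.

How similar do two cell types become under treatment? Measured four
ways: overlap of the top-expressed gene lists at baseline, percentage
of shared differentially expressed genes per condition, overlap of a
cell type's combined-treatment DE set with its single-treatment sets,
and the distance between cell-type centroids in PCA space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OverlapStats",
    "top_expressed",
    "overlap_stats",
    "condition_overlap_table",
    "within_celltype_overlap",
    "pca_samples",
    "centroid_distance",
]


@dataclass(frozen=True)
class OverlapStats:
    """Set-overlap summary between two gene sets A and B.

    ``jaccard_pct`` = 100*|A∩B|/|A∪B| (the primary shared-gene
    convention); ``sum_pct`` = 100*|A∩B|/(|A|+|B|); the ``frac_of_*``
    fields give the intersection as a percentage of each set alone.
    """

    size_a: int
    size_b: int
    intersection: int
    union: int
    jaccard_pct: float
    sum_pct: float
    frac_of_a_pct: float
    frac_of_b_pct: float

    def as_row(self) -> dict:
        return self.__dict__.copy()


def overlap_stats(a: Iterable[str], b: Iterable[str]) -> OverlapStats:
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("both sets empty: overlap percentages undefined")
    inter = len(a & b)
    union = len(a | b)
    return OverlapStats(
        size_a=len(a),
        size_b=len(b),
        intersection=inter,
        union=union,
        jaccard_pct=100.0 * inter / union,
        sum_pct=100.0 * inter / (len(a) + len(b)),
        frac_of_a_pct=100.0 * inter / len(a) if a else 0.0,
        frac_of_b_pct=100.0 * inter / len(b) if b else 0.0,
    )


def top_expressed(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    cell_type: str,
    condition: str = "NS",
    n: int = 2500,
) -> list[str]:
    """The ``n`` most highly expressed genes for one cell type in one
    condition, ranked by mean normalized expression (descending); ties
    broken by lexicographic gene id, so the ranking is deterministic."""
    if n > len(values):
        raise ValueError(f"n={n} exceeds gene count {len(values)}")
    mask = (metadata["cell_type"] == cell_type) & (
        metadata["treatment"] == condition
    )
    samples = [s for s in metadata.index[mask] if s in values.columns]
    if not samples:
        raise ValueError(
            f"no samples for cell type {cell_type!r} in condition {condition!r}"
        )
    means = values[samples].mean(axis=1)
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:n]]


def condition_overlap_table(
    de_sets: Mapping[tuple[str, str], set],
    baseline_sets: tuple[Iterable[str], Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Per-condition overlap between the two cell types' DE sets.

    ``de_sets`` is keyed by (cell_type, condition); exactly two cell
    types must appear. Conditions with an empty union are omitted.
    ``baseline_sets``, when given, adds a ``baseline`` row comparing
    the two cell types' top-expressed lists.
    """
    cell_types = sorted({ct for ct, _ in de_sets})
    if len(cell_types) != 2:
        raise ValueError(f"need exactly 2 cell types, got {cell_types}")
    ct_a, ct_b = cell_types
    conditions = [c for _, c in de_sets.keys()]
    seen, ordered = set(), []
    for c in conditions:
        if c not in seen:
            seen.add(c)
            ordered.append(c)
    rows = []
    if baseline_sets is not None:
        stats = overlap_stats(*baseline_sets)
        rows.append({"condition": "baseline", **stats.as_row()})
    for cond in ordered:
        if (ct_a, cond) not in de_sets or (ct_b, cond) not in de_sets:
            raise ValueError(f"condition {cond!r} missing a cell type")
        a, b = de_sets[(ct_a, cond)], de_sets[(ct_b, cond)]
        if not a and not b:
            continue
        rows.append({"condition": cond, **overlap_stats(a, b).as_row()})
    return pd.DataFrame(rows)


def within_celltype_overlap(
    combined: set,
    singles: Mapping[str, set],
) -> pd.DataFrame:
    """Overlap of one cell type's combined-treatment DE set (A) with
    each of its single-treatment DE sets (B); ``frac_of_a_pct`` is the
    share of the combined set that each single treatment explains."""
    if not combined:
        raise ValueError("empty combined-treatment DE set")
    rows = []
    for name, single in singles.items():
        if not single:
            rows.append({
                "versus": name, "size_a": len(combined), "size_b": 0,
                "intersection": 0, "union": len(combined), "jaccard_pct": 0.0,
                "sum_pct": 0.0, "frac_of_a_pct": 0.0, "frac_of_b_pct": 0.0,
            })
            continue
        rows.append({"versus": name, **overlap_stats(combined, single).as_row()})
    return pd.DataFrame(rows)


def pca_samples(
    values: pd.DataFrame,
    gene_subset: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Project samples onto principal components of the gene-centered
    expression matrix.

    Components are ordered by explained variance; each component's
    sign is fixed so its largest-magnitude gene loading is positive.
    Returns (coords: samples x PCs, explained_variance per PC; the
    explained variances sum to the total per-gene variance).
    """
    if gene_subset is not None:
        values = values.loc[values.index.intersection(set(gene_subset))]
    if values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)          # center per gene
    if np.allclose(Xc, 0):
        raise ValueError("matrix has no variance across samples")
    # SVD of genes x samples: columns of V are sample-space components
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(values.shape[1] - 1, int(np.sum(S > 1e-10 * S[0])))
    if k < 1:
        raise ValueError("fewer than 1 non-degenerate dimension")
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention: dominant loading (column of U) positive
    for i in range(k):
        j = np.argmax(np.abs(U[:, i]))
        if U[j, i] < 0:
            U[:, i] *= -1
            Vt[i] *= -1
    n = values.shape[1]
    coords = pd.DataFrame(
        (Vt * S[:, None]).T,
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    explained = pd.Series(
        S**2 / (n - 1), index=coords.columns, name="explained_variance"
    )
    return coords, explained


def centroid_distance(
    coords: pd.DataFrame,
    metadata: pd.DataFrame,
    condition: str,
    component: int = 2,
) -> dict:
    """Euclidean distance between the two cell-type centroids for one
    condition, on the designated component alone and on the PC1/PC2
    plane."""
    meta = metadata.loc[list(coords.index)]
    mask = meta["treatment"] == condition
    cell_types = sorted(meta.loc[mask, "cell_type"].unique())
    if len(cell_types) != 2:
        raise ValueError(
            f"condition {condition!r} lacks samples from both cell types"
        )
    centroids = {}
    for ct in cell_types:
        rows = coords.loc[mask.index[mask & (meta["cell_type"] == ct)]]
        centroids[ct] = rows.mean(axis=0)
    delta = centroids[cell_types[0]] - centroids[cell_types[1]]
    comp = f"PC{component}"
    if comp not in coords.columns:
        raise ValueError(f"coordinates lack component {comp}")
    plane_cols = [c for c in ("PC1", "PC2") if c in coords.columns]
    return {
        "condition": condition,
        "component": comp,
        "distance_component": float(abs(delta[comp])),
        "distance_plane": float(np.sqrt((delta[plane_cols] ** 2).sum())),
    }
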