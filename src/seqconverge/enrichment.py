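"""Simulation-based promoter/peak-dataset enrichment test.

Given a gene set, build strand-aware promoter windows around each TSS,
count how many of them overlap a peak dataset by at least one base
(the *observed overlap*), and calibrate that count against an
empirical null built from 2000 redraws of equally many randomly chosen
promoters from the full annotation. The null is summarized by a
normal-approximation Z-score and one-sided upper-tail P-value, and a
library of datasets is ranked by Z.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PeakDataset, PromoterAnnotation
from .diffexp import bh_fdr

__all__ = [
    "PromoterWindowDef",
    "NullDistribution",
    "EnrichmentResult",
    "DEFAULT_WINDOWS",
    "promoter_windows",
    "observed_overlap",
    "sample_null",
    "z_p_from_null",
    "enrich_library",
]

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class PromoterWindowDef:
    """A promoter window relative to the TSS: ``upstream`` bases before
    it and ``downstream`` bases from it onward (strand-aware)."""

    upstream: int
    downstream: int

    def __post_init__(self) -> None:
        if self.upstream + self.downstream < 1:
            raise ValueError("window must span at least 1 base")

    @property
    def label(self) -> str:
        return f"m{self.upstream}_p{self.downstream}"

    @property
    def length(self) -> int:
        return self.upstream + self.downstream


# the three standard definitions: (-1000,+500), (-1000,+1000), (-2000,+1)
DEFAULT_WINDOWS = (
    PromoterWindowDef(1000, 500),
    PromoterWindowDef(1000, 1000),
    PromoterWindowDef(2000, 1),
)


def promoter_windows(
    genes: Iterable[str],
    annotation: PromoterAnnotation,
    w: PromoterWindowDef,
) -> pd.DataFrame:
    """Strand-aware promoter windows as 0-based half-open intervals.

    Plus strand, TSS t: [t - upstream, t + downstream). Minus strand:
    the mirror image [t - downstream + 1, t + upstream + 1). Windows
    are clamped to the chromosome; every unclamped window has length
    upstream + downstream.
    """
    genes = list(genes)
    table = annotation.table
    missing = [g for g in genes if g not in table.index]
    if missing:
        raise KeyError(f"gene(s) absent from annotation: {missing[:5]}")
    sub = table.loc[genes]
    tss = sub["tss"].to_numpy(dtype=np.int64)
    plus = (sub["strand"] == "+").to_numpy()
    start = np.where(plus, tss - w.upstream, tss - w.downstream + 1)
    end = np.where(plus, tss + w.downstream, tss + w.upstream + 1)
    limits = sub["chrom"].map(annotation.chrom_sizes).to_numpy(dtype=np.int64)
    start = np.clip(start, 0, limits)
    end = np.clip(end, 0, limits)
    return pd.DataFrame({
        "chrom": sub["chrom"].to_numpy(),
        "start": start.astype(np.int64),
        "end": end.astype(np.int64),
        "name": genes,
    })


def _region_hits(regions: pd.DataFrame, peaks: PeakDataset) -> np.ndarray:
    """Boolean per-region: does the region share >= 1 base with any peak?

    Peaks are merged and sorted per chromosome, so the region [s, e)
    overlaps iff the last merged peak starting before e extends past s.
    """
    merged = peaks.merged_by_chrom()
    hits = np.zeros(len(regions), dtype=bool)
    pos = np.arange(len(regions))
    for chrom, grp in regions.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        m_starts, m_ends = merged[chrom]
        if len(m_starts) == 0:
            continue
        r_start = grp["start"].to_numpy()
        r_end = grp["end"].to_numpy()
        idx = np.searchsorted(m_starts, r_end, side="left") - 1
        ok = (idx >= 0) & (np.take(m_ends, idx, mode="clip") > r_start)
        ok &= r_end > r_start  # a fully clamped (empty) window hits nothing
        hits[pos[regions["chrom"].to_numpy() == chrom]] = ok
    return hits


def observed_overlap(regions: pd.DataFrame, peaks: PeakDataset) -> int:
    """Number of input regions overlapping >= 1 peak by >= 1 base.

    Half-open semantics: [0,10) and [10,20) do not overlap; [0,10)
    and [9,20) do. A region overlapping several peaks counts once.
    """
    if len(regions) == 0 or len(peaks) == 0:
        return 0
    return int(_region_hits(regions, peaks).sum())


@dataclass
class NullDistribution:
    """Empirical null of overlap counts from repeated size-matched
    random promoter draws. ``sd`` uses the n-1 denominator."""

    samples: np.ndarray
    n_iter: int
    rng_seed: int
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if len(self.samples) != self.n_iter:
            raise ValueError("sample count disagrees with n_iter")
        self.mean = float(self.samples.mean())
        self.sd = float(self.samples.std(ddof=1)) if self.n_iter > 1 else 0.0


def sample_null(
    input_size: int,
    universe: pd.DataFrame,
    peaks: PeakDataset,
    n_iter: int = 2000,
    rng_seed: int = 0,
    _hits: np.ndarray | None = None,
) -> NullDistribution:
    """Null overlap distribution from ``n_iter`` random promoter sets.

    Each iteration draws ``input_size`` windows uniformly without
    replacement from ``universe`` (all promoter windows of the same
    definition, hence the same length as the input windows) and records
    their observed overlap with ``peaks``. Because the overlap count is
    a sum of per-window indicators, the per-window hit flags are
    precomputed once with the same routine used for the observed count.
    """
    n_universe = len(universe)
    if input_size > n_universe:
        raise ValueError(
            f"input_size {input_size} exceeds universe size {n_universe}"
        )
    hits = _region_hits(universe, peaks) if _hits is None else _hits
    rng = np.random.default_rng(rng_seed)
    if input_size == n_universe:
        samples = np.full(n_iter, int(hits.sum()), dtype=np.int64)
    else:
        samples = np.empty(n_iter, dtype=np.int64)
        batch = max(1, min(n_iter, int(4e6 // max(1, n_universe))))
        done = 0
        while done < n_iter:
            b = min(batch, n_iter - done)
            keys = rng.random((b, n_universe))
            idx = np.argpartition(keys, input_size - 1, axis=1)[:, :input_size]
            samples[done:done + b] = hits[idx].sum(axis=1)
            done += b
    return NullDistribution(samples=samples, n_iter=n_iter, rng_seed=rng_seed)


class ZP(NamedTuple):
    z: float
    p: float
    degenerate: bool = False


def z_p_from_null(observed: int, null: NullDistribution) -> ZP:
    """Z-score and one-sided (enrichment) normal P from the empirical null.

    A degenerate null (sd = 0) yields z = 0, p = 0.5 when the observed
    count equals the null mean; otherwise z is an infinite sentinel
    with p floored at 1e-300 (enrichment) or set to 1 (depletion).
    """
    if null.sd > 0:
        z = (observed - null.mean) / null.sd
        return ZP(z=float(z), p=float(stats.norm.sf(z)), degenerate=False)
    if observed == null.mean:
        return ZP(z=0.0, p=0.5, degenerate=True)
    if observed > null.mean:
        return ZP(z=float("inf"), p=_P_FLOOR, degenerate=True)
    return ZP(z=float("-inf"), p=1.0, degenerate=True)


@dataclass
class EnrichmentResult:
    """Ranked library-wide enrichment table.

    One row per (dataset, window): observed overlap, null mean/sd, z,
    one-sided p, BH q across datasets within the window, input size,
    and a degenerate-null flag. Rows are sorted by z descending.
    """

    table: pd.DataFrame
    n_iter: int
    seed: int
    tail: str = "one"

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def top(self, window_label: str | None = None, n: int = 10) -> pd.DataFrame:
        t = self.table
        if window_label is not None:
            t = t[t["window"] == window_label]
        return t.head(n)


def _dataset_seed(master_seed: int, dataset_id: str, window_label: str) -> int:
    digest = hashlib.sha256(
        f"{master_seed}|{dataset_id}|{window_label}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def enrich_library(
    gene_set: Iterable[str],
    annotation: PromoterAnnotation,
    peak_library: Sequence[PeakDataset],
    windows: Sequence[PromoterWindowDef] = DEFAULT_WINDOWS,
    n_iter: int = 2000,
    seed: int = 0,
    tail: str = "one",
) -> EnrichmentResult:
    """Run the enrichment test for every (dataset, window) pair.

    Per-dataset RNG seeds are derived deterministically from the master
    seed, the dataset id and the window label, so results do not depend
    on library order. BH adjustment is applied across datasets within
    each window; raw p is kept alongside. Rows are sorted by z
    descending (ties by p then dataset id).
    """
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty input gene set")
    if not peak_library:
        raise ValueError("empty peak library")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    rows = []
    for w in windows:
        universe = promoter_windows(annotation.gene_ids, annotation, w)
        input_idx = universe.index[universe["name"].isin(set(gene_set))]
        for ds in peak_library:
            hits = _region_hits(universe, ds)
            observed = int(hits[input_idx].sum())
            ds_seed = _dataset_seed(seed, ds.name, w.label)
            null = sample_null(
                input_size=len(gene_set), universe=universe, peaks=ds,
                n_iter=n_iter, rng_seed=ds_seed, _hits=hits,
            )
            zp = z_p_from_null(observed, null)
            p = zp.p
            if tail == "two" and not zp.degenerate:
                p = float(2 * stats.norm.sf(abs(zp.z)))
            rows.append({
                "dataset": ds.name, "window": w.label, "observed": observed,
                "null_mean": null.mean, "null_sd": null.sd, "z": zp.z,
                "p": p, "input_size": len(gene_set),
                "degenerate_null": zp.degenerate,
            })
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for w in windows:
        mask = table["window"] == w.label
        table.loc[mask, "q"] = bh_fdr(table.loc[mask, "p"].to_numpy())
    table = table.sort_values(
        ["z", "p", "dataset"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    cols = ["dataset", "window", "observed", "null_mean", "null_sd", "z",
            "p", "q", "input_size", "degenerate_null"]
    return EnrichmentResult(table=table[cols], n_iter=n_iter, seed=seed,
                            tail=tail)
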