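"""Shared in-memory containers for the pipeline.

All genomic coordinates, in memory and on disk, are 0-based half-open
(BED convention). A transcription start site (TSS) is the 0-based
position of the first transcribed base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "PromoterAnnotation",
    "GenomicInterval",
    "PeakDataset",
    "VALID_STRANDS",
]

VALID_STRANDS = frozenset({"+", "-"})


class GenomicInterval(NamedTuple):
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    name: str = ""


@dataclass
class CountMatrix:
    """Raw gene-level counts with gene lengths and per-sample metadata.

    Parameters
    ----------
    counts
        Genes x samples integer matrix; the index holds gene ids and
        the columns hold sample ids.
    lengths
        Per-gene transcript length in base pairs, indexed like ``counts``.
    metadata
        One row per sample (indexed by sample id) with ``cell_type``,
        ``treatment`` and ``replicate`` columns.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.empty:
            raise ValueError("count matrix is empty")
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(vals != np.round(vals))[0]
                raise ValueError(
                    f"non-integer count at gene {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
            self.counts = counts = counts.round().astype(np.int64)
            vals = counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at gene {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        self.lengths = self.lengths.reindex(counts.index).rename("length_bp")
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive length_bp")
        missing = [c for c in counts.columns if c not in self.metadata.index]
        if missing:
            raise ValueError(f"sample column(s) missing from metadata: {missing}")
        for col in ("cell_type", "treatment", "replicate"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        counts.index.name = "gene_id"
        counts.columns.name = None
        meta = self.metadata.loc[list(counts.columns)]
        meta.index.name = "sample_id"
        dup = meta.duplicated(subset=["cell_type", "treatment", "replicate"])
        if dup.any():
            raise ValueError(
                "duplicate (cell_type, treatment, replicate) in metadata: "
                f"{list(meta.index[dup])}"
            )
        self.metadata = meta

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class PromoterAnnotation:
    """Gene TSS annotation plus chromosome sizes.

    ``table`` is indexed by gene id with columns ``chrom``, ``tss``
    (0-based) and ``strand`` (``+``/``-``); ``chrom_sizes`` maps
    chromosome name to its length in bases.
    """

    table: pd.DataFrame
    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in annotation: {dups}")
        bad_strand = ~t["strand"].isin(VALID_STRANDS)
        if bad_strand.any():
            raise ValueError(
                f"invalid strand for {t.index[bad_strand][0]!r}: "
                f"{t.loc[bad_strand, 'strand'].iloc[0]!r} (must be + or -)"
            )
        if (t["tss"] < 0).any():
            raise ValueError("negative TSS in annotation")
        self.chrom_sizes = dict(self.chrom_sizes)
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"non-positive size for chromosome {chrom!r}")
        unknown = set(t["chrom"]) - set(self.chrom_sizes)
        if unknown:
            raise ValueError(f"chromosomes without a size entry: {sorted(unknown)}")
        limits = t["chrom"].map(self.chrom_sizes)
        over = t["tss"] >= limits
        if over.any():
            raise ValueError(
                f"TSS beyond chromosome end for gene(s) {list(t.index[over])}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PeakDataset:
    """A named collection of peaks (0-based half-open intervals).

    ``intervals`` has columns ``chrom``, ``start``, ``end`` and is kept
    sorted by (chrom, start, end). Merged per-chromosome interval arrays
    used for fast overlap queries are cached lazily.
    """

    name: str
    intervals: pd.DataFrame
    _merged: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.intervals
        required = ["chrom", "start", "end"]
        if list(df.columns[:3]) != required:
            df = df.rename(
                columns=dict(zip(df.columns[:3], required))
            )[required]
        df = df.astype({"start": np.int64, "end": np.int64})
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"empty or inverted interval in {self.name!r}: "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )
        if (df["start"] < 0).any():
            raise ValueError(f"negative coordinate in {self.name!r}")
        self.intervals = df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Iterable[tuple]
    ) -> "PeakDataset":
        df = pd.DataFrame(
            [(i[0], i[1], i[2]) for i in intervals],
            columns=["chrom", "start", "end"],
        )
        if df.empty:
            df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                               "start": pd.Series(dtype=np.int64),
                               "end": pd.Series(dtype=np.int64)})
        return cls(name=name, intervals=df)

    def __len__(self) -> int:
        return len(self.intervals)

    def merged_by_chrom(self) -> dict:
        """Per-chromosome (starts, ends) arrays of merged, sorted peaks.

        Merging overlapping/adjacent-overlapping peaks preserves the
        region-overlap predicate (a region overlaps some peak iff it
        overlaps some merged peak) while making queries binary-search
        friendly.
        """
        if self._merged is None:
            merged: dict = {}
            for chrom, grp in self.intervals.groupby("chrom", sort=False):
                starts = grp["start"].to_numpy()
                ends = grp["end"].to_numpy()
                m_starts: list[int] = []
                m_ends: list[int] = []
                for s, e in zip(starts, ends):
                    if m_ends and s < m_ends[-1]:
                        if e > m_ends[-1]:
                            m_ends[-1] = int(e)
                    else:
                        m_starts.append(int(s))
                        m_ends.append(int(e))
                merged[chrom] = (
                    np.asarray(m_starts, dtype=np.int64),
                    np.asarray(m_ends, dtype=np.int64),
                )
            self._merged = merged
        return self._merged
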