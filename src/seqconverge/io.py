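"""Readers and writers for the pipeline's on-disk formats.

Tables are tab-separated with a header; peaks are BED3 (tab-separated,
0-based half-open, no header). Malformed lines are hard errors — nothing
is silently skipped.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Union

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix, PeakDataset, PromoterAnnotation

if TYPE_CHECKING:  # pragma: no cover
    from .diffexp import DEResult
    from .enrichment import EnrichmentResult

__all__ = [
    "read_counts_table",
    "write_counts_table",
    "read_annotation",
    "write_annotation",
    "read_bed",
    "write_bed",
    "write_results_table",
    "read_config",
]

PathLike = Union[str, Path]


def read_counts_table(path: PathLike, metadata_path: PathLike) -> CountMatrix:
    """Read a gene-level counts table plus its sample metadata.

    The counts table has columns ``gene_id``, ``length_bp``, then one
    column per sample; the metadata table maps ``sample_id`` to
    ``cell_type``, ``treatment`` and ``replicate``.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "length_bp"):
        if col not in df.columns:
            raise ValueError(f"counts table {path} lacks column {col!r}")
    df = df.set_index("gene_id")
    lengths = df.pop("length_bp")
    meta = pd.read_csv(metadata_path, sep="\t").set_index("sample_id")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            gene = df.index[numeric.isna()][0]
            raise ValueError(
                f"non-numeric count at gene {gene!r}, sample {col!r}"
            )
        df[col] = numeric
    return CountMatrix(counts=df, lengths=lengths, metadata=meta)


def write_counts_table(
    cm: CountMatrix, path: PathLike, metadata_path: PathLike
) -> None:
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths)
    out.to_csv(path, sep="\t", index_label="gene_id")
    cm.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_annotation(path: PathLike, chrom_sizes_path: PathLike) -> PromoterAnnotation:
    """Read a TSS annotation table and its companion chrom-sizes table."""
    t = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str}
    )
    for col in ("gene_id", "chrom", "tss", "strand"):
        if col not in t.columns:
            raise ValueError(f"annotation {path} lacks column {col!r}")
    t = t.set_index("gene_id")
    t["tss"] = pd.to_numeric(t["tss"], errors="raise").astype(np.int64)
    sizes = pd.read_csv(chrom_sizes_path, sep="\t", dtype={"chrom": str})
    chrom_sizes = dict(zip(sizes["chrom"], sizes["length"].astype(int)))
    return PromoterAnnotation(table=t, chrom_sizes=chrom_sizes)


def write_annotation(
    ann: PromoterAnnotation, path: PathLike, chrom_sizes_path: PathLike
) -> None:
    ann.table.to_csv(path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        sorted(ann.chrom_sizes.items()), columns=["chrom", "length"]
    ).to_csv(chrom_sizes_path, sep="\t", index=False)


def read_bed(path: PathLike, name: str | None = None) -> PeakDataset:
    """Read a BED3+ file into a :class:`PeakDataset`.

    The dataset name defaults to the file stem. Zero-length or inverted
    intervals and non-numeric coordinates are hard errors reported with
    their line number.
    """
    path = Path(path)
    rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinate {s!r}/{e!r}"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"[{start}, {end})"
                )
            rows.append((chrom, start, end))
    return PeakDataset.from_intervals(name or path.stem, rows)


def write_bed(dataset: PeakDataset, path: PathLike) -> None:
    """Write BED3, sorted by (chrom, start), newline-terminated."""
    df = dataset.intervals.sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        for chrom, start, end in df.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_results_table(result, path: PathLike) -> None:
    """Write a DE or enrichment result as a tab-separated table.

    Column order is the fixed order of the object's ``to_frame()``;
    floats carry 8 significant digits.
    """
    frame = result.to_frame() if hasattr(result, "to_frame") else result
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_config(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
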