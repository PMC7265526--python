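"""Synthetic study generator.

Emulates a two-cell-type (adipocyte, macrophage) x four-treatment
(NS, IFNB, LPS, IFNB_LPS) bulk RNA-seq design with negative-binomial
counts, plus promoter annotations and ChIP-seq-like peak libraries with
planted enrichment, so that every downstream stage can be checked
against known ground truth.

Planted gene programs
---------------------
* cell-type program: constitutively higher in one cell type.
* shared treatment program (per agent): induced in BOTH cell types by
  that agent, and under the combined treatment (which contains it).
* cell-type-specific treatment program (per cell type x agent): induced
  in one cell type only, under that agent and under the combined
  treatment.
* dormant-convergence program: silent in one cell type and
  constitutively active in the other at baseline; under the combined
  treatment both cell types are induced up to the same high level, so
  the cross-cell-type gap on these genes closes. Treatment effects are
  zero for both cell types outside the combined condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, PeakDataset, PromoterAnnotation

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "simulate_expression",
    "simulate_annotation",
    "simulate_peak_library",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Effect sizes are log2 fold changes over the baseline mean
    ``base_mean_log2`` (log2 expected reads per kilobase at scale
    factor 1). ``n_replicates`` defaults to 3 for a stable two-way
    ANOVA; :meth:`study_like` gives the fragile-but-legal n=2 design.
    """

    n_genes: int = 2000
    cell_types: tuple[str, str] = ("adipocyte", "macrophage")
    treatments: tuple[str, ...] = ("NS", "IFNB", "LPS", "IFNB_LPS")
    baseline_treatment: str = "NS"
    combined_treatment: str = "IFNB_LPS"
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    base_mean_log2: float = 5.0
    library_scale_factors: tuple[float, ...] | None = None
    n_celltype_genes: int = 200        # per cell type
    celltype_effect: float = 3.0
    n_shared_treatment_genes: int = 100  # per single agent, both cell types
    n_treatment_genes: int = 50        # per (cell type, single agent)
    treatment_effect: float = 2.0
    n_dormant_genes: int = 150
    dormant_effect: float = 2.5        # induction in the already-active cell type
    dormant_baseline_gap: float = 3.0  # baseline surplus of the active cell type
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes and n_replicates must be positive")
        if len(self.cell_types) != 2:
            raise ValueError("exactly 2 cell types are supported")
        if self.baseline_treatment not in self.treatments:
            raise ValueError("baseline treatment missing from treatments")
        if self.combined_treatment not in self.treatments:
            raise ValueError("combined treatment missing from treatments")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        single = [
            t for t in self.treatments
            if t not in (self.baseline_treatment, self.combined_treatment)
        ]
        n_programmed = (
            2 * self.n_celltype_genes
            + len(single) * self.n_shared_treatment_genes
            + 2 * len(single) * self.n_treatment_genes
            + self.n_dormant_genes
        )
        if n_programmed > self.n_genes:
            raise ValueError(
                f"program genes ({n_programmed}) exceed n_genes ({self.n_genes})"
            )
        if self.library_scale_factors is not None:
            sf = np.asarray(self.library_scale_factors, dtype=float)
            if len(sf) != self.n_samples:
                raise ValueError(
                    f"need {self.n_samples} scale factors, got {len(sf)}"
                )
            if (sf <= 0).any():
                raise ValueError("scale factors must be positive")

    @property
    def single_treatments(self) -> list[str]:
        return [
            t for t in self.treatments
            if t not in (self.baseline_treatment, self.combined_treatment)
        ]

    @property
    def n_samples(self) -> int:
        return len(self.cell_types) * len(self.treatments) * self.n_replicates

    @classmethod
    def study_like(cls, **kwargs) -> "SimulationConfig":
        """The study design: n = 2 replicates per condition."""
        kwargs.setdefault("n_replicates", 2)
        return cls(**kwargs)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TruthLabels:
    """Ground truth planted by the generators.

    ``gene_programs`` labels each gene ``background``,
    ``celltype:<ct>``, ``treatment:<ct>:<agent>`` or ``dormant``.
    ``scale_factors`` are the true per-sample library scale factors.
    ``enriched_datasets`` maps a peak dataset name to its target gene
    list (empty mapping entries mean unenriched).
    """

    gene_programs: pd.Series | None = None
    scale_factors: pd.Series | None = None
    enriched_datasets: Mapping[str, list[str]] | None = None

    def genes_in(self, prefix: str) -> list[str]:
        if self.gene_programs is None:
            return []
        mask = self.gene_programs.str.startswith(prefix)
        return list(self.gene_programs.index[mask])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed) % (2**31), stream])
    )


def _assign_programs(config: SimulationConfig) -> pd.Series:
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    labels = pd.Series("background", index=pd.Index(genes, name="gene_id"))
    rng = _rng(config, stream=1)
    order = rng.permutation(config.n_genes)
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        sel = order[cursor:cursor + n]
        cursor += n
        return list(sel)

    for ct in config.cell_types:
        labels.iloc[take(config.n_celltype_genes)] = f"celltype:{ct}"
    for agent in config.single_treatments:
        labels.iloc[take(config.n_shared_treatment_genes)] = (
            f"treatment_shared:{agent}"
        )
    for ct in config.cell_types:
        for agent in config.single_treatments:
            labels.iloc[take(config.n_treatment_genes)] = f"treatment:{ct}:{agent}"
    labels.iloc[take(config.n_dormant_genes)] = "dormant"
    return labels


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for ct in config.cell_types:
        for tr in config.treatments:
            for rep in range(1, config.n_replicates + 1):
                rows.append((f"{ct}_{tr}_r{rep}", ct, tr, rep))
    return pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "treatment", "replicate"]
    ).set_index("sample_id")


def _log2_means(config: SimulationConfig, programs: pd.Series,
                meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene per-sample log2 expected reads-per-kilobase."""
    active_ct = config.cell_types[1]   # constitutively active on dormant genes
    dormant_top = config.dormant_baseline_gap + config.dormant_effect
    log2mu = pd.DataFrame(
        config.base_mean_log2, index=programs.index, columns=meta.index,
        dtype=float,
    )
    for sample, row in meta.iterrows():
        ct, tr = row["cell_type"], row["treatment"]
        bump = pd.Series(0.0, index=programs.index)
        bump[programs == f"celltype:{ct}"] += config.celltype_effect
        if tr != config.baseline_treatment:
            agents = (
                config.single_treatments if tr == config.combined_treatment
                else [tr]
            )
            for agent in agents:
                bump[programs == f"treatment_shared:{agent}"] += config.treatment_effect
                bump[programs == f"treatment:{ct}:{agent}"] += config.treatment_effect
        dormant = programs == "dormant"
        if ct == active_ct:
            bump[dormant] += config.dormant_baseline_gap
        if tr == config.combined_treatment:
            # both cell types converge to base + gap + induction
            bump[dormant] = dormant_top
        log2mu[sample] += bump
    return log2mu


def simulate_expression(
    config: SimulationConfig,
) -> tuple[CountMatrix, TruthLabels]:
    """Draw a negative-binomial count matrix for the configured design.

    The expected count is mu[g, s] = 2**log2mean[g, s] * (len_g / 1e3)
    * scale_s with variance mu * (1 + dispersion * mu); dispersion 0
    falls back to Poisson. Gene lengths are uniform on [500, 10000] bp.
    Deterministic given ``config.rng_seed``.
    """
    programs = _assign_programs(config)
    meta = _sample_table(config)
    if config.library_scale_factors is None:
        scale = pd.Series(1.0, index=meta.index)
    else:
        scale = pd.Series(list(config.library_scale_factors), index=meta.index)

    rng = _rng(config, stream=2)
    lengths = pd.Series(
        rng.integers(500, 10001, size=config.n_genes),
        index=programs.index, name="length_bp",
    )
    log2mu = _log2_means(config, programs, meta)
    mu = (2.0 ** log2mu).mul(lengths / 1e3, axis=0).mul(scale, axis=1)

    mu_arr = mu.to_numpy()
    if config.nb_dispersion == 0:
        counts = rng.poisson(mu_arr)
    else:
        n = 1.0 / config.nb_dispersion
        p = n / (n + mu_arr)
        counts = rng.negative_binomial(n, p)
    cm = CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=programs.index,
                            columns=meta.index),
        lengths=lengths,
        metadata=meta,
    )
    truth = TruthLabels(gene_programs=programs, scale_factors=scale)
    return cm, truth


def simulate_annotation(config: SimulationConfig) -> PromoterAnnotation:
    """Place one TSS per gene, uniformly, with >= 5 kb clearance from
    chromosome ends; strands are fair coin flips. Deterministic given
    ``config.rng_seed``."""
    clearance = 5000
    if config.chrom_length <= 2 * clearance:
        raise ValueError(
            f"chromosome length {config.chrom_length} too short for "
            f"{clearance} bp end clearance"
        )
    rng = _rng(config, stream=3)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    chroms = [f"chr{1 + i % config.n_chroms}" for i in range(config.n_genes)]
    tss = rng.integers(clearance, config.chrom_length - clearance,
                       size=config.n_genes)
    strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    table = pd.DataFrame(
        {"chrom": chroms, "tss": tss.astype(np.int64), "strand": strand},
        index=pd.Index(genes, name="gene_id"),
    )
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    return PromoterAnnotation(table=table, chrom_sizes=sizes)


def simulate_peak_library(
    annotation: PromoterAnnotation,
    n_datasets: int,
    enriched: Mapping[str, tuple[Sequence[str], float]],
    p_bg: float = 0.1,
    peak_width: int = 200,
    n_decoys: int = 300,
    config: SimulationConfig | None = None,
    rng_seed: int | None = None,
) -> tuple[list[PeakDataset], TruthLabels]:
    """Generate ``n_datasets`` peak datasets over the annotation.

    ``enriched`` maps dataset name -> (target gene ids, p_fg): genes in
    the target set receive a TSS-centered peak with probability p_fg,
    all other genes with probability p_bg; 0 <= p_bg <= p_fg <= 1 for
    each enriched dataset. Decoy peaks (away from any promoter) are
    placed uniformly. Dataset names are ``ds00``, ``ds01``, ... unless
    named in ``enriched``.
    """
    if not 0 <= p_bg <= 1:
        raise ValueError("p_bg must lie in [0, 1]")
    genes = annotation.gene_ids
    for name, (targets, p_fg) in enriched.items():
        missing = set(targets) - set(genes)
        if missing:
            raise ValueError(
                f"dataset {name!r} targets genes absent from the "
                f"annotation: {sorted(missing)[:5]}"
            )
        if not p_bg <= p_fg <= 1:
            raise ValueError(f"dataset {name!r}: need p_bg <= p_fg <= 1")

    seed = rng_seed if rng_seed is not None else (
        config.rng_seed if config is not None else 0
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 4]))

    names = [f"ds{i:02d}" for i in range(n_datasets)]
    enriched_names = list(enriched)
    if len(enriched_names) > n_datasets:
        raise ValueError("more enriched datasets than n_datasets")
    for i, name in enumerate(enriched_names):
        names[i] = name

    tss = annotation.table["tss"].to_numpy()
    chroms = annotation.table["chrom"].to_numpy()
    sizes = annotation.chrom_sizes
    tss_by_chrom = {
        c: np.sort(tss[chroms == c]) for c in sizes
    }

    datasets: list[PeakDataset] = []
    truth_map: dict[str, list[str]] = {}
    half = peak_width // 2
    for name in names:
        targets, p_fg = enriched.get(name, ((), p_bg))
        target_set = set(targets)
        p = np.where(
            np.isin(genes.to_numpy(), list(target_set)), p_fg, p_bg
        )
        hit = rng.random(len(genes)) < p
        rows = []
        for g_idx in np.flatnonzero(hit):
            c = chroms[g_idx]
            start = max(0, int(tss[g_idx]) - half)
            end = min(sizes[c], start + peak_width)
            rows.append((c, start, end))
        # decoys: uniform positions re-drawn until clear of any promoter zone
        chrom_names = list(sizes)
        for _ in range(n_decoys):
            while True:
                c = chrom_names[rng.integers(0, len(chrom_names))]
                pos = int(rng.integers(0, sizes[c] - peak_width))
                near = tss_by_chrom[c]
                j = np.searchsorted(near, pos)
                lo = near[j - 1] if j > 0 else -np.inf
                hi = near[j] if j < len(near) else np.inf
                if pos - lo > 3000 + peak_width and hi - pos > 3000 + peak_width:
                    break
            rows.append((c, pos, pos + peak_width))
        datasets.append(PeakDataset.from_intervals(name, rows))
        truth_map[name] = sorted(target_set)
    return datasets, TruthLabels(enriched_datasets=truth_map)
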