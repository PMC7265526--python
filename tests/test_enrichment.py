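import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import seqconverge as sc
from seqconverge.containers import PeakDataset, PromoterAnnotation
from seqconverge.enrichment import (
    DEFAULT_WINDOWS,
    NullDistribution,
    PromoterWindowDef,
    observed_overlap,
    promoter_windows,
    sample_null,
    z_p_from_null,
)


def _annotation(records, chrom_sizes=None):
    table = pd.DataFrame(
        records, columns=["gene_id", "chrom", "tss", "strand"]
    ).set_index("gene_id")
    sizes = chrom_sizes or {c: 10**6 for c in table["chrom"].unique()}
    return PromoterAnnotation(table=table, chrom_sizes=sizes)


class TestPromoterWindows:
    def test_plus_strand_window(self):
        ann = _annotation([("g1", "chr1", 10000, "+")])
        w = promoter_windows(["g1"], ann, PromoterWindowDef(1000, 500))
        row = w.iloc[0]
        assert (row["start"], row["end"]) == (9000, 10500)
        assert row["end"] - row["start"] == 1500

    def test_minus_strand_is_mirror_image(self):
        ann = _annotation([("g1", "chr1", 10000, "-")])
        w = promoter_windows(["g1"], ann, PromoterWindowDef(1000, 500))
        row = w.iloc[0]
        assert (row["start"], row["end"]) == (9501, 11001)
        assert row["end"] - row["start"] == 1500

    def test_clamped_at_chromosome_start(self):
        ann = _annotation([("g1", "chr1", 300, "+")])
        w = promoter_windows(["g1"], ann, PromoterWindowDef(2000, 1))
        row = w.iloc[0]
        assert (row["start"], row["end"]) == (0, 301)

    def test_unknown_gene_named_in_error(self):
        ann = _annotation([("g1", "chr1", 300, "+")])
        with pytest.raises(KeyError, match="ghost"):
            promoter_windows(["ghost"], ann, PromoterWindowDef(100, 100))

    def test_default_windows_match_standard_definitions(self):
        assert [(w.upstream, w.downstream) for w in DEFAULT_WINDOWS] == [
            (1000, 500), (1000, 1000), (2000, 1)]


def brute_force_overlap(regions: pd.DataFrame, peaks: PeakDataset) -> int:
    """All-pairs overlap count; independent of the searchsorted path."""
    n = 0
    peak_rows = list(peaks.intervals.itertuples(index=False))
    for r in regions.itertuples(index=False):
        for p in peak_rows:
            if (r.chrom == p.chrom and max(r.start, p.start)
                    < min(r.end, p.end)):
                n += 1
                break
    return n


class TestObservedOverlap:
    def _regions(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_empty_peaks_give_zero(self):
        regions = self._regions([("chr1", 0, 10)])
        assert observed_overlap(regions, PeakDataset.from_intervals("e", [])) == 0

    def test_single_shared_base_counts(self):
        regions = self._regions([("chr1", 100, 200)])
        peaks = PeakDataset.from_intervals("p", [("chr1", 199, 300)])
        assert observed_overlap(regions, peaks) == 1

    def test_touching_half_open_intervals_do_not_overlap(self):
        regions = self._regions([("chr1", 0, 10)])
        peaks = PeakDataset.from_intervals("p", [("chr1", 10, 20)])
        assert observed_overlap(regions, peaks) == 0

    def test_region_overlapping_many_peaks_counts_once(self):
        regions = self._regions([("chr1", 0, 1000)])
        peaks = PeakDataset.from_intervals(
            "p", [("chr1", i, i + 10) for i in range(0, 900, 50)])
        assert observed_overlap(regions, peaks) == 1

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        chroms = ["chr1", "chr2"]
        regions = pd.DataFrame({
            "chrom": rng.choice(chroms, 60),
            "start": (s := rng.integers(0, 5000, 60)),
            "end": s + rng.integers(1, 400, 60),
        })
        ps = rng.integers(0, 5000, 150)
        peaks = PeakDataset.from_intervals("r", [
            (c, int(a), int(a + w)) for c, a, w in
            zip(rng.choice(chroms, 150), ps, rng.integers(1, 300, 150))
        ])
        assert observed_overlap(regions, peaks) == brute_force_overlap(
            regions, peaks)


class TestSampleNull:
    def _setup(self, n_genes=120, peak_every=None, seed=0):
        rng = np.random.default_rng(seed)
        recs = [(f"g{i}", "chr1", 10000 + 5000 * i,
                 "+" if rng.random() < 0.5 else "-")
                for i in range(n_genes)]
        ann = _annotation(recs, {"chr1": 10**7})
        universe = promoter_windows(ann.gene_ids, ann, PromoterWindowDef(500, 500))
        return ann, universe

    def test_peaks_covering_every_promoter_force_input_size(self):
        ann, universe = self._setup()
        peaks = PeakDataset.from_intervals(
            "all", [("chr1", 0, 10**7)])
        null = sample_null(30, universe, peaks, n_iter=50, rng_seed=1)
        assert (null.samples == 30).all() and null.sd == 0.0

    def test_no_peaks_give_constant_zero(self):
        ann, universe = self._setup()
        peaks = PeakDataset.from_intervals("none", [])
        null = sample_null(30, universe, peaks, n_iter=50, rng_seed=1)
        assert (null.samples == 0).all() and null.sd == 0.0

    def test_mean_matches_hit_rate_expectation(self):
        # peaks on ~10% of promoters: null mean ~ 0.1 * input size
        ann, universe = self._setup(seed=3)
        rng = np.random.default_rng(3)
        hit_genes = universe.sample(frac=0.1, random_state=5)
        peaks = PeakDataset.from_intervals("ten", [
            (r.chrom, (r.start + r.end) // 2, (r.start + r.end) // 2 + 10)
            for r in hit_genes.itertuples(index=False)])
        k = 40
        true_rate = len(hit_genes) / len(universe)
        null = sample_null(k, universe, peaks, n_iter=2000, rng_seed=7)
        se = np.sqrt(k * true_rate * (1 - true_rate)) / np.sqrt(2000)
        assert abs(null.mean - true_rate * k) < 4 * se

    def test_oversized_input_rejected(self):
        ann, universe = self._setup()
        peaks = PeakDataset.from_intervals("none", [])
        with pytest.raises(ValueError, match="exceeds"):
            sample_null(len(universe) + 1, universe, peaks, n_iter=10)

    def test_seeded_determinism(self):
        ann, universe = self._setup()
        peaks = PeakDataset.from_intervals("one", [("chr1", 0, 300000)])
        a = sample_null(20, universe, peaks, n_iter=100, rng_seed=9)
        b = sample_null(20, universe, peaks, n_iter=100, rng_seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestZP:
    def _null(self, samples):
        return NullDistribution(samples=np.asarray(samples),
                                n_iter=len(samples), rng_seed=0)

    def test_observed_at_mean_is_zero_z(self):
        null = self._null([9, 10, 11, 10])
        z, p, deg = z_p_from_null(10, null)
        assert z == 0.0 and p == 0.5 and not deg

    def test_three_sigma_upper_tail(self):
        # mean 10, sd 2, observed 16 -> z = 3, p ~ 1.35e-3
        samples = np.array([8, 12] * 1000)
        null = NullDistribution(samples=samples, n_iter=2000, rng_seed=0)
        sd = samples.std(ddof=1)
        obs = 10 + 3 * sd
        z, p, _ = z_p_from_null(obs, null)
        assert z == pytest.approx(3.0)
        assert p == pytest.approx(1.3499e-3, rel=1e-3)
        assert p == pytest.approx(stats.norm.sf(3))

    def test_p_strictly_decreasing_in_observed(self):
        null = self._null([5, 8, 10, 12, 15])
        ps = [z_p_from_null(o, null).p for o in range(0, 20)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_degenerate_null_conventions(self):
        null = self._null([7, 7, 7, 7])
        assert z_p_from_null(7, null) == (0.0, 0.5, True)
        z, p, deg = z_p_from_null(9, null)
        assert z == np.inf and p == 1e-300 and deg
        z, p, deg = z_p_from_null(5, null)
        assert z == -np.inf and p == 1.0 and deg


class TestStrandSymmetry:
    def test_flipping_strands_and_mirroring_peaks_preserves_overlap(self):
        rng = np.random.default_rng(11)
        n = 60
        # TSSs spaced so one gene's peak cannot touch another's window:
        # the per-gene reflection argument needs non-interacting genes
        tss_pos = 20000 + 12000 * np.arange(n) + rng.integers(-1000, 1000, n)
        recs = [(f"g{i}", "chr1", int(t), "+" if rng.random() < 0.5 else "-")
                for i, t in enumerate(tss_pos)]
        ann = _annotation(recs, {"chr1": 10**6})
        # one peak at a random offset near each TSS
        offs = rng.integers(-1500, 1500, n)
        widths = rng.integers(50, 400, n)
        peaks = PeakDataset.from_intervals("p", [
            ("chr1", int(t + o), int(t + o + w))
            for (_, _, t, _), o, w in zip(recs, offs, widths)])
        # mirror: strand flip plus reflection of each gene's peak about
        # its TSS (position x -> 2t - x maps [s, e) to [2t-e+1, 2t-s+1))
        flipped = [(g, c, t, "-" if s == "+" else "+") for g, c, t, s in recs]
        ann_f = _annotation(flipped, {"chr1": 10**6})
        peaks_f = PeakDataset.from_intervals("pf", [
            ("chr1", int(2 * t - (t + o + w) + 1), int(2 * t - (t + o) + 1))
            for (_, _, t, _), o, w in zip(recs, offs, widths)])
        for w in DEFAULT_WINDOWS:
            wins = promoter_windows(ann.gene_ids, ann, w)
            wins_f = promoter_windows(ann_f.gene_ids, ann_f, w)
            assert observed_overlap(wins, peaks) == observed_overlap(
                wins_f, peaks_f)


@pytest.fixture(scope="module")
def setting():
    cfg = sc.SimulationConfig(n_genes=300, rng_seed=13,
                              n_celltype_genes=0,
                              n_shared_treatment_genes=0,
                              n_treatment_genes=0, n_dormant_genes=0,
                              dormant_baseline_gap=0.0)
    ann = sc.simulate_annotation(cfg)
    targets = list(ann.gene_ids[:50])
    peaks, truth = sc.simulate_peak_library(
        ann, n_datasets=6, enriched={"planted": (targets, 0.9)},
        p_bg=0.1, rng_seed=13)
    return ann, targets, peaks


class TestEnrichLibrary:
    def test_single_dataset_q_equals_p(self, setting):
        ann, targets, peaks = setting
        res = sc.enrich_library(targets, ann, peaks[:1],
                                windows=DEFAULT_WINDOWS[:1], n_iter=200, seed=1)
        np.testing.assert_allclose(res.table["q"], res.table["p"])

    def test_identical_seed_reproduces_table(self, setting):
        ann, targets, peaks = setting
        a = sc.enrich_library(targets, ann, peaks, n_iter=200, seed=5)
        b = sc.enrich_library(targets, ann, peaks, n_iter=200, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_library_order_does_not_change_per_dataset_results(self, setting):
        ann, targets, peaks = setting
        a = sc.enrich_library(targets, ann, peaks,
                              windows=DEFAULT_WINDOWS[:1], n_iter=200, seed=5)
        b = sc.enrich_library(targets, ann, peaks[::-1],
                              windows=DEFAULT_WINDOWS[:1], n_iter=200, seed=5)
        at = a.table.set_index("dataset")
        bt = b.table.set_index("dataset")
        pd.testing.assert_frame_equal(at, bt.loc[at.index])

    def test_planted_dataset_ranks_first(self, setting):
        ann, targets, peaks = setting
        res = sc.enrich_library(targets, ann, peaks, n_iter=2000, seed=2)
        for w in res.table["window"].unique():
            sub = res.table[res.table["window"] == w]
            assert sub.iloc[0]["dataset"] == "planted"
            assert sub.iloc[0]["z"] > 3

    def test_z_sign_agrees_across_window_definitions(self, setting):
        # promoter-centered peaks: enrichment direction should not depend
        # on the window choice for the vast majority of datasets
        ann, targets, peaks = setting
        res = sc.enrich_library(targets, ann, peaks, n_iter=500, seed=3)
        signs = res.table.pivot(index="dataset", columns="window", values="z")
        agree = (np.sign(signs).nunique(axis=1) == 1).mean()
        assert agree >= 0.8

    def test_two_sided_tail_doubles_p(self, setting):
        ann, targets, peaks = setting
        one = sc.enrich_library(targets, ann, peaks[:2],
                                windows=DEFAULT_WINDOWS[:1], n_iter=200,
                                seed=4, tail="one")
        two = sc.enrich_library(targets, ann, peaks[:2],
                                windows=DEFAULT_WINDOWS[:1], n_iter=200,
                                seed=4, tail="two")
        o = one.table.set_index("dataset")
        t = two.table.set_index("dataset")
        for ds in o.index:
            zo = o.loc[ds, "z"]
            expected = 2 * stats.norm.sf(abs(zo))
            assert t.loc[ds, "p"] == pytest.approx(expected)

    def test_empty_inputs_rejected(self, setting):
        ann, targets, peaks = setting
        with pytest.raises(ValueError):
            sc.enrich_library([], ann, peaks)
        with pytest.raises(ValueError):
            sc.enrich_library(targets, ann, [])
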