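"""Peak normalization, window assignment, binding scores and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subreg.peak_scoring import (
    PeakSet,
    assign_peaks_to_windows,
    binding_enrichment_at_set,
    gene_binding_scores,
    normalize_peak_scores,
    peak_overlap_fraction,
    prioritize_experiments,
)

from conftest import toy_annotation, toy_peaks


class TestNormalization:
    def test_equal_signals_map_to_base_score(self):
        peaks = toy_peaks([("chr1", 0, 100, 7.0)] * 5)
        out = normalize_peak_scores(peaks)
        assert np.allclose(out["signalValue"], 500.0)

    def test_percentile_by_linear_interpolation(self):
        peaks = toy_peaks(
            [("chr1", i * 1000, i * 1000 + 100, s) for i, s in enumerate([10, 20, 30, 40])]
        )
        out = normalize_peak_scores(peaks)
        # q75 of [10,20,30,40] with linear interpolation = 32.5
        assert out["signalValue"].iloc[1] == pytest.approx(20 / 32.5 * 500)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        sig = rng.gamma(2, 5, size=30)
        peaks = toy_peaks([("chr1", i * 500, i * 500 + 100, s) for i, s in enumerate(sig)])
        doubled = peaks.copy()
        doubled["signalValue"] *= 2
        assert np.allclose(
            normalize_peak_scores(peaks)["signalValue"],
            normalize_peak_scores(doubled)["signalValue"],
        )

    def test_all_zero_signals_error(self):
        with pytest.raises(ValueError):
            normalize_peak_scores(toy_peaks([("chr1", 0, 100, 0.0)]))


class TestWindowAssignment:
    def test_single_gene_window(self):
        anno = toy_annotation([100_000, 400_000])
        peaks = toy_peaks([("chr1", 90_000, 90_200, 1.0)])
        hits = assign_peaks_to_windows(peaks, anno)
        assert len(hits[0]) == 1

    def test_shared_window_counts_two(self):
        anno = toy_annotation([100_000, 140_000])
        peaks = toy_peaks([("chr1", 119_000, 119_200, 1.0)])
        hits = assign_peaks_to_windows(peaks, anno)
        assert len(hits[0]) == 2

    def test_peak_outside_all_windows(self):
        anno = toy_annotation([100_000])
        peaks = toy_peaks([("chr1", 500_000, 500_200, 1.0)])
        hits = assign_peaks_to_windows(peaks, anno)
        assert len(hits[0]) == 0

    def test_chromosome_mismatch_raises(self):
        anno = toy_annotation([100_000])
        peaks = toy_peaks([("chrX", 0, 100, 1.0)])
        with pytest.raises(ValueError, match="chrX"):
            assign_peaks_to_windows(peaks, anno)


class TestGeneScores:
    def test_formula_fixture(self):
        # peaks with normalized scores 500 (1 gene) and 300 (2 genes):
        # first gene's score = 500 + 300/2 = 650
        anno = toy_annotation([100_000, 140_000])
        peaks = toy_peaks(
            [
                ("chr1", 60_000, 60_100, 500.0),  # only gene 0's window
                ("chr1", 119_000, 119_100, 300.0),  # shared by both
            ]
        )
        g = gene_binding_scores(peaks, anno, normalize=False)
        assert g["g0"] == pytest.approx(650.0)
        assert g["g1"] == pytest.approx(150.0)

    def test_no_peaks_all_zero(self):
        anno = toy_annotation([100_000, 200_000])
        g = gene_binding_scores(toy_peaks([]), anno, normalize=False)
        assert (g == 0).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        tss = np.sort(rng.choice(2_000_000, size=20, replace=False))
        anno = toy_annotation(list(tss))
        starts = rng.integers(0, 2_000_000, size=50)
        peaks = toy_peaks(
            [("chr1", int(s), int(s) + 200, float(v)) for s, v in zip(starts, rng.gamma(2, 5, 50))]
        )
        g = gene_binding_scores(peaks, anno, normalize=False)
        # O(G x F) double loop oracle
        w = 50_000
        expected = np.zeros(len(anno))
        nf = np.zeros(len(peaks))
        for f, prow in peaks.iterrows():
            for i, arow in anno.reset_index(drop=True).iterrows():
                if prow["start"] < arow["tss"] + w and prow["end"] > arow["tss"] - w:
                    nf[f] += 1
        for f, prow in peaks.iterrows():
            if nf[f] == 0:
                continue
            for i, arow in anno.reset_index(drop=True).iterrows():
                if prow["start"] < arow["tss"] + w and prow["end"] > arow["tss"] - w:
                    expected[i] += prow["signalValue"] / nf[f]
        assert np.allclose(g.to_numpy(), expected)

    def test_mass_conservation(self):
        rng = np.random.default_rng(4)
        tss = np.sort(rng.choice(1_000_000, size=15, replace=False))
        anno = toy_annotation(list(tss))
        peaks = toy_peaks(
            [
                ("chr1", int(s), int(s) + 300, float(v))
                for s, v in zip(rng.integers(0, 1_000_000, 40), rng.gamma(2, 5, 40))
            ]
        )
        g = gene_binding_scores(peaks, anno, normalize=True)
        hits = assign_peaks_to_windows(peaks, anno)
        normed = normalize_peak_scores(peaks)["signalValue"].to_numpy()
        covered = sum(normed[f] for f in range(len(peaks)) if len(hits[f]) >= 1)
        assert g.sum() == pytest.approx(covered)

    def test_adding_peak_never_decreases_scores(self):
        anno = toy_annotation([100_000, 300_000])
        base = toy_peaks([("chr1", 90_000, 90_100, 10.0)])
        more = toy_peaks(
            [("chr1", 90_000, 90_100, 10.0), ("chr1", 310_000, 310_100, 5.0)]
        )
        g0 = gene_binding_scores(base, anno, normalize=False)
        g1 = gene_binding_scores(more, anno, normalize=False)
        assert (g1 >= g0 - 1e-12).all()


class TestEnrichment:
    def test_top_set_minimal_p(self):
        scores = pd.Series(np.arange(100, 0, -1, dtype=float), index=[f"g{i}" for i in range(100)])
        top = [f"g{i}" for i in range(10)]
        p, _ = binding_enrichment_at_set(scores, top, n_random=999, rng=1)
        assert p == pytest.approx(1 / 1000)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(9)
        scores = pd.Series(rng.gamma(2, 5, 300), index=[f"g{i}" for i in range(300)])
        ps = []
        for rep in range(200):
            gene_set = [f"g{i}" for i in rng.choice(300, 15, replace=False)]
            p, _ = binding_enrichment_at_set(scores, gene_set, n_random=199, rng=rep)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_deterministic_under_seed(self):
        scores = pd.Series(
            np.random.default_rng(0).gamma(2, 5, 50), index=[f"g{i}" for i in range(50)]
        )
        s = [f"g{i}" for i in range(5)]
        p1, _ = binding_enrichment_at_set(scores, s, n_random=100, rng=42)
        p2, _ = binding_enrichment_at_set(scores, s, n_random=100, rng=42)
        assert p1 == p2


class TestPrioritization:
    def test_excluded_factor_absent(self, tiny_model, tiny_annotation):
        from subreg.synthetic_data import generate_chipseq

        reg = tiny_model.regulators_per_subtype["basal"][0]
        exps = [
            generate_chipseq(tiny_model, tiny_annotation, reg, n_background_peaks=200),
            generate_chipseq(
                tiny_model, tiny_annotation, "CTCF", decoy=True, n_background_peaks=200
            ),
            generate_chipseq(
                tiny_model, tiny_annotation, "H3K27ac", decoy=True, n_background_peaks=200
            ),
        ]
        esg = {"basal": set(tiny_model.module_genes("basal"))}
        table, summary = prioritize_experiments(
            exps, esg, tiny_annotation, n_random=100, rng=0
        )
        assert set(table["factor"]) == {reg}


class TestOverlapFraction:
    def _peaks(self, coords):
        return toy_peaks([(c, s, e, 1.0) for c, s, e in coords])

    def test_self_overlap_is_one(self):
        ref = self._peaks([("chr1", 0, 100), ("chr1", 500, 600)])
        assert peak_overlap_fraction(ref, [ref]) == 1.0

    def test_disjoint_is_zero(self):
        ref = self._peaks([("chr1", 0, 100)])
        q = self._peaks([("chr1", 200, 300)])
        assert peak_overlap_fraction(ref, [q]) == 0.0

    def test_partial_fraction(self):
        ref = self._peaks([("chr1", i * 1000, i * 1000 + 100) for i in range(10)])
        q = self._peaks([("chr1", i * 1000 + 50, i * 1000 + 150) for i in range(4)])
        assert peak_overlap_fraction(ref, [q]) == pytest.approx(0.4)
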