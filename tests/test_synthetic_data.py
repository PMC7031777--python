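"""Contracts and planted-effect checks for the synthetic cohort generators."""

import numpy as np
import pandas as pd
import pytest

from subreg.deregulation import gene_level_methylation
from subreg.synthetic_data import (
    ConfigurationError,
    PlantedModel,
    build_truth,
    generate_annotation,
    generate_chipseq,
    generate_cna,
    generate_expression_compendium,
    generate_genome_fasta,
    generate_methylation,
    generate_open_chromatin,
    planted_cna_genes,
    planted_methylation_genes,
)


class TestPlantedModel:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            PlantedModel(n_genes=5)
        with pytest.raises(ConfigurationError):
            PlantedModel(n_genes=100, n_tfs=200)

    def test_regulators_must_be_tfs(self):
        m = PlantedModel(n_genes=100, n_tfs=10, seed=0)
        non_tf = next(g for g in m.gene_ids if g not in set(m.tf_ids))
        with pytest.raises(ConfigurationError, match="TF"):
            PlantedModel(
                n_genes=100,
                n_tfs=10,
                regulators_per_subtype={"lumA": [non_tf]},
                seed=0,
            )

    def test_targets_cannot_cross_subtypes(self):
        m = PlantedModel(n_genes=100, n_tfs=50, seed=0)
        tfs = m.tf_ids
        with pytest.raises(ConfigurationError, match="planted in both"):
            PlantedModel(
                n_genes=100,
                n_tfs=50,
                regulators_per_subtype={"lumA": [tfs[0]], "basal": [tfs[1]]},
                targets_per_regulator={tfs[0]: ["G00001"], tfs[1]: ["G00001"]},
                seed=0,
            )


class TestAnnotation:
    def test_contract(self, tiny_model, tiny_annotation):
        anno = tiny_annotation
        assert len(anno) == tiny_model.n_genes
        assert anno["gene_id"].is_unique
        assert (anno["start"] < anno["end"]).all()
        assert ((anno["start"] <= anno["tss"]) & (anno["tss"] <= anno["end"])).all()
        plus = anno["strand"] == "+"
        assert (anno.loc[plus, "tss"] == anno.loc[plus, "start"]).all()
        assert (anno.loc[~plus, "tss"] == anno.loc[~plus, "end"]).all()

    def test_deterministic_under_seed(self, tiny_model):
        a1 = generate_annotation(tiny_model)
        a2 = generate_annotation(tiny_model)
        pd.testing.assert_frame_equal(a1, a2)

    def test_tight_spacing_makes_windows_overlap(self, tiny_model):
        anno = generate_annotation(tiny_model, n_chromosomes=1, spacing_mean=10_000)
        tss = np.sort(anno["tss"].to_numpy())
        gaps = np.diff(tss)
        assert (gaps < 100_000).mean() > 0.5  # adjacent +/-50 kb windows overlap

    def test_min_spacing_separates_windows(self, tiny_model):
        anno = generate_annotation(
            tiny_model, n_chromosomes=1, min_spacing=120_000
        )
        for _, grp in anno.groupby("chrom"):
            tss = np.sort(grp["tss"].to_numpy())
            assert (np.diff(tss) >= 100_000).all()


class TestExpression:
    def test_null_modules_uncorrelated(self):
        model = PlantedModel.random(
            n_genes=400,
            n_tfs=80,
            n_targets_per_regulator=20,
            seed=2,
            expression_effect=0.0,
            coexpression_loading=0.0,
        )
        (X, labels), = generate_expression_compendium(model, 1, 50)
        mod = model.module_genes("basal")
        C = np.corrcoef(X.loc[mod].to_numpy())
        iu = np.triu_indices_from(C, 1)
        assert abs(C[iu].mean()) < 0.1

    def test_one_factor_closed_form_correlation(self):
        # expected within-module r = l^2 / (l^2 + sd^2) = 0.49/1.49 = 0.329
        model = PlantedModel.random(
            n_genes=500, n_tfs=100, seed=3, expression_effect=0.0
        )
        (X, _), = generate_expression_compendium(model, 1, 60)
        mod = model.module_genes("basal")
        C = np.corrcoef(X.loc[mod].to_numpy())
        iu = np.triu_indices_from(C, 1)
        assert C[iu].mean() == pytest.approx(0.49 / 1.49, abs=0.05)

    def test_subtype_mean_shift(self):
        model = PlantedModel.random(
            n_genes=400, n_tfs=80, n_targets_per_regulator=20, seed=4
        )
        (X, labels), = generate_expression_compendium(model, 1, 60)
        mod = model.module_genes("basal")
        in_b = labels.index[labels == "basal"]
        in_l = labels.index[labels == "lumA"]
        diff = X.loc[mod, in_b].mean(axis=1) - X.loc[mod, in_l].mean(axis=1)
        # per-dataset scale jitter multiplies the planted effect of 1.0
        assert 0.6 < diff.mean() < 1.4

    def test_too_few_samples(self, tiny_model):
        with pytest.raises(ConfigurationError):
            generate_expression_compendium(tiny_model, 1, 4)


class TestChipseq:
    @staticmethod
    def _target_window_fraction(peaks, anno, targets, window=50_000):
        ta = anno.loc[[t for t in targets if t in anno.index]]
        n = 0
        for _, r in peaks.iterrows():
            sel = (
                (ta["chrom"] == r["chrom"])
                & (ta["tss"] - window < r["end"])
                & (ta["tss"] + window > r["start"])
            )
            n += bool(sel.any())
        return n / len(peaks)

    def test_null_enrichment_density(self, tiny_annotation):
        model = PlantedModel.random(
            n_genes=300,
            n_tfs=60,
            n_regulators_per_subtype=2,
            n_targets_per_regulator=8,
            seed=7,
            binding_enrichment=1.0,
        )
        reg = model.regulators_per_subtype["basal"][0]
        ps = generate_chipseq(model, tiny_annotation, reg, n_background_peaks=800)
        decoy = generate_chipseq(
            model, tiny_annotation, "DEC", decoy=True, n_background_peaks=800
        )
        targets = model.targets_per_regulator[reg]
        f_fg = self._target_window_fraction(ps.peaks, tiny_annotation, targets)
        f_bg = self._target_window_fraction(decoy.peaks, tiny_annotation, targets)
        assert f_fg == pytest.approx(f_bg, abs=0.08)

    def test_planted_enrichment_exceeds_background(self, tiny_model, tiny_annotation):
        reg = tiny_model.regulators_per_subtype["basal"][0]
        ps = generate_chipseq(tiny_model, tiny_annotation, reg, n_background_peaks=800)
        decoy = generate_chipseq(
            tiny_model, tiny_annotation, "DEC", decoy=True, n_background_peaks=800
        )
        targets = tiny_model.targets_per_regulator[reg]
        f_fg = self._target_window_fraction(ps.peaks, tiny_annotation, targets)
        f_bg = self._target_window_fraction(decoy.peaks, tiny_annotation, targets)
        assert f_fg >= 3 * f_bg

    def test_valid_narrowpeak_columns(self, tiny_model, tiny_annotation, tmp_path):
        from subreg import io as sio

        reg = tiny_model.regulators_per_subtype["lumA"][0]
        ps = generate_chipseq(tiny_model, tiny_annotation, reg, n_background_peaks=100)
        sio.write_narrowpeak(ps.peaks, tmp_path / "a.narrowPeak")
        back = sio.read_narrowpeak(tmp_path / "a.narrowPeak")
        assert len(back) == len(ps.peaks)
        assert (back["pValue"] == -1).all()

    def test_unknown_factor_rejected(self, tiny_model, tiny_annotation):
        with pytest.raises(ConfigurationError):
            generate_chipseq(tiny_model, tiny_annotation, "NOSUCH")


class TestCNA:
    def test_null_level(self, tiny_model, tiny_annotation):
        segs, labels = generate_cna(
            tiny_model, tiny_annotation, n_samples_per_subtype=20, gain_level=0.0
        )
        from subreg.deregulation import cna_sample_matrix

        g, l = cna_sample_matrix(segs, tiny_annotation)
        total = (g + l).mean(axis=1)
        assert np.abs(total).max() < 3 * 0.05 / np.sqrt(20) + 0.05

    def test_planted_level_recovered(self, tiny_model, tiny_annotation):
        segs, labels = generate_cna(
            tiny_model, tiny_annotation, n_samples_per_subtype=20, gain_level=0.5
        )
        planted = planted_cna_genes(tiny_model)
        reg = tiny_model.regulators_per_subtype["basal"][0]
        basal = labels.index[labels == "basal"]
        luma = labels.index[labels == "lumA"]
        seg_b = segs[segs["sample"].isin(basal)]
        # the segment covering the regulator carries the planted level
        anno = tiny_annotation.loc[reg]
        mid = (anno["start"] + anno["end"]) // 2
        cover = seg_b[
            (seg_b["chrom"] == anno["chrom"])
            & (seg_b["start"] <= mid)
            & (seg_b["end"] > mid)
        ]
        assert abs(cover["log_ratio"].mean()) == pytest.approx(0.5, abs=0.1)
        seg_l = segs[segs["sample"].isin(luma)]
        cover_l = seg_l[
            (seg_l["chrom"] == anno["chrom"])
            & (seg_l["start"] <= mid)
            & (seg_l["end"] > mid)
        ]
        assert abs(cover_l["log_ratio"].mean()) < 0.1

    def test_values_clipped(self, tiny_model, tiny_annotation):
        segs, _ = generate_cna(
            tiny_model, tiny_annotation, n_samples_per_subtype=5, gain_level=1.5
        )
        assert segs["log_ratio"].between(-1, 1).all()


class TestMethylation:
    def test_null_type_one_rate(self, tiny_annotation):
        from subreg.deregulation import methylation_calls

        model = PlantedModel.random(
            n_genes=300, n_tfs=60, n_regulators_per_subtype=2,
            n_targets_per_regulator=8, seed=7,
        )
        cpg, labels = generate_methylation(
            model, tiny_annotation, n_tumor_per_subtype=25, n_normal=25, delta_beta=0.0
        )
        sums = gene_level_methylation(cpg)
        calls = methylation_calls(sums, labels, alpha=0.01)
        rate = (calls["call"] != "none").mean()
        # binomial CI around 1% with 600 tests
        assert rate < 0.03

    def test_planted_gene_level_difference(self, tiny_model, tiny_annotation):
        cpg, labels = generate_methylation(
            tiny_model, tiny_annotation, n_tumor_per_subtype=30, n_normal=30,
            n_cpg_per_gene=5, delta_beta=0.2,
        )
        sums = gene_level_methylation(cpg)
        planted = list(planted_methylation_genes(tiny_model))
        lum = labels.index[labels == "lumA"]
        nor = labels.index[labels == "normal"]
        diff = sums.loc[planted, lum].mean(axis=1) - sums.loc[planted, nor].mean(axis=1)
        assert diff.mean() == pytest.approx(-0.2 * 5, abs=0.15)

    def test_betas_in_unit_interval(self, tiny_model, tiny_annotation):
        cpg, labels = generate_methylation(
            tiny_model, tiny_annotation, n_tumor_per_subtype=5, n_normal=5
        )
        vals = cpg[labels.index].to_numpy()
        assert (vals >= 0).all() and (vals <= 1).all()


class TestOpenChromatinAndFasta:
    def test_null_no_lineage_preference(self, tiny_model, tiny_annotation):
        from subreg.peak_scoring import gene_binding_scores

        oc, truth = generate_open_chromatin(
            tiny_model, tiny_annotation, enrichment=1.0
        )
        genes = sorted(truth)
        acc = pd.DataFrame(
            {
                cl: gene_binding_scores(ps.peaks, tiny_annotation, window=2000).reindex(genes)
                for cl, ps in oc.items()
            }
        )
        ratios = acc.mean(axis=0) / acc.mean(axis=0).mean()
        assert np.allclose(ratios, 1.0, atol=0.35)

    def test_consensus_planted_fraction(self):
        model = PlantedModel.random(
            n_genes=50, n_tfs=10, n_regulators_per_subtype=2,
            n_targets_per_regulator=5, seed=5,
        )
        anno = generate_annotation(model, n_chromosomes=2, spacing_mean=5_000)
        reg = model.regulators_per_subtype["basal"][0]
        ps = generate_chipseq(model, anno, reg, n_background_peaks=100)
        genome = generate_genome_fasta(
            model, anno, planted_peaks=ps.peaks,
            motif_consensus="TGACTCAG", planted_fraction=0.5,
        )
        hits = sum(
            "TGACTCAG" in genome[r["chrom"]][r["start"] : r["end"]]
            for _, r in ps.peaks.iterrows()
        )
        assert hits / len(ps.peaks) == pytest.approx(0.5, abs=0.05)

    def test_peaks_within_genome_bounds(self):
        model = PlantedModel.random(
            n_genes=50, n_tfs=10, n_regulators_per_subtype=2,
            n_targets_per_regulator=5, seed=5,
        )
        anno = generate_annotation(model, n_chromosomes=2, spacing_mean=5_000)
        genome = generate_genome_fasta(model, anno)
        oc, _ = generate_open_chromatin(model, anno, n_background_peaks=100)
        for ps in oc.values():
            for _, r in ps.peaks.iterrows():
                assert r["end"] <= len(genome[r["chrom"]])


class TestTruth:
    def test_truth_records_all_planted_structure(self, tiny_model):
        truth = build_truth(tiny_model)
        assert set(truth["regulators_per_subtype"]) == {"lumA", "basal"}
        assert truth["cna_subtype"] == "basal"
        assert truth["dname_subtype"] == "lumA"
        for r in truth["regulators_per_subtype"]["basal"]:
            assert r in truth["tf_ids"]
            assert truth["targets_per_regulator"][r]
        assert set(truth["cna_planted"]) >= set(
            truth["regulators_per_subtype"]["basal"]
        )
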