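"""CNA/methylation gene-level scoring and deregulation enrichment."""

import numpy as np
import pandas as pd
import pytest

from subreg.deregulation import (
    cna_sample_matrix,
    cna_subtype_association,
    combined_cna_magnitude,
    deregulation_enrichment,
    deregulation_report,
    gene_level_cna,
    gene_level_methylation,
    methylation_calls,
    methylation_magnitude,
)
from subreg.synthetic_data import (
    PlantedModel,
    generate_annotation,
    generate_cna,
    generate_methylation,
    planted_cna_genes,
    planted_methylation_genes,
)

from conftest import toy_annotation


def seg_table(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "log_ratio"])


class TestGeneLevelCNA:
    def test_single_gained_segment(self):
        # 5 genes inside one gained segment of 0.5 -> each gains 0.1
        anno = toy_annotation([10_000 * i for i in range(1, 6)])
        segs = seg_table([("s1", "chr1", 0, 100_000, 0.5)])
        out = gene_level_cna(segs, anno)
        assert np.allclose(out["gain"], 0.1)
        assert np.allclose(out["loss"], 0.0)

    def test_gain_and_loss_segments_any_overlap(self):
        # gene overlapping a gained segment (len 2) and a lost one (len 3)
        anno = toy_annotation([1_000, 5_000, 9_000, 12_000])
        anno.loc["g1", "end"] = 11_000  # g1 spans the breakpoint at 8_000
        segs = seg_table(
            [("s1", "chr1", 0, 8_000, 0.4), ("s1", "chr1", 8_000, 20_000, -0.3)]
        )
        out = gene_level_cna(segs, anno, mode="any")
        assert out.loc["g1", "gain"] == pytest.approx(0.4 / 2)
        assert out.loc["g1", "loss"] == pytest.approx(-0.3 / 3)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(21)
        for rep in range(20):
            tss = np.sort(rng.choice(500_000, size=12, replace=False))
            anno = toy_annotation(list(tss))
            bounds = np.sort(rng.choice(600_000, size=6, replace=False))
            segs = seg_table(
                [
                    ("s", "chr1", int(bounds[i]), int(bounds[i + 1]), float(v))
                    for i, v in zip(range(5), rng.uniform(-1, 1, 5))
                ]
            )
            out = gene_level_cna(segs, anno)
            mids = ((anno["start"] + anno["end"]) // 2).to_numpy()
            exp_gain = np.zeros(len(anno))
            exp_loss = np.zeros(len(anno))
            for _, s in segs.iterrows():
                inside = (mids >= s["start"]) & (mids < s["end"])
                ln = inside.sum()
                if ln == 0:
                    continue
                contrib = s["log_ratio"] / ln
                if contrib > 0:
                    exp_gain[inside] += contrib
                else:
                    exp_loss[inside] += contrib
            assert np.allclose(out["gain"], exp_gain)
            assert np.allclose(out["loss"], exp_loss)

    def test_conservation_gain_plus_loss(self):
        rng = np.random.default_rng(22)
        tss = np.sort(rng.choice(300_000, size=10, replace=False))
        anno = toy_annotation(list(tss))
        bounds = np.sort(rng.choice(400_000, size=5, replace=False))
        segs = seg_table(
            [
                ("s", "chr1", int(bounds[i]), int(bounds[i + 1]), float(v))
                for i, v in zip(range(4), rng.uniform(-1, 1, 4))
            ]
        )
        out = gene_level_cna(segs, anno)
        mids = ((anno["start"] + anno["end"]) // 2).to_numpy()
        signed = np.zeros(len(anno))
        for _, s in segs.iterrows():
            inside = (mids >= s["start"]) & (mids < s["end"])
            if inside.sum():
                signed[inside] += s["log_ratio"] / inside.sum()
        assert np.allclose(out["gain"] + out["loss"], signed)


class TestSubtypeAssociation:
    def test_planted_recovery_and_specificity(self, tiny_model, tiny_annotation):
        segs, labels = generate_cna(
            tiny_model, tiny_annotation, n_samples_per_subtype=25, gain_level=0.5
        )
        g, l = cna_sample_matrix(segs, tiny_annotation)
        assoc = cna_subtype_association(g, l, labels)
        planted = planted_cna_genes(tiny_model)
        gained = [x for x, s in planted.items() if s > 0]
        basal = assoc[assoc["subtype"] == "basal"].set_index("gene_id")
        luma = assoc[assoc["subtype"] == "lumA"].set_index("gene_id")
        # planted genes sharing a segment with an opposite-signed planted
        # gene can have diluted signal, so require bulk recovery
        assert (basal.loc[gained, "p_gain"] < 0.01).mean() >= 0.8
        assert (luma.loc[gained, "mean_gain"].abs() < 0.05).all()

    def test_all_zero_scores_give_p_one(self):
        g = pd.DataFrame(np.zeros((4, 6)), index=list("abcd"))
        labels = pd.Series(["x"] * 6, index=g.columns)
        assoc = cna_subtype_association(g, g, labels)
        assert (assoc["p_gain"] == 1.0).all()

    def test_null_type_one_rate_on_net_value(self, tiny_model, tiny_annotation):
        # gain alone is censored at zero (anti-conservative vs 0); the
        # signed net value is symmetric under the null and stays at ~alpha
        segs, labels = generate_cna(
            tiny_model, tiny_annotation, n_samples_per_subtype=25, gain_level=0.0
        )
        g, l = cna_sample_matrix(segs, tiny_annotation)
        assoc = cna_subtype_association(g, l, labels)
        rate = (assoc["p_net"] < 0.05).mean()
        assert rate < 0.12


class TestMethylationCalls:
    def test_planted_hypo_in_dname_subtype_only(self, tiny_model, tiny_annotation):
        cpg, labels = generate_methylation(
            tiny_model, tiny_annotation, n_tumor_per_subtype=30, n_normal=30,
            delta_beta=0.2,
        )
        sums = gene_level_methylation(cpg)
        calls = methylation_calls(sums, labels)
        planted = list(planted_methylation_genes(tiny_model))
        lum = calls[calls["subtype"] == "lumA"].set_index("gene_id")
        bas = calls[calls["subtype"] == "basal"].set_index("gene_id")
        assert (lum.loc[planted, "call"] == "hypo").all()
        assert (bas.loc[planted, "call"] == "hypo").mean() < 0.2

    def test_gene_without_cpgs_absent(self):
        cpg = pd.DataFrame(
            {
                "cpg_id": ["c1"],
                "chrom": ["chr1"],
                "pos": [100],
                "gene_id": ["gA"],
                "s1": [0.5],
                "s2": [0.6],
            }
        )
        sums = gene_level_methylation(cpg)
        assert list(sums.index) == ["gA"]


class TestDeregulationEnrichment:
    def test_top_set_minimal_statistic(self):
        mags = pd.Series(
            np.arange(50, 0, -1, dtype=float), index=[f"g{i}" for i in range(50)]
        )
        res = deregulation_enrichment([f"g{i}" for i in range(5)], mags)
        assert res.n_star == 5 and res.k_star == 5
        assert res.pvalue < 1e-4

    def test_disjoint_set_raises(self):
        mags = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="disjoint"):
            deregulation_enrichment(["zzz"], mags)

    def test_report_batch_qvalues(self):
        rng = np.random.default_rng(30)
        mags = pd.Series(rng.uniform(size=100), index=[f"g{i}" for i in range(100)])
        strong = mags.sort_values(ascending=False).index[:8].tolist()
        tests = [
            {"name": "strong", "gene_set": strong, "magnitudes": mags},
            {"name": "random", "gene_set": [f"g{i}" for i in range(0, 100, 13)], "magnitudes": mags},
        ]
        rep = deregulation_report(tests)
        assert list(rep["name"]) == ["strong", "random"]
        assert rep.loc[0, "q"] < rep.loc[1, "q"]
        assert (rep["q"] <= 1).all()


class TestTable1Pattern:
    def test_planted_aberrations_show_subtype_specific_pattern(self):
        """CNA hits basal regulators, methylation hits lumA regulators."""
        model = PlantedModel.random(n_genes=2000, n_tfs=200, seed=5)
        anno = generate_annotation(model)
        segs, cl = generate_cna(model, anno, n_samples_per_subtype=50, gain_level=0.5)
        g, l = cna_sample_matrix(segs, anno)
        cpg, ml = generate_methylation(
            model, anno, n_tumor_per_subtype=50, n_normal=30, delta_beta=0.2
        )
        sums = gene_level_methylation(cpg)
        tests = []
        for s in model.subtypes:
            tfs = set(model.regulators_per_subtype[s])
            tests.append(
                {
                    "name": f"{s}_TFs_CNA",
                    "gene_set": tfs,
                    "magnitudes": combined_cna_magnitude(g, l, cl, s),
                    "background": model.tf_ids,
                }
            )
            tests.append(
                {
                    "name": f"{s}_TFs_DNAme",
                    "gene_set": tfs,
                    "magnitudes": methylation_magnitude(sums, ml, s),
                    "background": model.tf_ids,
                }
            )
        rep = deregulation_report(tests).set_index("name")
        assert rep.loc["basal_TFs_CNA", "q"] < 0.05
        assert rep.loc["basal_TFs_DNAme", "q"] > 0.1
        assert rep.loc["lumA_TFs_DNAme", "q"] < 0.05
        assert rep.loc["lumA_TFs_CNA", "q"] > 0.1
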