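"""End-to-end orchestration on synthetic cohorts, plus validation checks.

``run_full`` executes the whole discovery pipeline in dependency order on
a generated cohort with planted truth: simulate inputs, expand seed
lists into ESGs, score ChIP-seq experiments and prioritize cell lines,
score CNA and methylation deregulation and test TF enrichment, build the
TF-target network, decompose the basal module into lineages, and run the
knockdown validation.  Every output lands in the output directory as
TSV/JSON together with a manifest carrying the config hash, seed and
recovery metrics against the planted truth.

``knockdown_validation`` implements the perturbation check: the
proportion of signature genes whose expression changes more than a
fold-change threshold upon knocking down a regulator, compared with
size-matched random gene sets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .deregulation import (
    cna_sample_matrix,
    combined_cna_magnitude,
    deregulation_report,
    gene_level_methylation,
    methylation_magnitude,
)
from .enrichment_stats import hypergeometric_tail, qvalues
from .lineage import (
    binding_assignment_table,
    chromatin_lfc_clustering,
    intersect_decompositions,
    select_bound_esgs,
)
from .networks import build_tf_target_network, network_to_edge_table
from .peak_scoring import gene_binding_scores, prioritize_experiments
from .signature_expansion import expand_signature
from .synthetic_data import (
    PlantedModel,
    build_truth,
    generate_annotation,
    generate_chipseq,
    generate_cna,
    generate_expression_compendium,
    generate_methylation,
    generate_open_chromatin,
)

__all__ = ["DEFAULT_CONFIG", "run_full", "knockdown_validation", "generic_set_enrichment"]

logger = logging.getLogger(__name__)

#: Study-scale defaults.  Thresholds carry the pipeline's canonical
#: values: 50 kb TSS windows, base score 500, methylation significance
#: P < 0.01, knockdown fold-change 1.5, signature size 200.
DEFAULT_CONFIG: dict = {
    "model": {
        "n_genes": 17_000,
        "n_tfs": 1_000,
        "n_regulators_per_subtype": 5,
        "n_targets_per_regulator": 40,
        "expression_effect": 1.0,
        "coexpression_loading": 0.7,
        "binding_enrichment": 5.0,
        "noise_sd": 1.0,
    },
    "annotation": {"n_chromosomes": 5, "spacing_mean": 30_000},
    "expression": {"n_datasets": 10, "samples_per_dataset": 50},
    "signature": {"k": 200, "n_seeds": 10},
    "chipseq": {
        "n_background_peaks": 2_000,
        "tag_mean": 10.0,
        "n_decoys": 6,
        "window": 50_000,
        "base_score": 500.0,
        "n_random": 2_000,
    },
    "cna": {
        "n_samples_per_subtype": 50,
        "gain_level": 0.5,
        "target_fraction": 0.5,
        "genes_per_segment": 5.0,
    },
    "methylation": {
        "n_tumor_per_subtype": 50,
        "n_normal": 30,
        "n_cpg_per_gene": 5,
        "delta_beta": 0.2,
        "target_fraction": 0.5,
        "alpha": 0.01,
    },
    "network": {"threshold_rule": "percentile", "percentile": 95.0},
    "lineage": {
        "experiments_per_group": 3,
        "alpha": 0.05,
        "min_experiments": 3,
        "enrichment": 4.0,
        "promoter_window": 2_000,
    },
    "knockdown": {"fc_threshold": 1.5, "n_random": 1_000, "knockdown_log2fc": -1.0},
}


def _deep_update(base: dict, overrides: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def knockdown_validation(
    expr_control: pd.DataFrame,
    expr_knockdown: pd.DataFrame,
    esg,
    fc_threshold: float = 1.5,
    n_random: int = 1_000,
    rng=None,
    log_base: float = 2.0,
) -> dict:
    """Perturbation check of a signature against a knockdown experiment.

    A gene is perturbed when its linear fold-change (knockdown vs
    control; expression is log_base-scale) exceeds ``fc_threshold`` in
    either direction.  The observed perturbed proportion in the
    signature is compared with size-matched random gene sets:
    p = (1 + #{random proportion >= observed}) / (n_random + 1).
    """
    rng = np.random.default_rng(rng)
    common = expr_control.index.intersection(expr_knockdown.index)
    diff = expr_knockdown.loc[common].mean(axis=1) - expr_control.loc[common].mean(axis=1)
    ratio = np.power(log_base, diff.to_numpy(dtype=float))
    perturbed = (ratio > fc_threshold) | (ratio < 1.0 / fc_threshold)
    perturbed = pd.Series(perturbed, index=common)
    esg_genes = [g for g in esg if g in perturbed.index]
    if not esg_genes:
        raise ValueError("signature shares no genes with the expression matrices")
    observed = float(perturbed.loc[esg_genes].mean())
    m = len(esg_genes)
    flags = perturbed.to_numpy()
    null = np.empty(n_random)
    for i in range(n_random):
        null[i] = flags[rng.choice(len(flags), size=m, replace=False)].mean()
    p = float((1 + (null >= observed - 1e-12).sum()) / (n_random + 1))
    return {
        "proportion_esg": observed,
        "proportion_null_mean": float(null.mean()),
        "p": p,
        "n_esg": m,
    }


def generic_set_enrichment(
    gene_set, term_table: dict[str, list], background
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set in each term.

    ``term_table`` maps term -> member genes.  Returns a per-term table
    (term, overlap, term_size, p, q) with q-values across terms.
    """
    background = set(background)
    gene_set = set(gene_set) & background
    rows = []
    for term in sorted(term_table):
        members = set(term_table[term]) & background
        k = len(members & gene_set)
        p = hypergeometric_tail(len(background), len(members), len(gene_set), k)
        rows.append({"term": term, "overlap": k, "term_size": len(members), "p": p})
    if not rows:
        return pd.DataFrame(columns=["term", "overlap", "term_size", "p", "q"])
    df = pd.DataFrame(rows)
    df["q"] = qvalues(df["p"].to_numpy())
    return df


def _experiment_ranks_above_decoys(table: pd.DataFrame, subtype: str, planted) -> bool:
    """True when every planted experiment outranks every decoy for the ESG."""
    col = f"p_{subtype}"
    planted_rows = table[table["factor"].isin(planted)]
    decoy_rows = table[~table["factor"].isin(planted)]
    if planted_rows.empty or decoy_rows.empty:
        return False
    return planted_rows[col].max() < decoy_rows[col].min()


def run_full(config: dict | None = None, out_dir=None, seed: int = 0, resume: bool = False) -> dict:
    """Run the whole pipeline on a synthetic cohort with planted truth.

    Returns a results bundle (dict of DataFrames plus the manifest).
    When ``out_dir`` is given every stage output is written there; with
    ``resume=True`` a directory holding a manifest with the same config
    hash and seed is loaded instead of recomputed.
    """
    cfg = _deep_update(DEFAULT_CONFIG, config or {})
    chash = config_hash(cfg)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        manifest_path = out / "manifest.json"
        if resume and manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
            if manifest.get("config_hash") == chash and manifest.get("seed") == seed:
                logger.info("resuming from cached outputs in %s", out)
                return _load_bundle(out)

    logger.info("stage simulate: planting model (seed=%d)", seed)
    mcfg = cfg["model"]
    model = PlantedModel.random(
        n_genes=mcfg["n_genes"],
        n_tfs=mcfg["n_tfs"],
        n_regulators_per_subtype=mcfg["n_regulators_per_subtype"],
        n_targets_per_regulator=mcfg["n_targets_per_regulator"],
        expression_effect=mcfg["expression_effect"],
        coexpression_loading=mcfg["coexpression_loading"],
        binding_enrichment=mcfg["binding_enrichment"],
        noise_sd=mcfg["noise_sd"],
        seed=seed,
    )
    annotation = generate_annotation(model, **cfg["annotation"])
    datasets = generate_expression_compendium(model, **cfg["expression"])
    logger.info(
        "simulated %d datasets x %d genes", len(datasets), model.n_genes
    )

    # --- signature expansion ---------------------------------------------
    sig_cfg = cfg["signature"]
    esgs: dict[str, pd.DataFrame] = {}
    esg_sets: dict[str, set] = {}
    seeds_per_subtype: dict[str, list] = {}
    for subtype in model.subtypes:
        module = model.module_genes(subtype)
        seeds = sorted(module)[: sig_cfg["n_seeds"]]
        seeds_per_subtype[subtype] = seeds
        esg = expand_signature(datasets, seeds, k=sig_cfg["k"])
        esgs[subtype] = esg
        esg_sets[subtype] = set(esg["gene_id"])
        logger.info("ESG %s: %d genes from %d seeds", subtype, len(esg), len(seeds))

    # --- ChIP-seq generation and prioritization --------------------------
    ccfg = cfg["chipseq"]
    cell_line_of = {s: f"{s}_model_line" for s in model.subtypes}
    experiments = []
    for subtype in model.subtypes:
        for reg in model.regulators_per_subtype[subtype]:
            experiments.append(
                generate_chipseq(
                    model,
                    annotation,
                    factor=reg,
                    cell_line=cell_line_of[subtype],
                    n_background_peaks=ccfg["n_background_peaks"],
                    tag_mean=ccfg["tag_mean"],
                    window=ccfg["window"],
                    experiment_id=f"{reg}@{cell_line_of[subtype]}",
                )
            )
    rng = np.random.default_rng([seed, 1001])
    non_planted_tfs = [
        t
        for t in model.tf_ids
        if all(t not in model.regulators_per_subtype[s] for s in model.subtypes)
    ]
    decoy_factors = list(
        np.array(non_planted_tfs)[
            rng.choice(len(non_planted_tfs), size=ccfg["n_decoys"], replace=False)
        ]
    )
    for fac in decoy_factors:
        experiments.append(
            generate_chipseq(
                model,
                annotation,
                factor=fac,
                cell_line="decoy_line",
                decoy=True,
                n_background_peaks=ccfg["n_background_peaks"],
                tag_mean=ccfg["tag_mean"],
                window=ccfg["window"],
                experiment_id=f"{fac}@decoy_line",
            )
        )
    # an excluded factor, to exercise the name filter
    experiments.append(
        generate_chipseq(
            model,
            annotation,
            factor="CTCF",
            cell_line="decoy_line",
            decoy=True,
            n_background_peaks=ccfg["n_background_peaks"],
            tag_mean=ccfg["tag_mean"],
            window=ccfg["window"],
            experiment_id="CTCF@decoy_line",
        )
    )
    prio_table, cell_summary = prioritize_experiments(
        experiments,
        esg_sets,
        annotation,
        window=ccfg["window"],
        n_random=ccfg["n_random"],
        rng=np.random.default_rng([seed, 1002]),
    )
    prioritization_recovery = {
        subtype: bool(
            _experiment_ranks_above_decoys(
                prio_table, subtype, set(model.regulators_per_subtype[subtype])
            )
        )
        for subtype in model.subtypes
    }

    # --- deregulation ------------------------------------------------------
    cna_cfg = cfg["cna"]
    segments, cna_labels = generate_cna(
        model,
        annotation,
        n_samples_per_subtype=cna_cfg["n_samples_per_subtype"],
        gain_level=cna_cfg["gain_level"],
        target_fraction=cna_cfg["target_fraction"],
        genes_per_segment=cna_cfg["genes_per_segment"],
    )
    gain_mat, loss_mat = cna_sample_matrix(segments, annotation)
    me_cfg = cfg["methylation"]
    cpg, me_labels = generate_methylation(
        model,
        annotation,
        n_tumor_per_subtype=me_cfg["n_tumor_per_subtype"],
        n_normal=me_cfg["n_normal"],
        n_cpg_per_gene=me_cfg["n_cpg_per_gene"],
        delta_beta=me_cfg["delta_beta"],
        target_fraction=me_cfg["target_fraction"],
    )
    gene_sums = gene_level_methylation(cpg)
    tf_background = model.tf_ids
    tests = []
    for subtype in model.subtypes:
        tf_set = set(model.regulators_per_subtype[subtype])
        cna_mag = combined_cna_magnitude(gain_mat, loss_mat, cna_labels, subtype)
        me_mag = methylation_magnitude(gene_sums, me_labels, subtype)
        tests.append(
            {
                "name": f"{subtype}_TFs_CNA",
                "gene_set": tf_set,
                "magnitudes": cna_mag,
                "background": tf_background,
            }
        )
        tests.append(
            {
                "name": f"{subtype}_TFs_DNAme",
                "gene_set": tf_set,
                "magnitudes": me_mag,
                "background": tf_background,
            }
        )
    dereg = deregulation_report(tests)
    qmap = dict(zip(dereg["name"], dereg["q"]))
    table1_pattern = bool(
        qmap[f"{model.cna_subtype}_TFs_CNA"] < 0.05
        and qmap[f"{model.cna_subtype}_TFs_DNAme"] > 0.1
        and qmap[f"{model.dname_subtype}_TFs_DNAme"] < 0.05
        and qmap[f"{model.dname_subtype}_TFs_CNA"] > 0.1
    )

    # --- networks ----------------------------------------------------------
    net_cfg = cfg["network"]
    networks = {}
    network_metrics = {}
    exp_by_factor = {e.factor: e for e in experiments}
    for subtype in model.subtypes:
        tf_scores = {
            reg: gene_binding_scores(
                exp_by_factor[reg].peaks, annotation, window=ccfg["window"]
            )
            for reg in model.regulators_per_subtype[subtype]
        }
        graph = build_tf_target_network(
            tf_scores,
            esg_sets[subtype],
            subtype=subtype,
            threshold_rule=net_cfg["threshold_rule"],
            percentile=net_cfg["percentile"],
        )
        networks[subtype] = graph
        truth_edges = {
            (r, t)
            for r in model.regulators_per_subtype[subtype]
            for t in model.targets_per_regulator.get(r, [])
            if t in esg_sets[subtype]
        }
        pred_edges = set(graph.edges())
        tp = len(truth_edges & pred_edges)
        network_metrics[subtype] = {
            "precision": tp / len(pred_edges) if pred_edges else 0.0,
            "recall": tp / len(truth_edges) if truth_edges else 0.0,
            "n_edges": len(pred_edges),
        }

    # --- lineage decomposition --------------------------------------------
    lin_cfg = cfg["lineage"]
    basal_like = model.cna_subtype
    oc_peaks, lineage_truth = generate_open_chromatin(
        model,
        annotation,
        subtype=basal_like,
        enrichment=lin_cfg["enrichment"],
        promoter_window=lin_cfg["promoter_window"],
    )
    module = model.module_genes(basal_like)
    group_defs = {
        "epithelial": [g for g, l in lineage_truth.items() if l == "epithelial"],
        "stem": [g for g, l in lineage_truth.items() if l == "stem"],
    }
    group_vectors: dict[str, list[pd.Series]] = {"epithelial": [], "stem": []}
    lineage_cell_lines = {"epithelial": "A549like", "stem": "H1like"}
    for grp, genes in group_defs.items():
        for i in range(lin_cfg["experiments_per_group"]):
            exp = generate_chipseq(
                model,
                annotation,
                factor=f"{grp}_factor_{i}",
                cell_line=lineage_cell_lines[grp],
                targets=genes,
                n_background_peaks=ccfg["n_background_peaks"],
                tag_mean=ccfg["tag_mean"],
                window=ccfg["window"],
                experiment_id=f"{grp}_{i}",
            )
            group_vectors[grp].append(
                gene_binding_scores(exp.peaks, annotation, window=ccfg["window"])
            )
    all_vectors = group_vectors["epithelial"] + group_vectors["stem"]
    bound = select_bound_esgs(
        module, all_vectors, min_experiments=lin_cfg["min_experiments"]
    )
    binding_labels = binding_assignment_table(
        group_vectors["epithelial"],
        group_vectors["stem"],
        bound,
        alpha=lin_cfg["alpha"],
    )
    acc = pd.DataFrame(
        {
            cl: gene_binding_scores(
                ps.peaks, annotation, window=lin_cfg["promoter_window"]
            ).reindex(bound)
            for cl, ps in oc_peaks.items()
        }
    )
    line_lineages = {"HMEC": "epithelial", "H1": "stem", "MSC": "mesenchymal"}
    chromatin_labels, _ = chromatin_lfc_clustering(acc, line_lineages)
    lineage_table, lineage_counts = intersect_decompositions(
        binding_labels, chromatin_labels
    )
    assigned = lineage_table[lineage_table["final"] != "none"]
    correct = sum(
        1 for g, row in assigned.iterrows() if lineage_truth.get(g) == row["final"]
    )
    lineage_accuracy = correct / len(assigned) if len(assigned) else 0.0

    # --- knockdown validation ---------------------------------------------
    kd_cfg = cfg["knockdown"]
    expr0, labels0 = datasets[0]
    control = expr0.loc[:, labels0[labels0 == basal_like].index]
    kd_reg = model.regulators_per_subtype[basal_like][0]
    kd = control.copy()
    kd.loc[[t for t in model.targets_per_regulator[kd_reg] if t in kd.index]] += kd_cfg[
        "knockdown_log2fc"
    ]
    kd_result = knockdown_validation(
        control,
        kd,
        esg_sets[basal_like],
        fc_threshold=kd_cfg["fc_threshold"],
        n_random=kd_cfg["n_random"],
        rng=np.random.default_rng([seed, 1003]),
    )

    truth = build_truth(
        model,
        cna_target_fraction=cna_cfg["target_fraction"],
        dname_target_fraction=me_cfg["target_fraction"],
        lineage_truth=lineage_truth,
    )
    esg_precision = {}
    for subtype in model.subtypes:
        planted = set(model.module_genes(subtype)) - set(seeds_per_subtype[subtype])
        top = set(esgs[subtype]["gene_id"])
        esg_precision[subtype] = len(top & planted) / len(top) if top else 0.0

    manifest = {
        "config_hash": chash,
        "seed": seed,
        "config": cfg,
        "metrics": {
            "esg_precision": esg_precision,
            "prioritization_recovery": prioritization_recovery,
            "table1_pattern": table1_pattern,
            "dereg_q": qmap,
            "network": network_metrics,
            "lineage_accuracy": lineage_accuracy,
            "lineage_counts": lineage_counts,
            "knockdown": kd_result,
        },
    }
    bundle = {
        "model": model,
        "annotation": annotation,
        "datasets": datasets,
        "esgs": esgs,
        "prioritization": prio_table,
        "cell_line_summary": cell_summary,
        "deregulation_report": dereg,
        "networks": networks,
        "lineage_table": lineage_table,
        "knockdown": kd_result,
        "truth": truth,
        "manifest": manifest,
    }
    if out is not None:
        _write_bundle(bundle, out)
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    sio.write_annotation(bundle["annotation"], out / "annotation.tsv")
    for subtype, esg in bundle["esgs"].items():
        esg.to_csv(out / f"esg_{subtype}.tsv", sep="\t", index=False)
    bundle["prioritization"].to_csv(out / "prioritization.tsv", sep="\t", index=False)
    bundle["cell_line_summary"].to_csv(
        out / "cell_line_summary.tsv", sep="\t", index=False
    )
    bundle["deregulation_report"].to_csv(
        out / "deregulation_report.tsv", sep="\t", index=False
    )
    for subtype, graph in bundle["networks"].items():
        network_to_edge_table(graph).to_csv(
            out / f"network_{subtype}.tsv", sep="\t", index=False
        )
    bundle["lineage_table"].to_csv(out / "lineage_table.tsv", sep="\t")
    sio.write_truth(bundle["truth"], out / "truth.json")
    (out / "manifest.json").write_text(
        json.dumps(bundle["manifest"], indent=2, default=str) + "\n"
    )


def _load_bundle(out: Path) -> dict:
    manifest = json.loads((out / "manifest.json").read_text())
    bundle = {"manifest": manifest, "truth": sio.read_truth(out / "truth.json")}
    bundle["annotation"] = sio.read_annotation(out / "annotation.tsv")
    bundle["prioritization"] = pd.read_csv(out / "prioritization.tsv", sep="\t")
    bundle["deregulation_report"] = pd.read_csv(
        out / "deregulation_report.tsv", sep="\t"
    )
    bundle["lineage_table"] = pd.read_csv(out / "lineage_table.tsv", sep="\t", index_col=0)
    bundle["esgs"] = {
        p.stem.removeprefix("esg_"): pd.read_csv(p, sep="\t")
        for p in sorted(out.glob("esg_*.tsv"))
    }
    return bundle
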