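"""Synthetic cohorts with planted ground truth.

Generates every input the pipeline consumes — gene annotation,
multi-dataset expression compendia, ChIP-seq and open-chromatin peak
files, per-sample copy-number segments, CpG methylation tables and a
genome FASTA — with a planted regulatory structure:

* two (or more) tumor subtypes, each driven by a small set of regulator
  TFs with coexpressed target modules (latent one-factor model);
* ChIP-seq peaks of a planted regulator enriched near its targets' TSS;
* copy-number gains/losses planted at one subtype's regulators (and a
  fraction of their targets) in that subtype's samples;
* hypo-/hyper-methylation planted at the other subtype's regulators in
  its samples, relative to a shared normal group;
* open-chromatin peaks opening preferentially near each lineage's gene
  subset, with a motif consensus planted in a stated fraction of a
  regulator's peaks.

A truth dictionary records everything planted so downstream recovery can
be scored.  All generators are deterministic under the model seed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peak_scoring import PeakSet

__all__ = [
    "ConfigurationError",
    "PlantedModel",
    "generate_annotation",
    "generate_expression_compendium",
    "generate_chipseq",
    "generate_cna",
    "generate_methylation",
    "generate_open_chromatin",
    "generate_genome_fasta",
    "build_truth",
]


class ConfigurationError(ValueError):
    """Raised when a generator receives an inconsistent configuration."""


# fixed sub-stream ids so each generator has an independent, reproducible
# random stream derived from the model seed
_STREAMS = {
    "annotation": 1,
    "expression": 2,
    "chipseq": 3,
    "cna": 4,
    "methylation": 5,
    "open_chromatin": 6,
    "fasta": 7,
}


def _rng(model: "PlantedModel", stream: str, extra: int = 0):
    return np.random.default_rng([model.seed, _STREAMS[stream], extra])


@dataclass
class PlantedModel:
    """Planted regulatory structure shared by all generators.

    Parameters
    ----------
    n_genes, n_tfs : int
        Genome size and the number of genes flagged as transcription
        factors (defaults 17000 and 1000, the magnitudes of a human
        protein-coding genome and its TF repertoire).
    subtypes : list of str
        Tumor subtype labels; the first two default to luminal A and
        basal-like.
    regulators_per_subtype : dict
        subtype -> list of planted regulator gene ids (must be TFs).
    targets_per_regulator : dict
        regulator -> list of planted target gene ids.  Target sets may
        overlap within a subtype but not across subtypes.
    expression_effect : float
        Log-scale mean shift of a subtype's targets in that subtype's
        samples.
    coexpression_loading : float
        Loading of the per-module latent factor (within-module Pearson
        correlation is loading^2 / (loading^2 + noise_sd^2)).
    binding_enrichment : float
        Fold-increase of peak density near planted targets.
    cna_subtype, dname_subtype : str
        Which subtype's regulators carry planted copy-number segments,
        and which carry planted methylation shifts.
    noise_sd : float
        Residual expression standard deviation.
    seed : int
        Root seed for every generator stream.
    """

    n_genes: int = 17_000
    n_tfs: int = 1_000
    subtypes: list = field(default_factory=lambda: ["lumA", "basal"])
    regulators_per_subtype: dict = field(default_factory=dict)
    targets_per_regulator: dict = field(default_factory=dict)
    expression_effect: float = 1.0
    coexpression_loading: float = 0.7
    binding_enrichment: float = 5.0
    cna_subtype: str = "basal"
    dname_subtype: str = "lumA"
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 10:
            raise ConfigurationError("n_genes must be >= 10")
        if not (0 < self.n_tfs <= self.n_genes):
            raise ConfigurationError("need 0 < n_tfs <= n_genes")
        valid = set(self.gene_ids)
        tfs = set(self.tf_ids)
        seen_targets: dict[str, str] = {}
        for subtype, regs in self.regulators_per_subtype.items():
            if subtype not in self.subtypes:
                raise ConfigurationError(f"unknown subtype {subtype!r}")
            for r in regs:
                if r not in valid:
                    raise ConfigurationError(f"regulator {r!r} is not a gene id")
                if r not in tfs:
                    raise ConfigurationError(f"regulator {r!r} is not flagged as a TF")
                for t in self.targets_per_regulator.get(r, []):
                    if t not in valid:
                        raise ConfigurationError(f"target {t!r} is not a gene id")
                    prev = seen_targets.get(t)
                    if prev is not None and prev != subtype:
                        raise ConfigurationError(
                            f"target {t!r} planted in both {prev!r} and {subtype!r}"
                        )
                    seen_targets[t] = subtype
        for subtype in (self.cna_subtype, self.dname_subtype):
            if subtype not in self.subtypes:
                raise ConfigurationError(f"unknown aberration subtype {subtype!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    @property
    def tf_ids(self) -> list[str]:
        """TF flags are assigned to a reproducible subset of the genome."""
        rng = np.random.default_rng([self.seed, 0])
        idx = np.sort(rng.choice(self.n_genes, size=self.n_tfs, replace=False))
        return [f"G{i:05d}" for i in idx]

    def module_genes(self, subtype: str) -> list[str]:
        """Union of planted target genes of a subtype's regulators."""
        out: set = set()
        for r in self.regulators_per_subtype.get(subtype, []):
            out.update(self.targets_per_regulator.get(r, []))
        return sorted(out)

    @classmethod
    def random(
        cls,
        n_genes: int = 17_000,
        n_tfs: int = 1_000,
        n_regulators_per_subtype: int = 5,
        n_targets_per_regulator: int = 40,
        seed: int = 0,
        **kwargs,
    ) -> "PlantedModel":
        """Draw a planted structure with disjoint per-subtype modules."""
        model = cls(n_genes=n_genes, n_tfs=n_tfs, seed=seed, **kwargs)
        rng = np.random.default_rng([seed, 99])
        tfs = model.tf_ids
        subtypes = model.subtypes
        n_reg = n_regulators_per_subtype * len(subtypes)
        if n_reg > len(tfs):
            raise ConfigurationError("more planted regulators than TFs")
        reg_ids = rng.choice(len(tfs), size=n_reg, replace=False)
        regulators = {
            s: [tfs[i] for i in reg_ids[j * n_regulators_per_subtype : (j + 1) * n_regulators_per_subtype]]
            for j, s in enumerate(subtypes)
        }
        all_regs = [r for regs in regulators.values() for r in regs]
        pool = [g for g in model.gene_ids if g not in set(all_regs)]
        need = n_targets_per_regulator * n_reg
        if need > len(pool):
            raise ConfigurationError("not enough genes for planted targets")
        chosen = rng.choice(len(pool), size=need, replace=False)
        targets = {}
        for i, r in enumerate(all_regs):
            sel = chosen[i * n_targets_per_regulator : (i + 1) * n_targets_per_regulator]
            targets[r] = sorted(pool[j] for j in sel)
        return cls(
            n_genes=n_genes,
            n_tfs=n_tfs,
            regulators_per_subtype=regulators,
            targets_per_regulator=targets,
            seed=seed,
            **kwargs,
        )


def generate_annotation(
    model: PlantedModel,
    n_chromosomes: int = 5,
    spacing_mean: float = 30_000.0,
    min_spacing: int | None = None,
    gene_length: tuple[int, int] = (2_000, 20_000),
) -> pd.DataFrame:
    """Lay genes out non-overlapping on ``n_chromosomes`` chromosomes.

    Intergenic gaps are exponential with mean ``spacing_mean`` (default
    30 kb, so neighbouring +/-50 kb TSS windows frequently overlap and
    peaks can be shared between genes).  Set ``min_spacing`` (e.g.
    120000) to force windows apart.  Deterministic under the model seed.
    """
    if n_chromosomes < 1:
        raise ConfigurationError("need at least one chromosome")
    rng = _rng(model, "annotation")
    genes = model.gene_ids
    tf_set = set(model.tf_ids)
    per_chrom = np.array_split(np.arange(model.n_genes), n_chromosomes)
    rows = []
    for c, idxs in enumerate(per_chrom):
        pos = 10_000
        chrom = f"chr{c + 1}"
        for i in idxs:
            gap = rng.exponential(spacing_mean)
            if min_spacing is not None:
                gap = max(gap, min_spacing)
            length = int(rng.integers(gene_length[0], gene_length[1] + 1))
            start = int(pos + gap)
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            rows.append((genes[i], chrom, start, end, strand, tss, genes[i] in tf_set))
            pos = end
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss", "is_tf"]
    )
    return df.set_index("gene_id", drop=False)


def _subtype_labels(subtypes, n_per_subtype, prefix="S"):
    labels = []
    names = []
    for s in subtypes:
        for i in range(n_per_subtype):
            names.append(f"{prefix}_{s}_{i:03d}")
            labels.append(s)
    return pd.Series(labels, index=names, name="subtype")


def generate_expression_compendium(
    model: PlantedModel,
    n_datasets: int = 10,
    samples_per_dataset: int = 50,
) -> list[tuple[pd.DataFrame, pd.Series]]:
    """Expression matrices (genes x samples) across synthetic datasets.

    Each subtype's planted targets follow a one-factor model: in every
    sample they load on a shared per-sample latent factor (weight
    ``coexpression_loading``) and in samples of their own subtype they
    additionally shift by ``expression_effect``.  Planted regulators
    track their module's latent factor, mimicking a TF coexpressed with
    its targets.  Per-dataset affine jitter (scale and offset) mimics
    platform diversity; rank-based downstream scores are invariant to it.
    """
    per_subtype = samples_per_dataset // len(model.subtypes)
    if per_subtype < 3:
        raise ConfigurationError("need >= 3 samples per subtype per dataset")
    gene_index = pd.Index(model.gene_ids, name="gene_id")
    gene_pos = {g: i for i, g in enumerate(gene_index)}
    out = []
    for d in range(n_datasets):
        rng = _rng(model, "expression", d)
        labels = _subtype_labels(model.subtypes, per_subtype, prefix=f"D{d}")
        n_samp = len(labels)
        X = rng.normal(0.0, model.noise_sd, size=(model.n_genes, n_samp))
        base = rng.normal(0.0, 1.0, size=model.n_genes)
        X += base[:, None]
        for s in model.subtypes:
            module = model.module_genes(s)
            regs = model.regulators_per_subtype.get(s, [])
            if not module and not regs:
                continue
            z = rng.normal(0.0, 1.0, size=n_samp)
            in_subtype = (labels.to_numpy() == s).astype(float)
            mod_idx = [gene_pos[g] for g in module]
            X[mod_idx, :] += (
                model.coexpression_loading * z[None, :]
                + model.expression_effect * in_subtype[None, :]
            )
            reg_idx = [gene_pos[g] for g in regs]
            # regulators track the module factor tightly
            X[reg_idx, :] = (
                base[reg_idx][:, None]
                + z[None, :]
                + model.expression_effect * in_subtype[None, :]
                + rng.normal(0.0, 0.3, size=(len(reg_idx), n_samp))
            )
        scale = rng.uniform(0.7, 1.3)
        offset = rng.normal(0.0, 1.0)
        X = X * scale + offset
        df = pd.DataFrame(X, index=gene_index, columns=labels.index)
        out.append((df, labels))
    return out


def _chrom_lengths(annotation: pd.DataFrame, margin: int = 100_000) -> dict[str, int]:
    return {
        chrom: int(grp["end"].max()) + margin
        for chrom, grp in annotation.groupby("chrom", sort=False)
    }


def _uniform_peaks(rng, chrom_lengths, n, width):
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    ci = rng.choice(len(chroms), size=n, p=probs)
    starts = (rng.random(n) * (lens[ci] - width)).astype(np.int64)
    return [chroms[i] for i in ci], starts


def generate_chipseq(
    model: PlantedModel,
    annotation: pd.DataFrame,
    factor: str,
    cell_line: str = "synthetic",
    n_background_peaks: int = 2_000,
    tag_mean: float = 10.0,
    peak_width: int = 200,
    window: int = 50_000,
    decoy: bool = False,
    targets: list | None = None,
    experiment_id: str = "",
) -> PeakSet:
    """One ChIP-seq experiment as a narrowPeak table.

    Background peaks fall uniformly over the genome.  When ``factor`` is
    a planted regulator (and not a decoy), extra peaks are placed inside
    the +/-50 kb TSS windows of its targets at ``binding_enrichment``
    times the background density, with tag counts drawn at twice the
    background mean.  signalValue carries the tag score; pValue/qValue
    are -1 (ENCODE convention for missing).
    """
    all_regs = {r for regs in model.regulators_per_subtype.values() for r in regs}
    if (
        not decoy
        and targets is None
        and factor not in all_regs
        and factor not in set(model.gene_ids)
    ):
        raise ConfigurationError(f"unknown factor {factor!r}; pass decoy=True for decoys")
    key = zlib.crc32(f"{factor}|{cell_line}|{experiment_id}".encode())
    rng = _rng(model, "chipseq", key)
    lengths = _chrom_lengths(annotation)
    genome_len = float(sum(lengths.values()))
    chroms, starts = _uniform_peaks(rng, lengths, n_background_peaks, peak_width)
    signal = rng.gamma(2.0, tag_mean / 2.0, size=n_background_peaks)

    fg_chroms: list[str] = []
    fg_starts: list[int] = []
    if targets is None:
        targets = [] if decoy else model.targets_per_regulator.get(factor, [])
    if targets and model.binding_enrichment > 0:
        anno = annotation.loc[[t for t in targets if t in annotation.index]]
        win_len = float(len(anno) * 2 * window)
        density = n_background_peaks / genome_len
        n_fg = int(round(model.binding_enrichment * density * win_len))
        if n_fg > 0:
            pick = rng.integers(0, len(anno), size=n_fg)
            tss = anno["tss"].to_numpy()[pick]
            chrom_arr = anno["chrom"].to_numpy()[pick]
            offs = rng.integers(-window, window - peak_width, size=n_fg)
            fg_starts = list(np.maximum(tss + offs, 0).astype(np.int64))
            fg_chroms = list(chrom_arr)
            signal = np.concatenate(
                [signal, rng.gamma(2.0, tag_mean, size=n_fg)]
            )
    chroms = list(chroms) + fg_chroms
    starts = np.concatenate([starts, np.asarray(fg_starts, dtype=np.int64)])
    n_tot = len(chroms)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + peak_width,
            "name": [f"{factor}_peak_{i}" for i in range(n_tot)],
            "score": np.minimum(1000, signal * 10).astype(int),
            "strand": ".",
            "signalValue": signal,
            "pValue": -1.0,
            "qValue": -1.0,
            "peak": peak_width // 2,
        }
    )
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return PeakSet(
        peaks=df,
        factor=factor,
        cell_line=cell_line,
        assay="ChIP-seq",
        experiment_id=experiment_id or f"{factor}_{cell_line}",
    )


def planted_cna_genes(model: PlantedModel, target_fraction: float = 0.5) -> dict[str, float]:
    """Planted CNA gene -> sign (+1 gain / -1 loss), deterministic."""
    out: dict[str, float] = {}
    regs = model.regulators_per_subtype.get(model.cna_subtype, [])
    for i, r in enumerate(regs):
        sign = 1.0 if i % 2 == 0 else -1.0
        out[r] = sign
        targets = model.targets_per_regulator.get(r, [])
        n_keep = int(round(target_fraction * len(targets)))
        for t in sorted(targets)[:n_keep]:
            out[t] = sign
    return out


def generate_cna(
    model: PlantedModel,
    annotation: pd.DataFrame,
    n_samples_per_subtype: int = 50,
    genes_per_segment: float = 5.0,
    gain_level: float = 0.5,
    target_fraction: float = 0.5,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample copy-number segment tables (long format).

    Chromosomes are cut into segments containing a geometric number of
    genes (mean ``genes_per_segment``).  In ``cna_subtype`` samples,
    segments covering a planted gene (regulators and ``target_fraction``
    of each regulator's targets; alternating gain/loss sign per
    regulator) receive log-ratio +/-``gain_level`` plus noise; all other
    segments are N(0, ``noise_sd``).  Values are clipped to [-1, +1].
    """
    if gain_level < 0:
        raise ConfigurationError("gain_level must be >= 0")
    rng = _rng(model, "cna")
    labels = _subtype_labels(model.subtypes, n_samples_per_subtype, prefix="CNA")
    planted = planted_cna_genes(model, target_fraction) if gain_level > 0 else {}
    lengths = _chrom_lengths(annotation)
    anno_by_chrom = {
        chrom: grp.sort_values("start") for chrom, grp in annotation.groupby("chrom")
    }
    rows = []
    p_break = 1.0 / max(genes_per_segment, 1.0)
    for sample, subtype in labels.items():
        aberrant = subtype == model.cna_subtype
        for chrom, genes in anno_by_chrom.items():
            n = len(genes)
            breaks = rng.random(n) < p_break
            breaks[0] = True
            seg_id = np.cumsum(breaks) - 1
            gene_start = genes["start"].to_numpy()
            gene_end = genes["end"].to_numpy()
            gid = genes["gene_id"].to_numpy()
            for s in range(seg_id.max() + 1):
                in_seg = seg_id == s
                seg_start = int(gene_start[in_seg].min()) - 1_000
                seg_end = int(gene_end[in_seg].max()) + 1_000
                value = rng.normal(0.0, noise_sd)
                if aberrant:
                    signs = [planted[g] for g in gid[in_seg] if g in planted]
                    if signs:
                        value = signs[0] * gain_level + rng.normal(0.0, noise_sd)
                rows.append(
                    (sample, chrom, max(seg_start, 0), min(seg_end, lengths[chrom]), value)
                )
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "log_ratio"])
    df["log_ratio"] = df["log_ratio"].clip(-1.0, 1.0)
    return df, labels


def planted_methylation_genes(
    model: PlantedModel, target_fraction: float = 0.5, direction: str = "hypo"
) -> dict[str, float]:
    """Planted methylation gene -> signed delta multiplier (-1 hypo / +1 hyper)."""
    sign = -1.0 if direction == "hypo" else 1.0
    out: dict[str, float] = {}
    regs = model.regulators_per_subtype.get(model.dname_subtype, [])
    for r in regs:
        out[r] = sign
        targets = model.targets_per_regulator.get(r, [])
        n_keep = int(round(target_fraction * len(targets)))
        for t in sorted(targets)[:n_keep]:
            out[t] = sign
    return out


def generate_methylation(
    model: PlantedModel,
    annotation: pd.DataFrame,
    n_tumor_per_subtype: int = 50,
    n_normal: int = 30,
    n_cpg_per_gene: int = 5,
    delta_beta: float = 0.2,
    target_fraction: float = 0.5,
    direction: str = "hypo",
    promoter_window: int = 1_500,
    concentration: float = 50.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """CpG-level beta tables for tumors of each subtype plus normals.

    CpGs sit in each gene's promoter window (TSS +/- ``promoter_window``).
    Betas are Beta-distributed around a per-gene baseline; in
    ``dname_subtype`` tumors the planted genes' CpG means shift by
    ``delta_beta`` down (hypo) or up (hyper).  Betas stay inside [0, 1]
    by construction.
    """
    if not 0 <= delta_beta < 1:
        raise ConfigurationError("delta_beta must be in [0, 1)")
    rng = _rng(model, "methylation")
    tumor_labels = _subtype_labels(model.subtypes, n_tumor_per_subtype, prefix="ME")
    normals = pd.Series(
        ["normal"] * n_normal,
        index=[f"ME_normal_{i:03d}" for i in range(n_normal)],
        name="subtype",
    )
    labels = pd.concat([tumor_labels, normals])
    planted = (
        planted_methylation_genes(model, target_fraction, direction)
        if delta_beta > 0
        else {}
    )
    genes = annotation["gene_id"].to_numpy()
    tss = annotation["tss"].to_numpy()
    chrom = annotation["chrom"].to_numpy()
    n_g = len(genes)
    baseline = rng.uniform(0.3, 0.7, size=n_g)
    n_cpg_total = n_g * n_cpg_per_gene
    offsets = rng.integers(-promoter_window, promoter_window, size=n_cpg_total)
    gene_rep = np.repeat(np.arange(n_g), n_cpg_per_gene)
    pos = np.maximum(tss[gene_rep] + offsets, 0)
    is_aberrant = labels.to_numpy() == model.dname_subtype
    delta_sign = np.array([planted.get(g, 0.0) for g in genes])
    mean_mat = np.tile(baseline[gene_rep][:, None], (1, len(labels)))
    shift = delta_beta * delta_sign[gene_rep][:, None] * is_aberrant[None, :]
    mean_mat = np.clip(mean_mat + shift, 0.02, 0.98)
    a = mean_mat * concentration
    b = (1.0 - mean_mat) * concentration
    betas = rng.beta(a, b)
    df = pd.DataFrame(
        {
            "cpg_id": [f"cg{i:07d}" for i in range(n_cpg_total)],
            "chrom": chrom[gene_rep],
            "pos": pos,
            "gene_id": genes[gene_rep],
        }
    )
    beta_df = pd.DataFrame(betas, columns=labels.index)
    df = pd.concat([df, beta_df], axis=1)
    return df, labels


def generate_open_chromatin(
    model: PlantedModel,
    annotation: pd.DataFrame,
    lineage_lines: dict[str, str] | None = None,
    subtype: str | None = None,
    enrichment: float = 4.0,
    n_background_peaks: int = 2_000,
    peak_width: int = 300,
    promoter_window: int = 2_000,
    tag_mean: float = 10.0,
) -> tuple[dict[str, PeakSet], dict[str, str]]:
    """Open-chromatin peak sets per lineage cell line, plus lineage truth.

    The planted targets of ``subtype`` (default the CNA subtype, i.e. the
    basal-like module) are partitioned round-robin into the lineages.
    Each cell line's peak set has uniform background peaks plus extra
    peaks near its own lineage genes' promoters at ``enrichment`` times
    the background density.  ``enrichment=1`` gives no lineage
    preference.
    """
    if lineage_lines is None:
        lineage_lines = {"epithelial": "HMEC", "stem": "H1", "mesenchymal": "MSC"}
    subtype = subtype or model.cna_subtype
    genes = model.module_genes(subtype)
    if not genes:
        raise ConfigurationError(f"no planted targets for subtype {subtype!r}")
    lineages = sorted(lineage_lines)
    truth = {g: lineages[i % len(lineages)] for i, g in enumerate(sorted(genes))}
    lengths = _chrom_lengths(annotation)
    genome_len = float(sum(lengths.values()))
    density = n_background_peaks / genome_len
    out: dict[str, PeakSet] = {}
    for li, lineage in enumerate(lineages):
        cell_line = lineage_lines[lineage]
        rng = _rng(model, "open_chromatin", li)
        chroms, starts = _uniform_peaks(rng, lengths, n_background_peaks, peak_width)
        signal = rng.gamma(2.0, tag_mean / 2.0, size=n_background_peaks)
        own = [g for g, l in truth.items() if l == lineage and g in annotation.index]
        anno = annotation.loc[own]
        win_len = float(len(anno) * 2 * promoter_window)
        n_fg = int(round(max(enrichment - 1.0, 0.0) * density * win_len))
        # every gene keeps a guaranteed promoter peak so per-gene
        # accessibility scores are defined, with extra signal for the
        # line's own lineage
        all_genes = [g for g in truth if g in annotation.index]
        ganno = annotation.loc[all_genes]
        base_starts = np.maximum(ganno["tss"].to_numpy() - peak_width // 2, 0)
        base_chroms = list(ganno["chrom"].to_numpy())
        own_mask = np.array([truth[g] == lineage for g in all_genes])
        base_signal = rng.gamma(2.0, tag_mean / 2.0, size=len(all_genes))
        base_signal[own_mask] *= max(enrichment, 1.0)
        fg_chroms: list[str] = []
        fg_starts = np.empty(0, dtype=np.int64)
        fg_signal = np.empty(0)
        if n_fg > 0 and len(anno):
            pick = rng.integers(0, len(anno), size=n_fg)
            offs = rng.integers(-promoter_window, promoter_window - peak_width, size=n_fg)
            fg_starts = np.maximum(anno["tss"].to_numpy()[pick] + offs, 0).astype(np.int64)
            fg_chroms = list(anno["chrom"].to_numpy()[pick])
            fg_signal = rng.gamma(2.0, tag_mean, size=n_fg)
        chroms = list(chroms) + base_chroms + fg_chroms
        starts = np.concatenate([starts, base_starts, fg_starts])
        signal = np.concatenate([signal, base_signal, fg_signal])
        n_tot = len(chroms)
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "start": starts.astype(np.int64),
                "end": starts.astype(np.int64) + peak_width,
                "name": [f"{cell_line}_oc_{i}" for i in range(n_tot)],
                "score": np.minimum(1000, signal * 10).astype(int),
                "strand": ".",
                "signalValue": signal,
                "pValue": -1.0,
                "qValue": -1.0,
                "peak": peak_width // 2,
            }
        ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        out[cell_line] = PeakSet(
            peaks=df,
            factor="open-chromatin",
            cell_line=cell_line,
            assay="DNase-seq",
            experiment_id=f"OC_{cell_line}",
        )
    return out, truth


def generate_genome_fasta(
    model: PlantedModel,
    annotation: pd.DataFrame,
    planted_peaks: pd.DataFrame | None = None,
    motif_consensus: str | None = None,
    planted_fraction: float = 0.5,
    max_genome_size: int = 100_000_000,
) -> dict[str, str]:
    """Random genome sequences consistent with the annotation coordinates.

    When ``motif_consensus`` and ``planted_peaks`` are given, the
    consensus string is written at the centre of a ``planted_fraction``
    of those peaks (chosen deterministically by peak order).
    """
    lengths = _chrom_lengths(annotation)
    total = sum(lengths.values())
    if total > max_genome_size:
        raise ConfigurationError(
            f"genome of {total} bp exceeds the {max_genome_size} bp FASTA cap; "
            "use a smaller model for sequence-level work"
        )
    rng = _rng(model, "fasta")
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {
        chrom: bytearray(rng.choice(alphabet, size=ln).tobytes())
        for chrom, ln in lengths.items()
    }
    if motif_consensus and planted_peaks is not None and len(planted_peaks):
        motif = motif_consensus.upper().encode()
        n_plant = int(round(planted_fraction * len(planted_peaks)))
        chosen = planted_peaks.iloc[:n_plant]
        for _, row in chosen.iterrows():
            centre = int((row["start"] + row["end"]) // 2 - len(motif) // 2)
            seq = seqs.get(str(row["chrom"]))
            if seq is None or centre < 0 or centre + len(motif) > len(seq):
                warnings.warn("planted peak outside genome bounds; skipped", stacklevel=2)
                continue
            seq[centre : centre + len(motif)] = motif
    return {chrom: seq.decode() for chrom, seq in seqs.items()}


def build_truth(
    model: PlantedModel,
    cna_target_fraction: float = 0.5,
    dname_target_fraction: float = 0.5,
    dname_direction: str = "hypo",
    lineage_truth: dict[str, str] | None = None,
) -> dict:
    """Assemble the planted ground-truth record for recovery scoring."""
    return {
        "subtypes": list(model.subtypes),
        "tf_ids": list(model.tf_ids),
        "regulators_per_subtype": {
            s: list(r) for s, r in model.regulators_per_subtype.items()
        },
        "targets_per_regulator": {
            r: list(t) for r, t in model.targets_per_regulator.items()
        },
        "module_genes": {s: model.module_genes(s) for s in model.subtypes},
        "cna_subtype": model.cna_subtype,
        "dname_subtype": model.dname_subtype,
        "cna_planted": planted_cna_genes(model, cna_target_fraction),
        "dname_planted": planted_methylation_genes(
            model, dname_target_fraction, dname_direction
        ),
        "lineage_truth": lineage_truth or {},
        "seed": model.seed,
    }
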