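"""Gene-level copy-number and DNA-methylation deregulation scoring.

Copy-number segments (log-ratios in [-1, +1]) are converted to per-gene
gain/loss scores by spreading each segment's value over the genes it
contains:

    gain(g) = sum over gained segments f containing g of cna(f) / len(f)
    loss(g) = sum over lost   segments f containing g of cna(f) / len(f)

where len(f) is the number of genes contained in f.  Per subtype, a
one-sample t-test against zero flags genes significantly associated with
gains or losses.

CpG beta values are summed to gene level per sample; a Welch test of
each subtype's tumors against the normal group calls hyper-/
hypo-methylated genes at P < 0.01.

Finally, genes are ranked by the magnitude of their subtype-mean
deregulation (|gain| + |loss| for CNA, |tumor - normal| for
methylation), and the minimum-hypergeometric test asks whether a gene
set (e.g. a subtype's planted or inferred TFs) concentrates near the top
of that ranking — against a TF background for TF sets, or the whole
genome for ESG sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment_stats import EnrichmentResult, mhg_pvalue, qvalues

__all__ = [
    "gene_level_cna",
    "cna_sample_matrix",
    "cna_subtype_association",
    "gene_level_methylation",
    "methylation_calls",
    "deregulation_enrichment",
    "deregulation_report",
]

logger = logging.getLogger(__name__)


def gene_level_cna(
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    mode: str = "midpoint",
) -> pd.DataFrame:
    """Per-gene (gain, loss) for one sample's segment table.

    A gene belongs to a segment when its body midpoint falls inside the
    segment (``mode="midpoint"``, the default, which avoids
    double-counting genes cut by breakpoints) or when any overlap exists
    (``mode="any"``).  len(f) counts genes under the same rule; segments
    containing no gene contribute nothing.
    """
    if mode not in ("midpoint", "any"):
        raise ValueError(f"unknown containment mode {mode!r}")
    anno = annotation.reset_index(drop=True)
    gain = np.zeros(len(anno))
    loss = np.zeros(len(anno))
    mid = ((anno["start"] + anno["end"]) // 2).to_numpy()
    for chrom, segs in segments.groupby("chrom"):
        gsel = np.flatnonzero((anno["chrom"] == chrom).to_numpy())
        if gsel.size == 0:
            continue
        seg_start = segs["start"].to_numpy()
        seg_end = segs["end"].to_numpy()
        seg_val = segs["log_ratio"].to_numpy(dtype=float)
        order = np.argsort(seg_start, kind="stable")
        seg_start, seg_end, seg_val = seg_start[order], seg_end[order], seg_val[order]
        if mode == "midpoint":
            pos = mid[gsel]
            idx = np.searchsorted(seg_start, pos, side="right") - 1
            ok = idx >= 0
            ok[ok] &= pos[ok] < seg_end[idx[ok]]
            counts = np.bincount(idx[ok], minlength=len(seg_start)).astype(float)
            contrib = np.zeros(gsel.size)
            with np.errstate(divide="ignore", invalid="ignore"):
                per_seg = np.where(counts > 0, seg_val / counts, 0.0)
            contrib[ok] = per_seg[idx[ok]]
            gain[gsel] += np.where(contrib > 0, contrib, 0.0)
            loss[gsel] += np.where(contrib < 0, contrib, 0.0)
        else:
            g_start = anno["start"].to_numpy()[gsel]
            g_end = anno["end"].to_numpy()[gsel]
            overlap = (g_start[:, None] < seg_end[None, :]) & (
                g_end[:, None] > seg_start[None, :]
            )
            counts = overlap.sum(axis=0).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                per_seg = np.where(counts > 0, seg_val / counts, 0.0)
            pos_part = overlap @ np.where(per_seg > 0, per_seg, 0.0)
            neg_part = overlap @ np.where(per_seg < 0, per_seg, 0.0)
            gain[gsel] += pos_part
            loss[gsel] += neg_part
    return pd.DataFrame(
        {"gain": gain, "loss": loss}, index=anno["gene_id"].to_numpy()
    )


def cna_sample_matrix(
    segments_long: pd.DataFrame, annotation: pd.DataFrame, mode: str = "midpoint"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample matrices of gain and loss scores from a long table."""
    gains, losses = {}, {}
    for sample, segs in segments_long.groupby("sample"):
        gl = gene_level_cna(segs, annotation, mode=mode)
        gains[sample] = gl["gain"]
        losses[sample] = gl["loss"]
    return pd.DataFrame(gains), pd.DataFrame(losses)


def _one_sample_t_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise one-sample t-test against 0; constant-zero rows get p=1."""
    n = mat.shape[1]
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    p = np.ones(mat.shape[0])
    ok = sd > 0
    t = np.zeros(mat.shape[0])
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), n - 1)
    degenerate = (~ok) & (mean != 0)
    p[degenerate] = 0.0
    return p


def cna_subtype_association(
    gain_matrix: pd.DataFrame,
    loss_matrix: pd.DataFrame,
    labels: pd.Series,
) -> pd.DataFrame:
    """Per-gene, per-subtype significance of CNA gains and losses.

    One-sample t-test of each subtype's samples' per-gene gain (resp.
    loss) values against zero.  Returns a long table (gene_id, subtype,
    mean_gain, p_gain, mean_loss, p_loss).
    """
    rows = []
    for subtype in labels.unique():
        samples = labels.index[labels == subtype]
        g = gain_matrix.loc[:, samples].to_numpy()
        l = loss_matrix.loc[:, samples].to_numpy()
        p_gain = _one_sample_t_rows(g)
        p_loss = _one_sample_t_rows(l)
        # gain and loss are censored at zero, so their tests are one-sided
        # screens; the net value is symmetric under a no-aberration null
        # and carries the calibrated type-I behavior
        p_net = _one_sample_t_rows(g + l)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": gain_matrix.index,
                    "subtype": subtype,
                    "mean_gain": g.mean(axis=1),
                    "p_gain": p_gain,
                    "mean_loss": l.mean(axis=1),
                    "p_loss": p_loss,
                    "mean_net": (g + l).mean(axis=1),
                    "p_net": p_net,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def gene_level_methylation(
    cpg_table: pd.DataFrame, sample_columns=None
) -> pd.DataFrame:
    """Sum CpG betas to gene-level values per sample (genes x samples)."""
    if sample_columns is None:
        sample_columns = [
            c
            for c in cpg_table.columns
            if c not in ("cpg_id", "chrom", "pos", "gene_id")
        ]
    sums = cpg_table.groupby("gene_id")[list(sample_columns)].sum()
    return sums


def methylation_calls(
    gene_sums: pd.DataFrame,
    labels: pd.Series,
    normal_label: str = "normal",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Welch test of each subtype's tumors against normals, per gene.

    Genes with P < ``alpha`` are called hyper- or hypo-methylated from
    the sign of (tumor mean - normal mean).  Returns a long table
    (gene_id, subtype, mean_tumor, mean_normal, diff, t, p, call).
    """
    normals = labels.index[labels == normal_label]
    if len(normals) < 2:
        raise ValueError("need >= 2 normal samples")
    norm_mat = gene_sums.loc[:, normals].to_numpy()
    rows = []
    for subtype in labels.unique():
        if subtype == normal_label:
            continue
        samples = labels.index[labels == subtype]
        tum = gene_sums.loc[:, samples].to_numpy()
        t, p = stats.ttest_ind(tum, norm_mat, axis=1, equal_var=False)
        diff = tum.mean(axis=1) - norm_mat.mean(axis=1)
        p = np.where(np.isnan(p), 1.0, p)
        call = np.where(p < alpha, np.where(diff > 0, "hyper", "hypo"), "none")
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_sums.index,
                    "subtype": subtype,
                    "mean_tumor": tum.mean(axis=1),
                    "mean_normal": norm_mat.mean(axis=1),
                    "diff": diff,
                    "t": t,
                    "p": p,
                    "call": call,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def deregulation_enrichment(
    gene_set,
    magnitudes: pd.Series,
    background=None,
    combine: str = "sum",
) -> EnrichmentResult:
    """mHG enrichment of a gene set near the top of a deregulation ranking.

    ``magnitudes`` maps background gene -> non-negative deregulation
    magnitude.  Background genes are ranked by descending magnitude with
    ties broken by gene id; the minimum-hypergeometric test scores how
    early the set members appear.  ``background`` restricts the ranking
    (e.g. to the TF universe); the gene set must intersect it.
    """
    mags = magnitudes if background is None else magnitudes.loc[
        [g for g in background if g in magnitudes.index]
    ]
    members = set(gene_set) & set(mags.index)
    if not members:
        raise ValueError("gene set is disjoint from the ranking background")
    frame = pd.DataFrame({"gene_id": mags.index, "mag": mags.to_numpy()})
    frame = frame.sort_values(
        ["mag", "gene_id"], ascending=[False, True], kind="stable"
    )
    membership = frame["gene_id"].isin(members).to_numpy(dtype=int)
    return mhg_pvalue(membership)


def combined_cna_magnitude(
    gain_matrix: pd.DataFrame,
    loss_matrix: pd.DataFrame,
    labels: pd.Series,
    subtype: str,
    combine: str = "sum",
) -> pd.Series:
    """Subtype-mean |gain| + |loss| (or max) per gene, for ranking."""
    samples = labels.index[labels == subtype]
    mg = gain_matrix.loc[:, samples].mean(axis=1).abs()
    ml = loss_matrix.loc[:, samples].mean(axis=1).abs()
    return mg + ml if combine == "sum" else np.maximum(mg, ml)


def methylation_magnitude(
    gene_sums: pd.DataFrame, labels: pd.Series, subtype: str, normal_label="normal"
) -> pd.Series:
    """|tumor mean - normal mean| gene-level methylation difference."""
    tum = gene_sums.loc[:, labels.index[labels == subtype]].mean(axis=1)
    nor = gene_sums.loc[:, labels.index[labels == normal_label]].mean(axis=1)
    return (tum - nor).abs()


def deregulation_report(tests: list[dict]) -> pd.DataFrame:
    """Run a batch of deregulation-enrichment tests with shared q-values.

    Each test dict needs keys ``name``, ``gene_set``, ``magnitudes`` and
    optionally ``background``.  Returns a table (name, p, q, statistic,
    n_star, background_size, set_size) mirroring a set x cohort x
    aberration significance report.
    """
    results = []
    for entry in tests:
        res = deregulation_enrichment(
            entry["gene_set"], entry["magnitudes"], entry.get("background")
        )
        results.append((entry["name"], res))
    qs = qvalues([r.pvalue for _, r in results])
    rows = []
    for (name, res), q in zip(results, qs):
        res.qvalue = float(q)
        rows.append(
            {
                "name": name,
                "p": res.pvalue,
                "q": res.qvalue,
                "statistic": res.statistic,
                "n_star": res.n_star,
                "background_size": res.background_size,
                "set_size": res.set_size,
            }
        )
    return pd.DataFrame(rows)
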