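"""ChIP-seq peak files to per-gene binding scores and experiment ranking.

The binding score of a gene is the sum, over peaks falling inside a
window around its TSS (default +/-50 kb), of the peak's normalized signal
divided by the number of gene windows the peak touches:

    g = sum_{f in P(g)} p_norm(f) / n(f)

where p_norm(f) = p(f) / q75(all peak signals) * 500.  Splitting each
peak's signal evenly among the genes it overlaps conserves total signal
mass, so an experiment's scores sum to the total normalized signal of
its window-overlapping peaks.

Experiments are prioritized for a subtype by asking whether the summed
binding score over the subtype's extended signature genes (ESG) exceeds
the sums over size-matched random gene sets.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakSet",
    "normalize_peak_scores",
    "assign_peaks_to_windows",
    "gene_binding_scores",
    "binding_enrichment_at_set",
    "prioritize_experiments",
    "peak_overlap_fraction",
    "DEFAULT_EXCLUDED_FACTORS",
]

#: Factors excluded from prioritization: architectural/cohesin factors,
#: RNA polymerase II, and histone marks (matched case-insensitively).
DEFAULT_EXCLUDED_FACTORS = ["CTCF", "RAD21", "POLR2A", "POL2", "H2*", "H3*", "H4*"]


@dataclass
class PeakSet:
    """One experiment's peaks (narrowPeak table) plus its metadata."""

    peaks: pd.DataFrame
    factor: str = ""
    cell_line: str = ""
    assay: str = "ChIP-seq"
    experiment_id: str = ""
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)


def normalize_peak_scores(peaks: pd.DataFrame, base_score: float = 500.0) -> pd.DataFrame:
    """Normalize signalValue by the experiment's 75th-percentile signal.

    p_norm(f) = p(f) / q75 * base_score, with q75 computed by linear
    interpolation between order statistics.  The result is invariant to
    uniform scaling of the raw signals.
    """
    signal = peaks["signalValue"].to_numpy(dtype=float)
    if len(signal) == 0 or not (signal > 0).any():
        raise ValueError("cannot normalize: no peak with positive signal")
    q75 = float(np.percentile(signal, 75, method="linear"))
    out = peaks.copy()
    out["signalValue"] = signal / q75 * base_score
    return out


def _tss_windows(annotation: pd.DataFrame, window: int) -> pd.DataFrame:
    win = pd.DataFrame(
        {
            "gene_id": annotation["gene_id"].to_numpy(),
            "chrom": annotation["chrom"].to_numpy(),
            "start": np.maximum(annotation["tss"].to_numpy() - window, 0),
            "end": annotation["tss"].to_numpy() + window,
        }
    )
    return win


def assign_peaks_to_windows(
    peaks: pd.DataFrame, annotation: pd.DataFrame, window: int = 50_000
) -> list[np.ndarray]:
    """For each peak, the integer indices of genes whose TSS window it hits.

    A peak [start, end) overlaps a gene iff it intersects
    [tss - window, tss + window) in at least 1 bp.  The length of each
    returned array is the peak's n(f).
    """
    peak_chroms = set(peaks["chrom"].unique())
    anno_chroms = set(annotation["chrom"].unique())
    orphan = peak_chroms - anno_chroms
    if orphan == peak_chroms and len(peak_chroms) > 0:
        raise ValueError(
            f"no peak chromosome matches the annotation: peaks use {sorted(orphan)}, "
            f"annotation uses {sorted(anno_chroms)}"
        )

    wins = _tss_windows(annotation, window)
    hits: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * len(peaks)
    for chrom, wgrp in wins.groupby("chrom", sort=False):
        mask = (peaks["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        p_idx = np.flatnonzero(mask)
        p_start = peaks["start"].to_numpy()[p_idx]
        p_end = peaks["end"].to_numpy()[p_idx]
        order = np.argsort(wgrp["start"].to_numpy(), kind="stable")
        w_start = wgrp["start"].to_numpy()[order]
        w_end = wgrp["end"].to_numpy()[order]
        w_gene = wgrp.index.to_numpy()[order]
        # windows are sorted by start; ends need not be sorted, so find a
        # candidate range by start and filter by end
        lo = np.searchsorted(w_start, p_start - (w_end - w_start).max(), side="left")
        hi = np.searchsorted(w_start, p_end, side="left")
        for j, pi in enumerate(p_idx):
            cand = slice(lo[j], hi[j])
            sel = w_end[cand] > p_start[j]
            sel &= w_start[cand] < p_end[j]
            hits[pi] = w_gene[cand][sel]
    return hits


def gene_binding_scores(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = 50_000,
    normalize: bool = True,
    base_score: float = 500.0,
) -> pd.Series:
    """Per-gene binding scores g = sum over nearby peaks of p_norm/n.

    Genes never overlapped by a peak score 0.  Returns a Series indexed
    by gene_id in annotation order.
    """
    anno = annotation.reset_index(drop=True)
    if normalize:
        peaks = normalize_peak_scores(peaks, base_score=base_score)
    scores = np.zeros(len(anno))
    if len(peaks):
        hits = assign_peaks_to_windows(peaks, anno, window=window)
        signal = peaks["signalValue"].to_numpy(dtype=float)
        for f, genes in enumerate(hits):
            n_f = len(genes)
            if n_f:
                scores[genes] += signal[f] / n_f
    return pd.Series(scores, index=anno["gene_id"].to_numpy(), name="binding_score")


def binding_enrichment_at_set(
    scores: pd.Series,
    gene_set,
    n_random: int = 10_000,
    rng=None,
) -> tuple[float, float]:
    """Permutation p-value for binding concentration at a gene set.

    The statistic is the sum of gene scores over the set; the null draws
    size-matched gene sets uniformly (without replacement) from all
    scored genes.  p = (1 + #{null >= observed}) / (n_random + 1).

    Returns (p, observed statistic).
    """
    rng = np.random.default_rng(rng)
    genes = [g for g in gene_set if g in scores.index]
    if not genes:
        raise ValueError("gene set shares no genes with the score vector")
    observed = float(scores.loc[genes].sum())
    vals = scores.to_numpy(dtype=float)
    m = len(genes)
    null = np.empty(n_random)
    for i in range(n_random):
        null[i] = vals[rng.choice(len(vals), size=m, replace=False)].sum()
    p = (1.0 + float((null >= observed - 1e-12).sum())) / (n_random + 1.0)
    return p, observed


def _factor_excluded(factor: str, patterns) -> bool:
    f = factor.strip().upper()
    for pat in patterns:
        if fnmatch.fnmatch(f, pat.upper()):
            return True
    return False


def prioritize_experiments(
    experiments: list[PeakSet],
    esg_sets: dict[str, set],
    annotation: pd.DataFrame,
    window: int = 50_000,
    n_random: int = 2_000,
    excluded_factors=DEFAULT_EXCLUDED_FACTORS,
    significance: float = 1e-3,
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank ChIP-seq experiments by binding enrichment at each subtype ESG.

    Architectural factors, Pol2 and histone marks are excluded up front.
    Returns the per-experiment table (p and -log10 p per subtype) and a
    per-cell-line summary (best p per subtype plus the count of
    experiments passing ``significance``).
    """
    rng = np.random.default_rng(rng)
    rows = []
    for exp in experiments:
        if _factor_excluded(exp.factor, excluded_factors):
            continue
        scores = gene_binding_scores(exp.peaks, annotation, window=window)
        row = {
            "experiment_id": exp.experiment_id,
            "factor": exp.factor,
            "cell_line": exp.cell_line,
        }
        for subtype, esg in esg_sets.items():
            p, obs = binding_enrichment_at_set(scores, esg, n_random=n_random, rng=rng)
            row[f"p_{subtype}"] = p
            row[f"neglog10p_{subtype}"] = -np.log10(p)
            row[f"stat_{subtype}"] = obs
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table, table

    summaries = []
    for cell_line, grp in table.groupby("cell_line"):
        rec = {"cell_line": cell_line, "n_experiments": len(grp)}
        for subtype in esg_sets:
            rec[f"best_p_{subtype}"] = grp[f"p_{subtype}"].min()
            rec[f"n_significant_{subtype}"] = int((grp[f"p_{subtype}"] < significance).sum())
        summaries.append(rec)
    summary = pd.DataFrame(summaries)
    return table, summary


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def peak_overlap_fraction(reference: pd.DataFrame, queries) -> float:
    """Fraction of reference peaks overlapped (>=1 bp) by any query peak.

    ``queries`` is an iterable of peak DataFrames pooled into a union of
    intervals before the overlap test.
    """
    if len(reference) == 0:
        raise ValueError("empty reference peak set")
    pool = pd.concat([q for q in queries], ignore_index=True)
    covered = 0
    for chrom, ref in reference.groupby("chrom"):
        qc = pool.loc[pool["chrom"] == chrom]
        if qc.empty:
            continue
        ms, me = _merge_intervals(
            qc["start"].to_numpy(dtype=np.int64), qc["end"].to_numpy(dtype=np.int64)
        )
        r_start = ref["start"].to_numpy(dtype=np.int64)
        r_end = ref["end"].to_numpy(dtype=np.int64)
        # a merged interval overlaps [s, e) iff its start < e and end > s;
        # merged intervals are disjoint and sorted, so check the neighbour
        idx = np.searchsorted(ms, r_end, side="left") - 1
        idx_ok = idx >= 0
        hit = np.zeros(len(ref), dtype=bool)
        hit[idx_ok] = me[idx[idx_ok]] > r_start[idx_ok]
        covered += int(hit.sum())
    return covered / len(reference)
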