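"""Expand seed gene lists into extended subtype signatures (ESGs).

A small list of subtype marker genes is expanded by a cross-dataset
coexpression search: within each expression dataset every gene is scored
by its mean Fisher-z-transformed Pearson correlation with the seeds,
rank-normalized to [0, 1]; datasets are weighted by how mutually
coexpressed the seeds are (leave-one-out); and the weighted mean of the
per-dataset rank scores, taken over the datasets where a gene is
measured, ranks the genome.  The top-k genes (default 200) form the ESG.

Rank normalization makes the aggregate invariant to any monotone
per-dataset rescaling of expression, which is what lets microarray and
RNA-seq datasets be combined.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dataset_coexpression_scores",
    "dataset_weight",
    "expand_signature",
    "coexpression_pvalue",
]

logger = logging.getLogger(__name__)

_Z_CAP = 0.999999  # cap |r| before arctanh to keep Fisher z finite


def _corr_to_seeds(X: np.ndarray, seed_idx: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of X with the seed rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    sd[sd == 0] = np.nan
    Z = Xc / sd[:, None]
    r = Z @ Z[seed_idx].T / X.shape[1]
    return np.clip(np.nan_to_num(r, nan=0.0), -_Z_CAP, _Z_CAP)


def _rank_normalize(values: np.ndarray) -> np.ndarray:
    """Map scores to [0, 1] by rank (ties averaged, best score -> 1)."""
    if len(values) == 1:
        return np.ones(1)
    ranks = stats.rankdata(values, method="average")
    return (ranks - 1.0) / (len(values) - 1.0)


def dataset_coexpression_scores(dataset: pd.DataFrame, seeds) -> pd.Series:
    """Rank-normalized seed-coexpression score of every non-seed gene.

    Score of gene g = mean over present seeds of arctanh(Pearson r(g,
    seed)), rank-normalized to [0, 1] within the dataset.  Raises if
    fewer than two seeds are measured in the dataset.
    """
    seeds = sorted(set(seeds))
    present = [s for s in seeds if s in dataset.index]
    if len(present) < 2:
        raise ValueError(f"only {len(present)} seed(s) present; need >= 2")
    genes = dataset.index.to_numpy()
    X = dataset.to_numpy(dtype=float)
    seed_idx = np.array([dataset.index.get_loc(s) for s in present])
    r = _corr_to_seeds(X, seed_idx)
    z = np.arctanh(r)
    mean_z = z.mean(axis=1)
    non_seed = ~np.isin(genes, present)
    scores = _rank_normalize(mean_z[non_seed])
    return pd.Series(scores, index=genes[non_seed], name="coexpression_score")


def dataset_weight(dataset: pd.DataFrame, seeds) -> float:
    """Mutual-coexpression weight of a dataset in [0, 1].

    For each present seed, score it against the remaining seeds and
    rank-normalize among all candidate genes; the weight is the mean of
    these leave-one-out scores.  Datasets where the seeds are not
    mutually coexpressed land near 0.5 (a random gene's expected rank);
    datasets with fewer than two present seeds weigh 0.
    """
    seeds = sorted(set(seeds))
    present = [s for s in seeds if s in dataset.index]
    if len(present) < 2:
        return 0.0
    genes = dataset.index.to_numpy()
    X = dataset.to_numpy(dtype=float)
    loo_scores = []
    for s in present:
        rest = [t for t in present if t != s]
        seed_idx = np.array([dataset.index.get_loc(t) for t in rest])
        mean_z = np.arctanh(_corr_to_seeds(X, seed_idx)).mean(axis=1)
        candidates = ~np.isin(genes, rest)
        ranked = _rank_normalize(mean_z[candidates])
        loo_scores.append(float(pd.Series(ranked, index=genes[candidates]).loc[s]))
    return float(np.mean(loo_scores))


def aggregate_scores(datasets, seeds) -> pd.Series:
    """Weight-weighted mean rank score per gene over covering datasets."""
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    usable = 0
    for i, ds in enumerate(datasets):
        ds = ds[0] if isinstance(ds, tuple) else ds
        try:
            scores = dataset_coexpression_scores(ds, seeds)
        except ValueError as err:
            logger.warning("dataset %d skipped: %s", i, err)
            continue
        w = dataset_weight(ds, seeds)
        if w <= 0:
            logger.warning("dataset %d skipped: zero weight", i)
            continue
        usable += 1
        for g, sc in scores.items():
            num[g] = num.get(g, 0.0) + w * sc
            den[g] = den.get(g, 0.0) + w
    if usable == 0:
        raise ValueError("no usable dataset (need >= 2 seeds measured somewhere)")
    agg = pd.Series({g: num[g] / den[g] for g in num}, name="score")
    return agg.sort_index()


def expand_signature(datasets, seeds, k: int = 200) -> pd.DataFrame:
    """Build the extended signature: top-k genes by aggregated score.

    Returns a DataFrame (rank, gene_id, score) sorted by descending
    score with ties broken by gene id.  Seed genes never appear in the
    output.
    """
    agg = aggregate_scores(datasets, seeds)
    if k > len(agg):
        warnings.warn(
            f"k={k} exceeds the {len(agg)} scored genes; returning all",
            stacklevel=2,
        )
        k = len(agg)
    ordered = agg.reset_index()
    ordered.columns = ["gene_id", "score"]
    ordered = ordered.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="stable"
    ).head(k)
    ordered.insert(0, "rank", np.arange(1, len(ordered) + 1))
    return ordered.reset_index(drop=True)


def coexpression_pvalue(
    gene: str, seeds, datasets, n_perm: int = 999, rng=None
) -> float:
    """Empirical p-value of a gene's aggregated coexpression score.

    p = (1 + #{random genes with score >= gene's}) / (n_perm + 1), with
    random genes sampled uniformly from all measured genes.
    Deterministic under a fixed rng seed.
    """
    rng = np.random.default_rng(rng)
    agg = aggregate_scores(datasets, seeds)
    if gene not in agg.index:
        raise ValueError(f"gene {gene!r} not measured in any usable dataset")
    observed = agg.loc[gene]
    others = agg.drop(gene)
    draw = others.to_numpy()[rng.integers(0, len(others), size=n_perm)]
    return float((1 + (draw >= observed).sum()) / (n_perm + 1))
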