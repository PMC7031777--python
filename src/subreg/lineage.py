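"""Decompose signature genes into epithelial / stem / mesenchymal lineages.

Two independent assignments are intersected:

1. *Differential TF binding*: for each gene, its binding scores across
   the ChIP-seq experiments of an epithelial cell-line group are
   compared with those of a stem group by Welch's t-test; a significant
   difference labels the gene by the higher-binding group.
2. *Open chromatin*: each gene's accessibility scores across single
   DNase/ATAC experiments of epithelial, stem and mesenchymal lines are
   converted to log fold-changes (each line against the mean of the
   others, pseudocount 1), hierarchically clustered (average linkage,
   Euclidean), and each cluster is labeled by the line with maximal mean
   LFC.  The mesenchymal lineage can only come from this route.

A gene receives a final lineage when the approaches agree (mesenchymal:
chromatin label with no contradicting binding label).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .enrichment_stats import welch_t_test

__all__ = [
    "select_bound_esgs",
    "binding_group_assignment",
    "chromatin_lfc_clustering",
    "intersect_decompositions",
]

AMBIGUOUS = "ambiguous"


def select_bound_esgs(
    esg,
    score_vectors: list[pd.Series],
    min_experiments: int = 3,
    min_score: float = 0.0,
) -> list[str]:
    """Keep ESG genes with substantial genome-wide TF binding.

    A gene qualifies when its binding score exceeds ``min_score`` in at
    least ``min_experiments`` experiments.  ``min_experiments=0`` keeps
    the full ESG.
    """
    esg = sorted(set(esg))
    if min_experiments <= 0:
        return esg
    counts = pd.Series(0, index=pd.Index(esg))
    for vec in score_vectors:
        present = vec.reindex(esg).fillna(0.0)
        counts += (present > min_score).astype(int)
    return [g for g in esg if counts[g] >= min_experiments]


def binding_group_assignment(
    gene_scores_a,
    gene_scores_b,
    label_a: str = "epithelial",
    label_b: str = "stem",
    alpha: float = 0.05,
) -> str:
    """Label one gene from its binding scores in two experiment groups.

    Welch's unequal-variance t-test across experiments; the gene is
    labeled by the direction of the difference when p < alpha, otherwise
    ``"ambiguous"``.
    """
    a = np.asarray(gene_scores_a, dtype=float)
    b = np.asarray(gene_scores_b, dtype=float)
    t, _, p = welch_t_test(a, b)
    if p < alpha:
        return label_a if t > 0 else label_b
    return AMBIGUOUS


def binding_assignment_table(
    score_vectors_a: list[pd.Series],
    score_vectors_b: list[pd.Series],
    genes,
    label_a: str = "epithelial",
    label_b: str = "stem",
    alpha: float = 0.05,
) -> pd.Series:
    """Vector version of :func:`binding_group_assignment` over many genes."""
    genes = sorted(set(genes))
    A = np.column_stack([v.reindex(genes).fillna(0.0).to_numpy() for v in score_vectors_a])
    B = np.column_stack([v.reindex(genes).fillna(0.0).to_numpy() for v in score_vectors_b])
    out = []
    for i in range(len(genes)):
        out.append(binding_group_assignment(A[i], B[i], label_a, label_b, alpha))
    return pd.Series(out, index=genes, name="binding_label")


def chromatin_lfc_clustering(
    accessibility: pd.DataFrame,
    line_lineages: dict[str, str],
    n_lineages: int = 3,
    min_lfc: float = 0.1,
    pseudocount: float = 1.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster genes by open-chromatin log fold-changes between lines.

    ``accessibility`` is a genes x cell-lines score table (one experiment
    per line).  Per gene and line, LFC = log2((x + c) / (mean of the
    other lines + c)).  Rows are clustered by average-linkage Euclidean
    hierarchical clustering into ``n_lineages`` clusters; each cluster is
    labeled by the lineage of the line with maximal mean LFC, or
    ``"ambiguous"`` when that mean LFC is below ``min_lfc``.  Input rows
    are sorted by gene id first, so the procedure is deterministic.

    Returns (per-gene lineage labels, per-gene LFC table).
    """
    acc = accessibility.sort_index()
    lines = list(acc.columns)
    X = acc.to_numpy(dtype=float)
    lfc = np.empty_like(X)
    for j in range(len(lines)):
        others = np.delete(X, j, axis=1).mean(axis=1)
        lfc[:, j] = np.log2((X[:, j] + pseudocount) / (others + pseudocount))
    lfc_df = pd.DataFrame(lfc, index=acc.index, columns=lines)
    if len(acc) <= n_lineages:
        clusters = np.arange(1, len(acc) + 1)
    else:
        # cluster on direction, not magnitude: unit-norm rows keep the
        # linkage from chaining on a few extreme-LFC genes
        norm = np.linalg.norm(lfc, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        linkage = hierarchy.linkage(
            lfc / norm, method="average", metric="euclidean"
        )
        clusters = hierarchy.fcluster(linkage, t=n_lineages, criterion="maxclust")
    labels = pd.Series(AMBIGUOUS, index=acc.index, name="chromatin_label", dtype=object)
    for c in np.unique(clusters):
        mask = clusters == c
        mean_lfc = lfc[mask].mean(axis=0)
        j = int(np.argmax(mean_lfc))
        if mean_lfc[j] >= min_lfc:
            labels.iloc[mask] = line_lineages[lines[j]]
    return labels, lfc_df


def intersect_decompositions(
    binding_labels: pd.Series,
    chromatin_labels: pd.Series,
    mesenchymal_label: str = "mesenchymal",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Final lineage call where the two decompositions agree.

    Epithelial/stem calls require both approaches to agree; the
    mesenchymal lineage is observable only through chromatin, so it is
    assigned when chromatin says mesenchymal and binding is ambiguous
    (a confident contradictory binding label vetoes it).

    Returns the merged per-gene table and the counts per final class.
    """
    genes = sorted(set(binding_labels.index) & set(chromatin_labels.index))
    rows = []
    for g in genes:
        b = binding_labels[g]
        c = chromatin_labels[g]
        if b == c and b != AMBIGUOUS:
            final = b
        elif c == mesenchymal_label and b == AMBIGUOUS:
            final = mesenchymal_label
        else:
            final = "none"
        rows.append((g, b, c, final))
    table = pd.DataFrame(
        rows, columns=["gene_id", "binding_label", "chromatin_label", "final"]
    ).set_index("gene_id")
    counts = table["final"].value_counts().to_dict()
    counts.pop("none", None)
    return table, counts
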