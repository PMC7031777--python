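"""Directed TF -> target and TF -> TF binding networks.

A ChIP'd TF (one with at least one ChIP-seq experiment) is connected to
an ESG gene when the gene's binding score in that TF's experiment is
higher than expected — operationalized as exceeding a genome-wide
percentile of the experiment's nonzero gene scores (default the 95th).
Edge weights are the binding scores themselves.  The TF-TF network is
the restriction of the targets to genes flagged as TFs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "binding_threshold",
    "build_tf_target_network",
    "build_tf_tf_network",
    "partition_targets_by_regulator_combination",
    "network_to_edge_table",
]


def binding_threshold(
    scores: pd.Series, rule: str = "percentile", percentile: float = 95.0, cutoff: float = 0.0
) -> float:
    """Edge threshold for one experiment's gene score vector.

    ``rule`` is one of ``"percentile"`` (default: the given percentile of
    nonzero scores), ``"mean_sd"`` (mean + 2 sd of nonzero scores) or
    ``"absolute"`` (the given cutoff).
    """
    nonzero = scores[scores > 0]
    if rule == "absolute":
        return float(cutoff)
    if len(nonzero) == 0:
        return np.inf
    if rule == "percentile":
        return float(np.percentile(nonzero, percentile))
    if rule == "mean_sd":
        return float(nonzero.mean() + 2.0 * nonzero.std(ddof=1))
    raise ValueError(f"unknown threshold rule {rule!r}")


def build_tf_target_network(
    tf_scores: dict[str, pd.Series],
    esg,
    tf_flags: dict[str, bool] | None = None,
    subtype: str = "",
    threshold_rule: str = "percentile",
    percentile: float = 95.0,
    cutoff: float = 0.0,
    combine: str = "mean",
) -> nx.DiGraph:
    """Directed network from ChIP'd TFs to ESG genes they bind strongly.

    ``tf_scores`` maps each ChIP'd TF to its per-gene binding score
    vector; when a TF has several experiments their vectors should be
    combined (mean by default) before the call, or passed as a list which
    is combined here.  An edge TF -> g exists iff g is in the ESG and
    score_TF(g) exceeds the experiment's threshold.  Self-loops are kept
    and flagged with the ``self_loop`` edge attribute.
    """
    esg = sorted(set(esg))
    tf_flags = tf_flags or {}
    graph = nx.DiGraph(threshold_rule=threshold_rule, percentile=percentile, subtype=subtype)
    for tf in sorted(tf_scores):
        vec = tf_scores[tf]
        if isinstance(vec, (list, tuple)):
            stacked = pd.concat(vec, axis=1)
            vec = stacked.mean(axis=1) if combine == "mean" else stacked.max(axis=1)
        thr = binding_threshold(vec, threshold_rule, percentile, cutoff)
        graph.add_node(tf, is_chipd_tf=True, is_esg_tf=tf_flags.get(tf, True))
        for g in esg:
            score = float(vec.get(g, 0.0))
            if score > thr:
                graph.add_node(
                    g,
                    is_chipd_tf=graph.nodes.get(g, {}).get("is_chipd_tf", False),
                    is_esg_tf=tf_flags.get(g, False),
                )
                graph.add_edge(tf, g, weight=score, self_loop=(tf == g))
    return graph


def build_tf_tf_network(network: nx.DiGraph) -> nx.DiGraph:
    """Restrict targets to genes flagged as TFs (``is_esg_tf`` or source)."""
    sub = nx.DiGraph(**network.graph)
    for u, v, data in network.edges(data=True):
        v_is_tf = network.nodes[v].get("is_esg_tf", False) or network.nodes[v].get(
            "is_chipd_tf", False
        )
        if v_is_tf:
            sub.add_node(u, **network.nodes[u])
            sub.add_node(v, **network.nodes[v])
            sub.add_edge(u, v, **data)
    return sub


def partition_targets_by_regulator_combination(network: nx.DiGraph) -> dict[str, list]:
    """Group target nodes by their exact set of upstream regulators.

    Returns a mapping from a deterministic group key (the sorted,
    '+'-joined source set) to the sorted list of targets sharing it.
    """
    groups: dict[str, list] = {}
    targets = [n for n in network.nodes if network.in_degree(n) > 0]
    for t in sorted(targets):
        sources = sorted(network.predecessors(t))
        key = "+".join(sources)
        groups.setdefault(key, []).append(t)
    return groups


def network_to_edge_table(network: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", np.nan)}
        for u, v, d in sorted(network.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight"])
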