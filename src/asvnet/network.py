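"""Spearman co-occurrence network construction.

Edges are pairwise Spearman rank correlations over samples passing strict
dual thresholds (``|rho| > 0.7`` and ``p < 0.05`` by default); p-values use
the t-approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` with ``n-2``
degrees of freedom.  The resulting graph is simple and undirected, stores
``rho``/``p``/``sign`` as edge attributes, and excludes isolated ASVs.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats

from asvnet._util import logger
from asvnet.feature_table import FeatureTable

EDGE_COLUMNS = ["asv_a", "asv_b", "rho", "p", "sign"]


class NetworkError(ValueError):
    pass


def spearman_matrix(
    table: FeatureTable, min_samples: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p matrices over ASVs.

    Ranks use the average-rank convention for ties.  Pairs involving a
    zero-variance (constant) ASV have rho and p set to NaN and are logged
    as skipped.  ``rho = +/-1`` maps to the smallest positive p rather
    than zero.
    """
    n = table.n_samples
    if n < min_samples:
        raise NetworkError(f"need at least {min_samples} samples, got {n}")
    counts = table.counts.astype(float)
    ranks = np.apply_along_axis(stats.rankdata, 0, counts)
    constant = counts.std(axis=0) == 0
    if constant.any():
        skipped = [a for a, c in zip(table.asv_ids, constant) if c]
        logger.info("spearman: skipping %d constant ASVs: %s",
                    len(skipped), skipped[:10])
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered ** 2).sum(axis=0))
    norms[constant] = np.nan
    rho = (centered.T @ centered) / np.outer(norms, norms)
    rho = np.clip(rho, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = np.finfo(float).tiny
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, np.nan)
    ids = table.asv_ids
    return (pd.DataFrame(rho, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


def threshold_edges(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    rho_threshold: float = 0.7,
    p_threshold: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Canonical edge list of pairs with ``|rho| > rho_threshold`` and
    ``p < p_threshold`` (both strict).

    ``bh_correct=True`` applies Benjamini-Hochberg adjustment to the upper
    triangle of p-values before thresholding; off by default so raw
    p-values are used.
    """
    if rho.shape != p.shape:
        raise NetworkError("rho and p matrices are not conformable")
    ids = list(rho.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    rho_vals = rho.to_numpy()[iu, ju]
    p_vals = p.to_numpy()[iu, ju].copy()
    if bh_correct:
        finite = np.isfinite(p_vals)
        p_vals[finite] = stats.false_discovery_control(p_vals[finite], method="bh")
    keep = (
        np.isfinite(rho_vals) & np.isfinite(p_vals)
        & (np.abs(rho_vals) > rho_threshold) & (p_vals < p_threshold)
    )
    records = [
        {
            "asv_a": ids[i], "asv_b": ids[j],
            "rho": float(r), "p": float(pv),
            "sign": "positive" if r > 0 else "negative",
        }
        for i, j, r, pv in zip(iu[keep], ju[keep], rho_vals[keep], p_vals[keep])
    ]
    edges = pd.DataFrame(records, columns=EDGE_COLUMNS)
    return edges.sort_values(["asv_a", "asv_b"]).reset_index(drop=True)


def build_network(
    edges: pd.DataFrame, node_attrs: pd.DataFrame | None = None
) -> nx.Graph:
    """Simple undirected graph from a canonical edge list.

    Only ASVs participating in at least one edge become nodes.  Optional
    ``node_attrs`` (indexed by ASV id, e.g. taxonomy) are attached to the
    nodes present.  Nodes and edges are inserted in sorted order so that
    downstream algorithms are deterministic.
    """
    graph = nx.Graph()
    nodes = sorted(set(edges["asv_a"]) | set(edges["asv_b"]))
    graph.add_nodes_from(nodes)
    for row in edges.sort_values(["asv_a", "asv_b"]).itertuples(index=False):
        if row.asv_a == row.asv_b:
            raise NetworkError(f"self-edge on {row.asv_a}")
        graph.add_edge(row.asv_a, row.asv_b,
                       rho=float(row.rho), p=float(row.p), sign=row.sign)
    if node_attrs is not None:
        for node in nodes:
            if node in node_attrs.index:
                graph.nodes[node].update(node_attrs.loc[node].to_dict())
    return graph


def network_from_table(
    table: FeatureTable,
    rho_threshold: float = 0.7,
    p_threshold: float = 0.05,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Convenience: Spearman matrices -> thresholded edges -> graph."""
    rho, p = spearman_matrix(table)
    edges = threshold_edges(rho, p, rho_threshold, p_threshold)
    return build_network(edges), edges


def export_network(graph: nx.Graph, graphml_path=None, edges_path=None) -> None:
    """Write the network as GraphML (Gephi-ingestible) and/or edge CSV."""
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
    if edges_path is not None:
        edge_table(graph).to_csv(edges_path, index=False)


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    records = [
        {"source": min(u, v), "target": max(u, v),
         "rho": d.get("rho", np.nan), "p": d.get("p", np.nan),
         "sign": d.get("sign", "")}
        for u, v, d in graph.edges(data=True)
    ]
    df = pd.DataFrame(records, columns=["source", "target", "rho", "p", "sign"])
    return df.sort_values(["source", "target"]).reset_index(drop=True)


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
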