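"""Co-occurrence network over differentially abundant features.

Pairwise Pearson correlations of feature abundances across samples, p-values
from the t transform, multiplicity adjustment over the upper triangle (Holm
by default), and a thresholded graph (|r| > 0.6, adjusted p < 0.05) with
connected-component labels and k-core indices.  Negative correlations that
clear the absolute threshold become signed edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrEdge",
    "CorrNetwork",
    "correlation_matrix",
    "adjust_pvalues",
    "adjust_pvalue_matrix",
    "build_network",
    "k_core_decomposition",
]


@dataclass
class CorrEdge:
    """A signed correlation edge between two features."""

    u: str
    v: str
    r: float
    p_adj: float
    sign: str  # {"positive", "negative"}


@dataclass
class CorrNetwork:
    """Thresholded correlation graph with component and k-core structure."""

    graph: nx.Graph
    edges: list[CorrEdge]
    component_id: dict[str, int]
    core_index: dict[str, int]
    direction: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def correlation_matrix(
    abundance: np.ndarray, feature_ids: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pairwise Pearson correlation of feature rows across samples.

    Zero-variance features are excluded with a warning.  p-values come from
    the two-sided t transform ``t = r sqrt(n-2) / sqrt(1-r^2)`` with n-2
    degrees of freedom.  Returns ``(r, p, kept_feature_ids)``.
    """
    abundance = np.asarray(abundance, dtype=float)
    if abundance.ndim != 2 or abundance.shape[0] != len(feature_ids):
        raise ValueError("abundance must be (n_features, n_samples)")
    n = abundance.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    variances = abundance.var(axis=1)
    keep = variances > 0
    if not np.all(keep):
        dropped = [f for f, k in zip(feature_ids, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} zero-variance feature(s)", stacklevel=2
        )
    kept_ids = [f for f, k in zip(feature_ids, keep) if k]
    sub = abundance[keep]
    if sub.shape[0] == 0:
        return np.zeros((0, 0)), np.zeros((0, 0)), []
    r = np.corrcoef(sub)
    r = np.clip(np.atleast_2d(r), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0  # |r| == 1
    np.fill_diagonal(p, 0.0)
    return r, p, kept_ids


def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Multiplicity adjustment of a p-value vector (Holm step-down or BH)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError("method must be 'holm' or 'bh'")
    return multipletests(p, method=key)[1]


def adjust_pvalue_matrix(p_matrix: np.ndarray, method: str = "holm") -> np.ndarray:
    """Adjust the strictly-upper-triangle p-values of a symmetric matrix and
    mirror the result; the diagonal is set to 0."""
    p_matrix = np.asarray(p_matrix, dtype=float)
    m = p_matrix.shape[0]
    out = np.zeros_like(p_matrix)
    iu = np.triu_indices(m, k=1)
    if iu[0].size:
        adj = adjust_pvalues(p_matrix[iu], method=method)
        out[iu] = adj
        out[(iu[1], iu[0])] = adj
    return out


def build_network(
    r_matrix: np.ndarray,
    p_adj_matrix: np.ndarray,
    feature_ids: list[str],
    r_min: float = 0.6,
    alpha: float = 0.05,
    directions: dict[str, str] | None = None,
) -> CorrNetwork:
    """Threshold correlations into a graph: edge iff ``|r| > r_min`` and
    adjusted p < ``alpha``.  Isolated nodes are retained; components are
    labeled deterministically and k-core indices computed by peeling."""
    r_matrix = np.asarray(r_matrix, dtype=float)
    p_adj_matrix = np.asarray(p_adj_matrix, dtype=float)
    m = len(feature_ids)
    if r_matrix.shape != (m, m) or p_adj_matrix.shape != (m, m):
        raise ValueError("matrices must be square and match feature_ids")

    graph = nx.Graph()
    graph.add_nodes_from(feature_ids)
    edges: list[CorrEdge] = []
    for i in range(m):
        for j in range(i + 1, m):
            r = r_matrix[i, j]
            p = p_adj_matrix[i, j]
            if abs(r) > r_min and p < alpha:
                sign = "positive" if r > 0 else "negative"
                edges.append(
                    CorrEdge(feature_ids[i], feature_ids[j], float(r), float(p), sign)
                )
                graph.add_edge(feature_ids[i], feature_ids[j], r=float(r),
                               p_adj=float(p), sign=sign)

    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    component_id = {}
    for cid, comp in enumerate(components):
        for node in comp:
            component_id[node] = cid
    core_index = k_core_decomposition(graph)
    directions = dict(directions or {})
    nx.set_node_attributes(graph, component_id, "component")
    nx.set_node_attributes(graph, core_index, "k_core")
    if directions:
        nx.set_node_attributes(graph, directions, "direction")
    return CorrNetwork(
        graph=graph,
        edges=edges,
        component_id=component_id,
        core_index=core_index,
        direction=directions,
    )


def k_core_decomposition(graph: nx.Graph | CorrNetwork) -> dict[str, int]:
    """Core index per node: the largest k at which the node survives
    iterative removal of all nodes with degree < k."""
    if isinstance(graph, CorrNetwork):
        graph = graph.graph
    return dict(nx.core_number(graph))


def edges_to_dataframe(network: CorrNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"u": e.u, "v": e.v, "r": e.r, "p_adj": e.p_adj, "sign": e.sign}
            for e in network.edges
        ],
        columns=["u", "v", "r", "p_adj", "sign"],
    )


def nodes_to_dataframe(network: CorrNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": n,
                "direction": network.direction.get(n, ""),
                "component": network.component_id[n],
                "k_core": network.core_index[n],
                "degree": network.graph.degree[n],
            }
            for n in network.graph.nodes
        ],
        columns=["feature_id", "direction", "component", "k_core", "degree"],
    )


def write_edges(network: CorrNetwork, path: str | Path) -> None:
    edges_to_dataframe(network).to_csv(path, sep="\t", index=False)


def write_graphml(network: CorrNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, str(path))
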