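"""Topological-overlap network, module cut, centrality, PCA contributions, hubs.

The co-expression network over the differential proteins is unsigned:
adjacency a_ij = |Pearson r|^beta with soft-thresholding power beta (default
5). The topological overlap of two nodes combines their direct adjacency
with the strength of their shared neighbourhood:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj (u != i, j),   k_i = sum_u a_iu (u != i)

and 1 - TOM is the dissimilarity clustered (average linkage) into a fixed
number of modules. Centrality is intramodular TOM connectivity (the row sum
of TOM restricted to the node's module); hubs are nodes above a
configurable cut. An orthogonal ranking comes from PCA on node-standardized
data: the contribution of a node to a component is its squared loading as a
percentage, aggregated over the top components with eigenvalue weights. The
hub consensus sums a node's rank in both tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "TomNetwork",
    "ContributionTable",
    "correlation_adjacency",
    "topological_overlap",
    "cut_modules",
    "centrality",
    "pca_contributions",
    "hub_consensus",
    "build_tom_network",
]


@dataclass
class TomNetwork:
    node_ids: list[str]
    adjacency: np.ndarray
    tom: np.ndarray
    module_of: pd.Series      # node -> module label (1 = largest)
    centrality: pd.Series     # node -> intramodular TOM connectivity
    soft_power: int


@dataclass
class ContributionTable:
    """Per-node contribution percentages to principal components."""

    table: pd.DataFrame  # index node; columns PC1..PCk, aggregate

    @property
    def aggregate(self) -> pd.Series:
        return self.table["aggregate"]


def _as_values(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.index)
    arr = np.asarray(data, dtype=float)
    return arr, [f"N{i + 1:03d}" for i in range(arr.shape[0])]


def correlation_adjacency(data, soft_power: int = 5) -> np.ndarray:
    """Unsigned soft-thresholded adjacency |r|^beta with unit diagonal.

    ``data`` is node x sample (DataFrame or array); every node must be
    non-constant and there must be at least 3 nodes and 4 samples.
    """
    values, ids = _as_values(data)
    n, m = values.shape
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if m < 4:
        raise ValueError("need at least 4 samples")
    sds = values.std(axis=1)
    if (sds == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant nodes: {bad}")
    r = np.corrcoef(values)
    a = np.abs(r) ** soft_power
    np.fill_diagonal(a, 1.0)
    return a


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric [0,1] adjacency."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.nanmin(a) < 0 or np.nanmax(a) > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    ao = a.copy()
    np.fill_diagonal(ao, 0.0)
    l = ao @ ao                      # shared-neighbour strength (diag terms vanish)
    k = ao.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - ao
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + ao) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return tom


def cut_modules(tom: np.ndarray, n_modules: int, node_ids=None) -> pd.Series:
    """Average-linkage cut of the 1 - TOM dissimilarity into n modules.

    Labels are ordered by module size (1 = largest); size ties break on the
    smallest member index.
    """
    n = tom.shape[0]
    if not (1 <= n_modules <= n):
        raise ValueError("n_modules must lie in [1, n nodes]")
    if node_ids is None:
        node_ids = [f"N{i + 1:03d}" for i in range(n)]
    if n_modules == n:
        raw = np.arange(1, n + 1)
    else:
        d = 1.0 - tom
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="average")
        raw = fcluster(z, t=n_modules, criterion="maxclust")
    # relabel: largest module -> 1, ties by first appearance
    sizes = pd.Series(raw).value_counts()
    first_seen = {lab: int(np.flatnonzero(raw == lab)[0]) for lab in sizes.index}
    ordered = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_seen[lab]))
    relabel = {lab: i + 1 for i, lab in enumerate(ordered)}
    labels = pd.Series(
        [relabel[lab] for lab in raw], index=pd.Index(node_ids, name="node_id"),
        name="module",
    )
    return labels


def centrality(
    tom: np.ndarray, module_of: pd.Series, module=None
) -> pd.Series:
    """Intramodular TOM connectivity: sum of TOM to same-module partners.

    With ``module`` given, only that module's nodes are returned.
    """
    ids = list(module_of.index)
    labels = module_of.to_numpy()
    out = np.zeros(len(ids))
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        sub = tom[np.ix_(idx, idx)]
        out[idx] = sub.sum(axis=1) - np.diag(sub)
    series = pd.Series(out, index=module_of.index, name="centrality")
    if module is not None:
        series = series[module_of == module]
    return series


def pca_contributions(data, n_components: int = 5) -> ContributionTable:
    """Contribution (%) of each node to the top principal components.

    PCA runs on node-standardized data (correlation PCA) with nodes as
    variables and samples as observations. Per component the contributions
    are 100 x squared loading (summing to 100); the aggregate weights each
    component's contribution by its eigenvalue share over the top
    ``n_components``.
    """
    values, ids = _as_values(data)
    n, m = values.shape
    n_components = int(n_components)
    if not (1 <= n_components <= min(n, m)):
        raise ValueError("n_components must lie in [1, min(nodes, samples)]")
    sds = values.std(axis=1, ddof=1)
    if (sds == 0).any() or not np.isfinite(sds).all():
        bad = [ids[i] for i in np.flatnonzero((sds == 0) | ~np.isfinite(sds))]
        raise ValueError(f"zero-variance nodes: {bad}")
    x = (values - values.mean(axis=1, keepdims=True)) / sds[:, None]
    obs = x.T                                # samples x nodes, each column mean 0
    _, s, vt = np.linalg.svd(obs, full_matrices=False)
    eig = (s**2) / (m - 1)
    contrib = 100.0 * (vt**2)                # components x nodes; rows sum to 100
    top = slice(0, n_components)
    weights = eig[top] / eig[top].sum()
    aggregate = (contrib[top] * weights[:, None]).sum(axis=0)
    table = pd.DataFrame(
        {f"PC{c + 1}": contrib[c] for c in range(n_components)},
        index=pd.Index(ids, name="node_id"),
    )
    table["aggregate"] = aggregate
    return ContributionTable(table)


def hub_consensus(
    centrality_table: pd.Series,
    contribution_table: pd.Series,
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank nodes by summed rank in centrality and PCA contribution.

    Both inputs map node -> value (higher = more central / contributing).
    Ties in the consensus break lexicographically by node id; ``top_k``
    larger than the node count returns the full ranking.
    """
    common = [i for i in centrality_table.index if i in set(contribution_table.index)]
    if not common:
        raise ValueError("centrality and contribution tables share no node ids")
    cent = centrality_table[common]
    contrib = contribution_table[common]
    rank_c = cent.rank(ascending=False, method="min")
    rank_p = contrib.rank(ascending=False, method="min")
    score = rank_c + rank_p
    out = pd.DataFrame(
        {
            "centrality": cent,
            "contribution": contrib,
            "rank_centrality": rank_c.astype(int),
            "rank_contribution": rank_p.astype(int),
            "rank_sum": score.astype(int),
        }
    )
    # stable sort after an index sort -> rank_sum ties break lexicographically
    out = out.sort_index(kind="mergesort").sort_values("rank_sum", kind="mergesort")
    out["consensus_rank"] = np.arange(1, len(out) + 1)
    return out.head(int(top_k)) if top_k < len(out) else out


def build_tom_network(
    data, soft_power: int = 5, n_modules: int = 2
) -> TomNetwork:
    """Adjacency, TOM, module cut and centrality in one call."""
    values, ids = _as_values(data)
    adjacency = correlation_adjacency(values, soft_power)
    tom = topological_overlap(adjacency)
    modules = cut_modules(tom, n_modules, node_ids=ids)
    cent = centrality(tom, modules)
    return TomNetwork(ids, adjacency, tom, modules, cent, soft_power)
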