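"""Correlation-network construction, graph metrics and network comparison.

Within each stratum (by default genotype x condition, pooling time
points so the replicate count supports FDR-thresholded edges), Pearson
correlations are computed for all metabolite pairs, p-values are
Benjamini–Hochberg adjusted over the full set of pairwise tests, and
pairs with q below the threshold become signed weighted edges.

Graph metrics follow the Cytoscape NetworkAnalyzer conventions:
heterogeneity is the coefficient of variation of the degree
distribution and centralization is Freeman degree centralization.
Networks are compared by Bray–Curtis dissimilarity on node-degree
vectors and by Jaccard distance on (sign-agnostic) edge sets, then
clustered with the Ward criterion (Ward.D2 semantics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import braycurtis, squareform
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    MetaboliteTable,
    SampleMetadata,
    TableState,
    ValidationError,
)

__all__ = [
    "CorrelationNetwork",
    "NetworkMetrics",
    "NetworkComparison",
    "build_network",
    "network_metrics",
    "degree_histogram",
    "network_dissimilarity",
    "ward_cluster",
    "linkage_to_newick",
]

Edge = tuple[str, str]


@dataclass
class CorrelationNetwork:
    """Signed weighted metabolite graph for one stratum."""

    stratum: str
    nodes: list[str]                       # full metabolite universe
    edges: dict[Edge, tuple[float, float, float]]  # (a,b) a<b -> (r, p, q)
    n_samples: int
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValidationError(f"self-edge on {a!r}")
            if a > b:
                raise ValidationError("edge pairs must be ordered (a < b)")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree_vector(self) -> pd.Series:
        deg = pd.Series(0, index=self.nodes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def edge_set(self, signed: bool = False) -> set:
        if not signed:
            return set(self.edges)
        return {(a, b, 1 if r > 0 else -1) for (a, b), (r, _, _) in self.edges.items()}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), (r, p, q) in self.edges.items():
            g.add_edge(a, b, r=r, p=p, q=q, sign=1 if r > 0 else -1)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"id_a": a, "id_b": b, "r": r, "p": p, "q": q}
            for (a, b), (r, p, q) in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "r", "p", "q"])


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges_pos: int
    n_edges_neg: int
    pos_neg_ratio: float | None    # None when no negative edges
    density: float
    diameter: int
    heterogeneity: float
    centralization: float
    degrees: pd.Series = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges_pos": self.n_edges_pos,
            "n_edges_neg": self.n_edges_neg,
            "pos_neg_ratio": self.pos_neg_ratio,
            "density": self.density,
            "diameter": self.diameter,
            "heterogeneity": self.heterogeneity,
            "centralization": self.centralization,
        }


@dataclass
class NetworkComparison:
    labels: list[str]
    matrix: np.ndarray            # symmetric, zero diagonal, values in [0, 1]
    method: str                   # bray_curtis_degrees | jaccard_edges

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def build_network(
    table: MetaboliteTable,
    metadata: SampleMetadata,
    stratum: dict,
    q_threshold: float = 0.05,
    stratum_label: str | None = None,
) -> CorrelationNetwork:
    """Pearson correlation network for the samples selected by `stratum`.

    `stratum` maps metadata factors to levels, e.g.
    ``{"genotype": "A", "condition": "hypoxia"}``.  Zero-variance
    metabolites are excluded from testing with a warning but stay in the
    node universe (degree 0).
    """
    table.require_state(TableState.IMPUTED, TableState.LOG_SCALED)
    if not 0 < q_threshold <= 1:
        raise ValidationError("q_threshold must lie in (0, 1]")
    sample_ids = metadata.select(**stratum)
    sample_ids = [s for s in sample_ids if s in table.values.index]
    n = len(sample_ids)
    if n < 4:
        raise ValidationError(
            f"stratum {stratum} selects only {n} samples; >= 4 required"
        )
    X = table.values.loc[sample_ids].to_numpy()
    if np.isnan(X).any():
        raise ValidationError("stratum contains missing values; impute first")
    sd = X.std(axis=0)
    usable = sd > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} zero-variance metabolites excluded from "
            "correlation testing",
            stacklevel=2,
        )
    ids = np.array(table.metabolite_ids)
    Xu = X[:, usable]
    corr = np.corrcoef(Xu, rowvar=False)
    iu = np.triu_indices(corr.shape[0], k=1)
    r = np.clip(corr[iu], -1.0, 1.0)
    # two-sided p from the exact t transform of Pearson r
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p[np.abs(r) >= 1.0] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    keep = q < q_threshold
    used_ids = ids[usable]
    edges: dict[Edge, tuple[float, float, float]] = {}
    for idx in np.where(keep)[0]:
        a, b = used_ids[iu[0][idx]], used_ids[iu[1][idx]]
        if a > b:
            a, b = b, a
        edges[(a, b)] = (float(r[idx]), float(p[idx]), float(q[idx]))
    label = stratum_label or "_".join(str(v) for v in stratum.values())
    return CorrelationNetwork(label, list(ids), edges, n, q_threshold)


def network_metrics(net: CorrelationNetwork) -> NetworkMetrics:
    """NetworkAnalyzer-style summary metrics over the full node universe."""
    deg = net.degree_vector()
    n = len(net.nodes)
    n_pos = sum(1 for (r, _, _) in net.edges.values() if r > 0)
    n_neg = net.n_edges - n_pos
    ratio = (n_pos / n_neg) if n_neg else None
    density = 2 * net.n_edges / (n * (n - 1)) if n > 1 else 0.0
    if net.n_edges == 0:
        return NetworkMetrics(n, 0, 0, ratio, density, 0, 0.0, 0.0, deg)
    g = net.to_graph()
    components = list(nx.connected_components(g))
    largest = max(components, key=len)
    diameter = nx.diameter(g.subgraph(largest)) if len(largest) > 1 else 0
    mean_deg = float(deg.mean())
    het = float(np.sqrt(deg.to_numpy().var()) / mean_deg) if mean_deg else 0.0
    k_max = int(deg.max())
    centralization = (
        (n / (n - 2)) * (k_max / (n - 1) - density) if n > 2 else 0.0
    )
    return NetworkMetrics(
        n, n_pos, n_neg, ratio, density, int(diameter), het,
        float(centralization), deg,
    )


def degree_histogram(
    net: CorrelationNetwork, bins: list[int] | None = None
) -> pd.DataFrame:
    """Counts of nodes per degree (or per supplied bin edges), incl. degree 0."""
    deg = net.degree_vector().to_numpy()
    if bins is None:
        values, counts = np.unique(deg, return_counts=True)
        return pd.DataFrame({"degree": values, "count": counts})
    counts, edges = np.histogram(deg, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def _aligned_degrees(nets: list[CorrelationNetwork]) -> pd.DataFrame:
    universe = sorted(set().union(*(set(n.nodes) for n in nets)))
    frame = pd.DataFrame(0, index=universe, columns=[n.stratum for n in nets])
    for net in nets:
        frame.loc[net.degree_vector().index, net.stratum] = net.degree_vector()
    return frame


def network_dissimilarity(
    nets: list[CorrelationNetwork],
    method: str = "bray_curtis_degrees",
) -> NetworkComparison:
    """Pairwise dissimilarity matrix between networks.

    * ``bray_curtis_degrees`` — BC(u, v) = Σ|u−v| / Σ(u+v) on node-degree
      vectors aligned by metabolite id (degree 0 for absent nodes);
    * ``jaccard_edges`` — 1 − |Ea ∩ Eb| / |Ea ∪ Eb| on unordered,
      sign-agnostic metabolite pairs.

    Two edgeless networks compare as 0 by convention (with a warning).
    """
    if len(nets) < 2:
        raise ValidationError("need >= 2 networks to compare")
    labels = [n.stratum for n in nets]
    if len(set(labels)) != len(labels):
        raise ValidationError("network stratum labels must be unique")
    k = len(nets)
    d = np.zeros((k, k))
    if method == "bray_curtis_degrees":
        degs = _aligned_degrees(nets)
        for i in range(k):
            for j in range(i + 1, k):
                u = degs.iloc[:, i].to_numpy(dtype=float)
                v = degs.iloc[:, j].to_numpy(dtype=float)
                if u.sum() + v.sum() == 0:
                    warnings.warn("both networks are edgeless; dissimilarity 0",
                                  stacklevel=2)
                    d[i, j] = d[j, i] = 0.0
                else:
                    d[i, j] = d[j, i] = float(braycurtis(u, v))
    elif method == "jaccard_edges":
        edge_sets = [n.edge_set() for n in nets]
        for i in range(k):
            for j in range(i + 1, k):
                union = edge_sets[i] | edge_sets[j]
                if not union:
                    warnings.warn("both networks are edgeless; dissimilarity 0",
                                  stacklevel=2)
                    d[i, j] = d[j, i] = 0.0
                else:
                    inter = edge_sets[i] & edge_sets[j]
                    d[i, j] = d[j, i] = 1.0 - len(inter) / len(union)
    else:
        raise ValidationError(
            f"unknown method {method!r}; expected 'bray_curtis_degrees' or "
            "'jaccard_edges'"
        )
    return NetworkComparison(labels, d, method)


def ward_cluster(comparison: NetworkComparison) -> tuple[np.ndarray, str]:
    """Ward clustering of a network dissimilarity matrix.

    Returns the SciPy linkage matrix together with a Newick string whose
    branch lengths derive from the merge heights (Ward.D2 semantics:
    squared distances internally).  Leaf order is deterministic.
    """
    d = comparison.matrix
    if not np.allclose(d, d.T):
        raise ValidationError("dissimilarity matrix must be symmetric")
    if len(comparison.labels) < 2:
        raise ValidationError("need >= 2 items to cluster")
    condensed = squareform(d, checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    newick = linkage_to_newick(linkage, comparison.labels)
    return linkage, newick


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Rooted Newick tree with branch lengths = difference of merge heights."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
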