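"""Twelve node-centrality measures on a correlation network.

For each network the profile holds, per node: degree K and strength S
(row sums of A and W); nearest-neighbor average degree Knn and strength
Snn; closeness CC and weighted closeness WCC, (N-1)/sum_j d_ij with
topological (hop-count) and weighted distances; betweenness BC and
weighted betweenness WBC, the fraction of shortest paths through the
node with the 1/C(N-1, 2) Freeman normalization (endpoints excluded);
the clustering coefficient Clust = triangles_i / C(K_i, 2), undefined
for K_i < 2; the inverse participation ratio IPR, by default the
edge-weight disparity Y_i = sum_j (W_ij / S_i)^2 (1/K_i for uniform
weights, -> 1 when one edge dominates); and the spectral centralities
SC and WSC, SC_i = sum_j A_ij (v_i - v_j)^2 with v the Fiedler vector
(unit-norm eigenvector of the second-smallest Laplacian eigenvalue) of
the binary or weighted combinatorial Laplacian.

Weighted distances use edge length 1/w (strong similarity = short edge);
the chordal distance S itself is available as an alternative. Undefined
entries (Clust for K < 2, Knn/Snn/IPR for isolated nodes) are reported
as NaN and excluded from whole-network averages downstream.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin

from .netbuild import CorrelationNetwork

__all__ = [
    "MEASURES",
    "CentralityProfiler",
    "centrality_profile",
    "degree_strength",
    "nn_degree_strength",
    "closeness",
    "betweenness",
    "clustering_coefficient",
    "spectral_centrality",
    "inverse_participation_ratio",
    "fiedler_vector",
]

MEASURES = (
    "degree",
    "strength",
    "nn_degree",
    "nn_strength",
    "closeness",
    "w_closeness",
    "betweenness",
    "w_betweenness",
    "clustering",
    "ipr",
    "spectral",
    "w_spectral",
)


def _as_matrices(net) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(net, CorrelationNetwork):
        return np.asarray(net.adjacency, float), np.asarray(net.weights, float)
    adjacency, weights = net
    return np.asarray(adjacency, float), np.asarray(weights, float)


def degree_strength(net) -> tuple[np.ndarray, np.ndarray]:
    """Node degree K_i = sum_j A_ij and strength S_i = sum_j W_ij."""
    adjacency, weights = _as_matrices(net)
    return adjacency.sum(axis=1), weights.sum(axis=1)


def nn_degree_strength(net, degree: np.ndarray | None = None,
                       strength: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean of neighbor degrees / strengths; NaN for isolated nodes."""
    adjacency, weights = _as_matrices(net)
    if degree is None or strength is None:
        degree, strength = degree_strength((adjacency, weights))
    with np.errstate(invalid="ignore", divide="ignore"):
        knn = (adjacency @ degree) / degree
        snn = (adjacency @ strength) / degree
    knn[degree == 0] = np.nan
    snn[degree == 0] = np.nan
    return knn, snn


def _length_graph(adjacency: np.ndarray, weights: np.ndarray,
                  weighted: bool, distance: str) -> nx.Graph:
    graph = nx.from_numpy_array(adjacency if not weighted else weights)
    if weighted:
        if distance == "inverse":
            for _, _, data in graph.edges(data=True):
                data["length"] = 1.0 / data["weight"]
        elif distance == "chordal":
            # w = exp(-S^2) at sigma from construction; recover S as length
            for _, _, data in graph.edges(data=True):
                data["length"] = float(np.sqrt(max(-np.log(data["weight"]), 0.0)))
        else:
            raise ValueError(f"unknown weighted distance {distance!r}")
    return graph


def closeness(net, mode: str = "topo", distance: str = "inverse") -> np.ndarray:
    """Closeness centrality (N-1)/sum_j d_ij, topological or weighted.

    On a disconnected network each node is scored within its component
    with Wasserman–Faust scaling by the reachable fraction (the connected
    case reduces to the plain formula); a warning is emitted.
    """
    adjacency, weights = _as_matrices(net)
    graph = _length_graph(adjacency, weights, mode == "weighted", distance)
    if not nx.is_connected(graph) and graph.number_of_nodes() > 1:
        warnings.warn("disconnected network: closeness uses per-component "
                      "Wasserman-Faust scaling")
    dist = "length" if mode == "weighted" else None
    cc = nx.closeness_centrality(graph, distance=dist, wf_improved=True)
    return np.array([cc[i] for i in range(graph.number_of_nodes())])


def betweenness(net, mode: str = "topo", distance: str = "inverse") -> np.ndarray:
    """Betweenness centrality, normalized by C(N-1, 2), endpoints excluded."""
    adjacency, weights = _as_matrices(net)
    graph = _length_graph(adjacency, weights, mode == "weighted", distance)
    dist = "length" if mode == "weighted" else None
    bc = nx.betweenness_centrality(graph, weight=dist, normalized=True)
    return np.array([bc[i] for i in range(graph.number_of_nodes())])


def clustering_coefficient(net) -> np.ndarray:
    """Clust_i = (A^3)_ii / 2 / C(K_i, 2); NaN where K_i < 2."""
    adjacency, _ = _as_matrices(net)
    degree = adjacency.sum(axis=1)
    triangles = np.diag(adjacency @ adjacency @ adjacency) / 2.0
    pairs = degree * (degree - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        clust = triangles / pairs
    clust = np.where(degree < 2, np.nan, clust)
    return clust


def fiedler_vector(matrix: np.ndarray, degenerate_tol: float = 1e-10) -> np.ndarray:
    """Unit-norm eigenvector of the second-smallest eigenvalue of L = D - M.

    Requires a connected graph (second eigenvalue > 0). The global sign is
    fixed deterministically: the first entry exceeding 1e-12 in magnitude
    is made positive. A (near-)degenerate second eigenvalue triggers a
    warning; the eigh eigenvector with the sign convention is still
    returned, so results are deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    laplacian = np.diag(matrix.sum(axis=1)) - matrix
    eigvals, eigvecs = eigh(laplacian)
    if eigvals[1] <= degenerate_tol * max(1.0, abs(eigvals[-1])):
        raise ValueError("graph is disconnected (zero Fiedler value); "
                         "restrict to a connected component first")
    if len(eigvals) > 2 and abs(eigvals[2] - eigvals[1]) <= degenerate_tol * max(
            1.0, abs(eigvals[-1])):
        warnings.warn("near-degenerate Fiedler eigenvalue; eigenvector choice "
                      "fixed by deterministic sign convention")
    vec = eigvecs[:, 1]
    nz = np.flatnonzero(np.abs(vec) > 1e-12)
    if len(nz) and vec[nz[0]] < 0:
        vec = -vec
    return vec


def spectral_centrality(net, mode: str = "topo",
                        on_disconnected: str = "raise") -> np.ndarray:
    """SC_i = sum_j M_ij (v_i - v_j)^2 with v the Fiedler vector of L = D - M.

    ``mode='topo'`` uses the binary adjacency, ``mode='weighted'`` the
    weight matrix. Invariant under the global sign of v. The Fiedler
    vector needs a connected graph; on a disconnected one,
    ``on_disconnected='raise'`` errors instructing component restriction
    while ``'giant'`` computes the measure on the largest connected
    component and reports NaN for the remaining nodes (warned).
    """
    adjacency, weights = _as_matrices(net)
    matrix = adjacency if mode == "topo" else weights
    try:
        vec = fiedler_vector(matrix)
    except ValueError:
        if on_disconnected != "giant":
            raise
        from scipy.sparse.csgraph import connected_components

        n_comp, labels = connected_components(adjacency > 0, directed=False)
        giant = labels == np.bincount(labels).argmax()
        warnings.warn(f"disconnected network ({n_comp} components): spectral "
                      "centrality restricted to the giant component "
                      f"({int(giant.sum())}/{len(giant)} nodes), NaN elsewhere")
        out = np.full(matrix.shape[0], np.nan)
        sub = matrix[np.ix_(giant, giant)]
        vec = fiedler_vector(sub)
        diff = vec[:, None] - vec[None, :]
        out[giant] = (sub * diff ** 2).sum(axis=1)
        return out
    diff = vec[:, None] - vec[None, :]
    return (matrix * diff ** 2).sum(axis=1)


def inverse_participation_ratio(net, variant: str = "disparity") -> np.ndarray:
    """Per-node IPR.

    ``variant='disparity'`` (default): edge-weight disparity
    Y_i = sum_j (W_ij / S_i)^2, the concentration of a node's strength
    among its edges (1/K_i for uniform weights). ``variant='fiedler'``:
    localization weight v_i^4 of the weighted Fiedler vector, an
    eigenvector-participation reading of the same name. NaN for nodes
    with zero strength.
    """
    adjacency, weights = _as_matrices(net)
    if variant == "disparity":
        strength = weights.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ipr = ((weights / strength[:, None]) ** 2).sum(axis=1)
        ipr[strength == 0] = np.nan
        return ipr
    if variant == "fiedler":
        vec = fiedler_vector(weights)
        return vec ** 4
    raise ValueError(f"unknown IPR variant {variant!r}")


class CentralityProfiler(BaseEstimator, TransformerMixin):
    """Compute the 12-measure node-centrality profile of a network.

    Parameters
    ----------
    weighted_distance : {'inverse', 'chordal'}, default 'inverse'
        Edge length for weighted shortest paths: 1/w, or the chordal
        distance recovered from the weight.
    ipr_variant : {'disparity', 'fiedler'}, default 'disparity'
    on_disconnected : {'raise', 'giant'}, default 'raise'
        Policy for spectral measures on disconnected networks.
    """

    def __init__(self, weighted_distance: str = "inverse",
                 ipr_variant: str = "disparity",
                 on_disconnected: str = "raise"):
        self.weighted_distance = weighted_distance
        self.ipr_variant = ipr_variant
        self.on_disconnected = on_disconnected

    def fit(self, net, y=None):
        return self

    def transform(self, net: CorrelationNetwork) -> pd.DataFrame:
        """Node x measure DataFrame; undefined entries are NaN."""
        adjacency, weights = _as_matrices(net)
        pair = (adjacency, weights)
        degree, strength = degree_strength(pair)
        knn, snn = nn_degree_strength(pair, degree, strength)
        columns = {
            "degree": degree,
            "strength": strength,
            "nn_degree": knn,
            "nn_strength": snn,
            "closeness": closeness(pair, "topo"),
            "w_closeness": closeness(pair, "weighted", self.weighted_distance),
            "betweenness": betweenness(pair, "topo"),
            "w_betweenness": betweenness(pair, "weighted", self.weighted_distance),
            "clustering": clustering_coefficient(pair),
            "ipr": self._ipr(pair),
            "spectral": spectral_centrality(pair, "topo", self.on_disconnected),
            "w_spectral": spectral_centrality(pair, "weighted",
                                              self.on_disconnected),
        }
        index = (net.feature_ids if isinstance(net, CorrelationNetwork)
                 else pd.RangeIndex(adjacency.shape[0]))
        profile = pd.DataFrame(columns, index=index)[list(MEASURES)]
        profile.index.name = "feature_id"
        return profile

    def fit_transform(self, net, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(net).transform(net)

    def _ipr(self, pair) -> np.ndarray:
        try:
            return inverse_participation_ratio(pair, self.ipr_variant)
        except ValueError:
            # Fiedler-variant IPR on a disconnected network
            if self.on_disconnected != "giant":
                raise
            return np.full(pair[0].shape[0], np.nan)


def centrality_profile(net, weighted_distance: str = "inverse",
                       ipr_variant: str = "disparity") -> pd.DataFrame:
    """Functional wrapper around :class:`CentralityProfiler`."""
    profiler = CentralityProfiler(weighted_distance=weighted_distance,
                                  ipr_variant=ipr_variant)
    return profiler.fit_transform(net)


def write_profile(profile: pd.DataFrame, path, conventions: dict | None = None) -> None:
    """Export a profile as CSV with 'NA' for undefined entries, plus JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    profile.to_csv(path, na_rep="NA")
    meta = {"measures": list(profile.columns),
            "missing_sentinel": "NA",
            "conventions": conventions or {}}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
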