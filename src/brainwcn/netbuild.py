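"""Weighted correlation network construction.

A group-level network is built from a subjects-by-features table in four
steps: (1) every feature becomes a node; (2) the pairwise Spearman rank
correlation matrix r_S is computed across subjects; (3) node pairs whose
r_S exceeds the empirical q-quantile (default q = 0.85) of the whole
off-diagonal correlation distribution are linked, which fixes the link
density at 1 - q regardless of the correlation scale; (4) each link gets
a similarity weight w = exp(-S^2 / sigma^2) from the chordal distance
S = sin(arccos(r_S) / 2), which maps r_S in [-1, 1] to S in [0, 1].

Because every step depends on the data only through ranks, the resulting
networks are invariant under any strictly monotone per-feature transform
of the input (log, power, normalization by a constant, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .schema import FeatureTable

__all__ = [
    "CorrelationMatrix",
    "CorrelationNetwork",
    "CorrelationNetworkBuilder",
    "spearman_matrix",
    "threshold_adjacency",
    "chordal_weights",
    "build_network",
]


@dataclass
class CorrelationMatrix:
    """Symmetric features-by-features Spearman correlation matrix."""

    values: np.ndarray
    feature_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.feature_ids):
            raise ValueError("correlation matrix / feature_ids shape mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries (each unordered pair once)."""
        iu = np.triu_indices(self.n_features, k=1)
        return self.values[iu]


@dataclass
class CorrelationNetwork:
    """Paired binary (A) and weighted (W) network over one node set.

    ``A`` and ``W`` share the sparsity pattern exactly: W_ij > 0 iff
    A_ij = 1. Both are symmetric with zero diagonal.
    """

    adjacency: np.ndarray
    weights: np.ndarray
    feature_ids: list[str]
    source: CorrelationMatrix
    threshold: float
    quantile: float
    sigma: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def components(self) -> tuple[int, np.ndarray]:
        """Number of connected components and per-node component labels."""
        n, labels = connected_components(self.adjacency, directed=False)
        return int(n), labels

    @property
    def is_connected(self) -> bool:
        return self.components()[0] == 1

    # -- exports -----------------------------------------------------------
    def edge_list(self) -> pd.DataFrame:
        """Weighted edge list (i, j, rS, S, w), one row per unordered pair."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        r = self.source.values[iu, ju]
        chord = np.sin(0.5 * np.arccos(np.clip(r, -1.0, 1.0)))
        ids = np.asarray(self.feature_ids)
        return pd.DataFrame({
            "i": ids[iu], "j": ids[ju], "rS": r, "S": chord,
            "w": self.weights[iu, ju],
        })

    def to_networkx(self, weighted: bool = True):
        import networkx as nx

        graph = nx.Graph()
        graph.add_nodes_from(self.feature_ids)
        ids = np.asarray(self.feature_ids)
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        if weighted:
            graph.add_weighted_edges_from(
                zip(ids[iu], ids[ju], self.weights[iu, ju]))
        else:
            graph.add_edges_from(zip(ids[iu], ids[ju]))
        return graph

    def write(self, prefix) -> list:
        """Export edge list TSV, adjacency MTX, and GraphML under a path prefix."""
        import networkx as nx
        from pathlib import Path
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = []
        edge_path = prefix.with_suffix(".edges.tsv")
        self.edge_list().to_csv(edge_path, sep="\t", index=False)
        paths.append(edge_path)
        mtx_path = prefix.with_suffix(".adjacency.mtx")
        mmwrite(str(mtx_path), csr_matrix(self.adjacency))
        paths.append(mtx_path)
        gml_path = prefix.with_suffix(".graphml")
        graph = self.to_networkx(weighted=True)
        nx.write_graphml(graph, gml_path)
        paths.append(gml_path)
        return paths


def spearman_matrix(table: FeatureTable | pd.DataFrame,
                    include_normalizers: bool = False) -> CorrelationMatrix:
    """Pairwise Spearman correlation across subjects, ties mid-ranked.

    Raises ``ValueError`` for a constant feature (its rank variance is
    zero, so its correlations are undefined).
    """
    if isinstance(table, FeatureTable):
        values = table.node_values(include_normalizers)
    else:
        values = table
    if values.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a correlation network")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 features")
    arr = values.to_numpy(dtype=float)
    constant = np.ptp(arr, axis=0) == 0
    if constant.any():
        name = values.columns[np.flatnonzero(constant)[0]]
        raise ValueError(f"constant feature {name!r}: Spearman undefined")
    rho = np.asarray(stats.spearmanr(arr).statistic, dtype=float)
    if rho.ndim == 0:  # scipy returns a scalar for exactly two features
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(rho, list(values.columns))


def threshold_adjacency(corr: CorrelationMatrix, q: float = 0.85
                        ) -> tuple[np.ndarray, float]:
    """Quantile-threshold a correlation matrix into a binary adjacency.

    Exactly the ``m = P - 1 - floor(q * (P - 1))`` most strongly
    correlated of the P unordered off-diagonal pairs are linked (signed
    correlations, so negative pairs can never link at high q). When all
    pair values are distinct this is identical to linking pairs whose
    r_S strictly exceeds the empirical q-quantile (linear
    interpolation); when values are tied at the cut, ties are broken
    deterministically by pair index so that the link count — and hence
    the link density 1 - q and the mean degree — is the same for every
    network of the same size. That fixed density is what makes the
    whole-network degree comparison a built-in negative control.

    Returns ``(A, t)`` with t the smallest linked correlation value.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    offdiag = corr.off_diagonal()
    if np.ptp(offdiag) == 0:
        raise ValueError("degenerate correlation distribution: all values equal")
    n_pairs = offdiag.size
    n_links = n_pairs - 1 - int(np.floor(q * (n_pairs - 1)))
    if n_links < 1:
        raise ValueError(f"quantile {q} leaves no links for {n_pairs} pairs")
    order = np.argsort(-offdiag, kind="stable")  # desc r, ties by pair index
    linked = order[:n_links]
    t = float(offdiag[linked[-1]])
    n = corr.n_features
    iu = np.triu_indices(n, k=1)
    adjacency = np.zeros((n, n), dtype=np.int8)
    rows, cols = iu[0][linked], iu[1][linked]
    adjacency[rows, cols] = 1
    adjacency[cols, rows] = 1
    return adjacency, t


def chordal_weights(corr: CorrelationMatrix, adjacency: np.ndarray,
                    sigma: float = 1.0, tol: float = 1e-8) -> np.ndarray:
    """Gaussian similarity weights from the chordal distance on linked pairs.

    W_ij = exp(-S_ij^2 / sigma^2) with S_ij = sin(arccos(r_ij) / 2) where
    A_ij = 1, zero elsewhere. Correlations outside [-1, 1] beyond ``tol``
    raise; values within tolerance are clamped.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.asarray(corr.values, dtype=float)
    if np.abs(r).max() > 1.0 + tol:
        raise ValueError("correlation outside [-1, 1] beyond tolerance")
    r = np.clip(r, -1.0, 1.0)
    chord = np.sin(0.5 * np.arccos(r))
    weights = np.exp(-(chord ** 2) / sigma ** 2)
    weights = np.where(adjacency > 0, weights, 0.0)
    np.fill_diagonal(weights, 0.0)
    return weights


class CorrelationNetworkBuilder(BaseEstimator):
    """Estimator building a :class:`CorrelationNetwork` from a feature table.

    Parameters
    ----------
    quantile : float, default 0.85
        Correlation quantile used as link threshold; link density is
        1 - quantile up to pair-count rounding.
    sigma : float, default 1.0
        Width of the Gaussian similarity kernel on the chordal distance.
    include_normalizers : bool, default False
        Whether normalizer columns (e.g. total brain volume) become nodes.

    Attributes
    ----------
    correlation_ : CorrelationMatrix
    network_ : CorrelationNetwork
    threshold_ : float
    density_ : float
    n_components_ : int
    """

    def __init__(self, quantile: float = 0.85, sigma: float = 1.0,
                 include_normalizers: bool = False):
        self.quantile = quantile
        self.sigma = sigma
        self.include_normalizers = include_normalizers

    def fit(self, table: FeatureTable | pd.DataFrame, y=None):
        corr = spearman_matrix(table, include_normalizers=self.include_normalizers)
        adjacency, threshold = threshold_adjacency(corr, self.quantile)
        weights = chordal_weights(corr, adjacency, self.sigma)
        net = CorrelationNetwork(adjacency, weights, corr.feature_ids, corr,
                                 threshold, self.quantile, self.sigma)
        n_comp, labels = net.components()
        if n_comp > 1:
            sizes = np.bincount(labels)
            warnings.warn(
                f"network has {n_comp} connected components "
                f"(sizes {sorted(sizes, reverse=True)[:5]}); distance-based "
                "centralities will use per-component scaling")
        self.correlation_ = corr
        self.network_ = net
        self.threshold_ = threshold
        self.density_ = net.density
        self.n_components_ = n_comp
        self.feature_ids_ = list(corr.feature_ids)
        return self

    def fit_network(self, table) -> CorrelationNetwork:
        return self.fit(table).network_


def build_network(table: FeatureTable | pd.DataFrame, quantile: float = 0.85,
                  sigma: float = 1.0, include_normalizers: bool = False
                  ) -> CorrelationNetwork:
    """Functional wrapper around :class:`CorrelationNetworkBuilder`."""
    builder = CorrelationNetworkBuilder(quantile=quantile, sigma=sigma,
                                        include_normalizers=include_normalizers)
    return builder.fit_network(table)
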