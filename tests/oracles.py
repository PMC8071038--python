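"""Brute-force reference implementations used to cross-check the package.

Everything here is deliberately naive — exhaustive path enumeration,
triple loops, rank-then-Pearson — and shares no code with the library
under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def rank_average_ties(values):
    """Ranks with mid-rank ties, 1-based, by explicit sorting."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(x, y):
    """Spearman correlation as Pearson on mid-ranked data."""
    rx, ry = rank_average_ties(x), rank_average_ties(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


def degree_strength_brute(A, W):
    n = len(A)
    K = [sum(A[i][j] for j in range(n)) for i in range(n)]
    S = [sum(W[i][j] for j in range(n)) for i in range(n)]
    return K, S


def nn_brute(A, K, S):
    n = len(A)
    knn, snn = [], []
    for i in range(n):
        nb = [j for j in range(n) if A[i][j]]
        if not nb:
            knn.append(float("nan"))
            snn.append(float("nan"))
        else:
            knn.append(sum(K[j] for j in nb) / len(nb))
            snn.append(sum(S[j] for j in nb) / len(nb))
    return knn, snn


def _simple_paths(A, src, dst):
    """All simple paths src -> dst on an adjacency matrix (n <= ~8)."""
    n = len(A)
    paths = []

    def extend(path):
        last = path[-1]
        if last == dst:
            paths.append(list(path))
            return
        for nxt in range(n):
            if A[last][nxt] and nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([src])
    return paths


def shortest_paths_brute(A, lengths, src, dst, tol=1e-12):
    """(min length, list of minimal paths) by exhaustive enumeration."""
    paths = _simple_paths(A, src, dst)
    if not paths:
        return float("inf"), []
    costs = [sum(lengths[p[k]][p[k + 1]] for k in range(len(p) - 1))
             for p in paths]
    best = min(costs)
    minimal = [p for p, c in zip(paths, costs) if c <= best * (1 + tol) + tol]
    return best, minimal


def closeness_brute(A, lengths):
    """(N-1) / sum of shortest-path distances, connected graphs only."""
    n = len(A)
    out = []
    for i in range(n):
        total = 0.0
        for j in range(n):
            if j == i:
                continue
            d, _ = shortest_paths_brute(A, lengths, i, j)
            total += d
        out.append((n - 1) / total)
    return out


def betweenness_brute(A, lengths):
    """Freeman betweenness with 1/C(N-1,2) normalization, endpoints excluded."""
    n = len(A)
    score = [0.0] * n
    for j1, j2 in itertools.combinations(range(n), 2):
        _, minimal = shortest_paths_brute(A, lengths, j1, j2)
        if not minimal:
            continue
        for i in range(n):
            if i in (j1, j2):
                continue
            through = sum(1 for p in minimal if i in p)
            score[i] += through / len(minimal)
    norm = (n - 1) * (n - 2) / 2
    return [s / norm for s in score]


def clustering_brute(A):
    """Triangle fraction by triple loop; NaN where degree < 2."""
    n = len(A)
    out = []
    for i in range(n):
        nb = [j for j in range(n) if A[i][j]]
        k = len(nb)
        if k < 2:
            out.append(float("nan"))
            continue
        tri = sum(1 for a, b in itertools.combinations(nb, 2) if A[a][b])
        out.append(tri / (k * (k - 1) / 2))
    return out


def ipr_brute(W):
    """Edge-weight disparity sum_j (w_ij / s_i)^2; NaN for zero strength."""
    n = len(W)
    out = []
    for i in range(n):
        s = sum(W[i])
        if s == 0:
            out.append(float("nan"))
        else:
            out.append(sum((w / s) ** 2 for w in W[i]))
    return out


def spectral_brute(M):
    """SC_i = sum_j M_ij (v_i - v_j)^2, v the unit Fiedler vector of D - M.

    Uses numpy.linalg.eigh on the explicitly assembled Laplacian with the
    same first-nonzero-entry-positive sign convention.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            L[i][j] = (sum(M[i]) if i == j else 0.0) - M[i][j]
    eigvals, eigvecs = np.linalg.eigh(L)
    v = eigvecs[:, 1]
    for entry in v:
        if abs(entry) > 1e-12:
            if entry < 0:
                v = -v
            break
    return [sum(M[i][j] * (v[i] - v[j]) ** 2 for j in range(n))
            for i in range(n)]


def ks_statistic_brute(a, b):
    """Two-sample KS statistic as the max ECDF gap over all data points."""
    a, b = sorted(a), sorted(b)

    def ecdf(sample, x):
        return sum(1 for v in sample if v <= x) / len(sample)

    grid = a + b
    return max(abs(ecdf(a, x) - ecdf(b, x)) for x in grid)
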