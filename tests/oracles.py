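"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles —
exact rational arithmetic, Floyd-Warshall, dense linear solves — and
shares no code with the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, inf

import numpy as np


def exact_hypergeom_tail(T: int, t: int, N: int, r: int) -> Fraction:
    """P(X >= r), X ~ Hypergeometric(T, t, N), as an exact rational."""
    num = sum(comb(t, k) * comb(T - t, N - k) for k in range(r, min(t, N) + 1) if N - k <= T - t)
    return Fraction(num, comb(T, N))


def pairwise_distances_and_counts(adj: dict):
    """Floyd-Warshall distances plus shortest-path counts for an
    undirected, unweighted graph given as {node: set(neighbors)}."""
    nodes = sorted(adj)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for v, nbrs in adj.items():
        for w in nbrs:
            dist[idx[v]][idx[w]] = 1
    for k in range(n):
        for i in range(n):
            dik = dist[i][k]
            if dik is inf:
                continue
            for j in range(n):
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    # path counts by dynamic programming in order of distance
    sigma = [[0] * n for _ in range(n)]
    for s in range(n):
        sigma[s][s] = 1
        order = sorted((d, j) for j, d in enumerate(dist[s]) if d is not inf and j != s)
        for d, j in order:
            sigma[s][j] = sum(
                sigma[s][idx[w]]
                for w in adj[nodes[j]]
                if dist[s][idx[w]] == d - 1
            )
    return nodes, dist, sigma


def brute_force_centralities(adj: dict):
    """Degree, normalized betweenness, and Wasserman-Faust closeness by
    exhaustive shortest-path enumeration."""
    nodes, dist, sigma = pairwise_distances_and_counts(adj)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    degree = {v: len(adj[v]) for v in nodes}

    betweenness = {}
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    for v in nodes:
        vi = idx[v]
        total = 0.0
        for si in range(n):
            for ti in range(si + 1, n):
                if si == vi or ti == vi or dist[si][ti] is inf:
                    continue
                if dist[si][vi] + dist[vi][ti] == dist[si][ti]:
                    total += sigma[si][vi] * sigma[vi][ti] / sigma[si][ti]
        betweenness[v] = total * scale

    closeness = {}
    for v in nodes:
        vi = idx[v]
        reach = [dist[vi][j] for j in range(n) if j != vi and dist[vi][j] is not inf]
        k = len(reach)
        if k == 0 or n == 1:
            closeness[v] = 0.0
        else:
            closeness[v] = (k / sum(reach)) * (k / (n - 1))
    return degree, betweenness, closeness


def dense_rwr_fixed_point(adj_matrix: np.ndarray, p0: np.ndarray, restart: float) -> np.ndarray:
    """Direct linear solve of p = (1-r) W p + r p0 with W column-normalized."""
    colsum = adj_matrix.sum(axis=0)
    W = np.divide(adj_matrix, colsum, out=np.zeros_like(adj_matrix, dtype=float), where=colsum > 0)
    n = W.shape[0]
    return restart * np.linalg.solve(np.eye(n) - (1.0 - restart) * W, p0)


def paired_t_pvalues(ec: np.ndarray, eu: np.ndarray):
    """Textbook paired t-test, feature-wise, computed from the definition."""
    d = ec - eu
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    t = mean / (sd / np.sqrt(n))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(np.abs(t), df=n - 1)
    return t, p
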