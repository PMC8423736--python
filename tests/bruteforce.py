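"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package (and of
networkx's centrality functions): shortest paths come from
Floyd-Warshall on the dense adjacency matrix, betweenness from explicit
shortest-path counting, PageRank from dense power iteration on the
Google matrix.
"""

from __future__ import annotations

import numpy as np


def adjacency(G) -> tuple[list, np.ndarray]:
    nodes = list(G.nodes)
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v in G.edges():
        A[pos[u], pos[v]] = 1.0
        if not G.is_directed():
            A[pos[v], pos[u]] = 1.0
    return nodes, A


def floyd_warshall(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    D[A > 0] = 1.0
    for k in range(n):
        D = np.minimum(D, D[:, k : k + 1] + D[k : k + 1, :])
    return D


def closeness_oracle(G) -> dict:
    """Wasserman-Faust closeness over reachable nodes (outward
    distances)."""
    nodes, A = adjacency(G)
    D = floyd_warshall(A)
    n = len(nodes)
    out = {}
    for i, v in enumerate(nodes):
        d = np.delete(D[i], i)
        reach = np.isfinite(d)
        r = int(reach.sum())
        if r == 0 or n == 1:
            out[v] = 0.0
        else:
            out[v] = (r / d[reach].sum()) * (r / (n - 1))
    return out


def eccentricity_oracle(G) -> dict:
    nodes, A = adjacency(G)
    D = floyd_warshall(A)
    out = {}
    for i, v in enumerate(nodes):
        d = np.delete(D[i], i)
        finite = d[np.isfinite(d)]
        out[v] = int(finite.max()) if finite.size else 0
    return out


def _path_counts(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of shortest s->t paths."""
    n = A.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(D[s])
        for t in order:
            if t == s or not np.isfinite(D[s, t]):
                continue
            preds = [u for u in range(n) if A[u, t] > 0 and D[s, u] == D[s, t] - 1]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    return sigma


def betweenness_oracle(G) -> dict:
    """Raw (unnormalized) shortest-path betweenness; unordered pairs
    for undirected graphs, ordered for directed."""
    nodes, A = adjacency(G)
    D = floyd_warshall(A)
    sigma = _path_counts(A, D)
    n = len(nodes)
    out = dict.fromkeys(range(n), 0.0)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(D[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if (
                    np.isfinite(D[s, v])
                    and np.isfinite(D[v, t])
                    and D[s, v] + D[v, t] == D[s, t]
                ):
                    out[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if not G.is_directed():
        out = {v: c / 2.0 for v, c in out.items()}
    return {nodes[i]: out[i] for i in range(n)}


def pagerank_oracle(G, alpha: float = 0.85, tol: float = 1e-14) -> dict:
    nodes, A = adjacency(G)
    n = len(nodes)
    if n == 0:
        return {}
    outdeg = A.sum(axis=1)
    M = np.where(outdeg[:, None] > 0, A / np.where(outdeg[:, None] > 0, outdeg[:, None], 1.0), 1.0 / n)
    p = np.ones(n) / n
    for _ in range(100000):
        p_new = alpha * (p @ M) + (1.0 - alpha) / n
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    return dict(zip(nodes, p))


def rank_sum_exact_p(x, y, alternative: str = "two-sided") -> float:
    """Exact Wilcoxon rank-sum p-value by full enumeration (tiny n
    only)."""
    import itertools

    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = _midranks(pooled)
    obs = sum(ranks[i] for i in range(n1))
    stats_all = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), n1)
    ]
    stats_all = np.array(stats_all)
    if alternative == "greater":
        return float(np.mean(stats_all >= obs))
    if alternative == "less":
        return float(np.mean(stats_all <= obs))
    mean = stats_all.mean()
    return float(np.mean(np.abs(stats_all - mean) >= abs(obs - mean)))


def _midranks(values) -> list[float]:
    order = np.argsort(values, kind="stable")
    ranks = [0.0] * len(values)
    i = 0
    sorted_vals = [values[j] for j in order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks
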