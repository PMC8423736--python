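"""Directed acyclic "QTL networks" over significant SNPs.

The phenotype is first put into a SNP-based representation: for each
significant SNP, every host is assigned the mean phenotype of its
genotype group at that SNP (the genotype-mean transform). A Bayesian
network over these columns is then learned by greedy hill climbing on
the Gaussian BIC score with add/delete/reverse moves, a parent-count
cap, and random restarts. High-degree nodes of the learned DAG are
reported as hub QTLs.

Edge directions are statistical dependency orientations chosen by the
score; they are not claims of biological causality.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from rhizonet.errors import StructureError

__all__ = [
    "genotype_mean_transform",
    "score_dag",
    "local_score",
    "learn_bn",
    "hub_qtls",
    "QtlNetwork",
    "enumerate_dags",
]

_VAR_FLOOR = 1e-12


def genotype_mean_transform(y, hit_calls: pd.DataFrame) -> pd.DataFrame:
    """Replace each host's genotype at each SNP by its genotype-group
    phenotype mean.

    ``hit_calls`` is hosts x significant SNPs with 0/1 (possibly
    imputed) calls; calls are split at 0.5 so every column takes at
    most two distinct values. Monomorphic columns become constant and
    are flagged in ``df.attrs["constant_columns"]``.
    """
    y = np.asarray(y, dtype=float)
    X = hit_calls.to_numpy(dtype=float)
    if X.shape[0] != y.shape[0]:
        raise StructureError("phenotype and genotype host counts differ")
    out = np.empty_like(X)
    constant = []
    for j in range(X.shape[1]):
        carrier = X[:, j] > 0.5
        if carrier.all() or (~carrier).all():
            out[:, j] = y.mean()
            constant.append(hit_calls.columns[j])
            continue
        out[carrier, j] = y[carrier].mean()
        out[~carrier, j] = y[~carrier].mean()
    df = pd.DataFrame(out, index=hit_calls.index, columns=hit_calls.columns)
    df.attrs["constant_columns"] = constant
    return df


def local_score(data: np.ndarray, child: int, parents: tuple[int, ...]) -> float:
    """Gaussian BIC contribution of one node given its parents.

    Log-likelihood of the child regressed on its parents (with
    intercept, MLE variance) minus (log n / 2) * k, where k counts the
    regression coefficients, the intercept, and the variance.
    """
    n = data.shape[0]
    yj = data[:, child]
    if parents:
        Z = np.column_stack([np.ones(n), data[:, list(parents)]])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
    else:
        resid = yj - yj.mean()
    sigma2 = max(float(resid @ resid) / n, _VAR_FLOOR)
    ll = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    k = len(parents) + 2
    return ll - 0.5 * math.log(n) * k


def score_dag(data, dag) -> float:
    """Total Gaussian BIC of a DAG over the data columns (higher is
    better; decomposes as a sum of per-node local scores)."""
    arr, _ = _as_array(data)
    G = _as_digraph(dag, arr.shape[1])
    if not nx.is_directed_acyclic_graph(G):
        raise StructureError("graph must be acyclic")
    total = 0.0
    for j in range(arr.shape[1]):
        parents = tuple(sorted(G.predecessors(j)))
        total += local_score(arr, j, parents)
    return total


def _as_array(data) -> tuple[np.ndarray, list]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    return arr, list(range(arr.shape[1]))


def _as_digraph(dag, k: int) -> nx.DiGraph:
    if isinstance(dag, nx.DiGraph):
        return dag
    G = nx.DiGraph()
    G.add_nodes_from(range(k))
    G.add_edges_from(dag)
    return G


@dataclass
class QtlNetwork:
    """Learned DAG over SNP nodes with its score and hub annotations."""

    graph: nx.DiGraph
    score: float
    node_ids: list
    hub_ids: list = field(default_factory=list)
    excluded_constant: list = field(default_factory=list)


class _HillClimber:
    """Greedy add/delete/reverse search with cached local scores."""

    def __init__(self, data: np.ndarray, max_parents: int):
        self.data = data
        self.k = data.shape[1]
        self.max_parents = max_parents
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, child: int, parents: frozenset[int]) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            self._cache[key] = local_score(self.data, child, key[1])
        return self._cache[key]

    def climb(self, G: nx.DiGraph) -> tuple[nx.DiGraph, float]:
        parents = {j: frozenset(G.predecessors(j)) for j in range(self.k)}
        score = sum(self.local(j, parents[j]) for j in range(self.k))
        while True:
            best_delta, best_move = 1e-9, None
            for u, v in itertools.permutations(range(self.k), 2):
                if G.has_edge(u, v):
                    # delete u -> v
                    delta = self.local(v, parents[v] - {u}) - self.local(v, parents[v])
                    if delta > best_delta:
                        best_delta, best_move = delta, ("del", u, v)
                    # reverse u -> v (cycle iff another u ~> v path exists)
                    if len(parents[u]) < self.max_parents:
                        G.remove_edge(u, v)
                        ok = not nx.has_path(G, u, v)
                        G.add_edge(u, v)
                        if ok:
                            delta = (
                                self.local(v, parents[v] - {u})
                                - self.local(v, parents[v])
                                + self.local(u, parents[u] | {v})
                                - self.local(u, parents[u])
                            )
                            if delta > best_delta:
                                best_delta, best_move = delta, ("rev", u, v)
                else:
                    # add u -> v (cycle iff v ~> u path exists)
                    if len(parents[v]) >= self.max_parents:
                        continue
                    if nx.has_path(G, v, u):
                        continue
                    delta = self.local(v, parents[v] | {u}) - self.local(v, parents[v])
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", u, v)
            if best_move is None:
                return G, score
            op, u, v = best_move
            if op == "add":
                G.add_edge(u, v)
                parents[v] = parents[v] | {u}
            elif op == "del":
                G.remove_edge(u, v)
                parents[v] = parents[v] - {u}
            else:
                G.remove_edge(u, v)
                G.add_edge(v, u)
                parents[v] = parents[v] - {u}
                parents[u] = parents[u] | {v}
            score += best_delta


def _random_dag(rng: np.random.Generator, k: int, max_parents: int) -> nx.DiGraph:
    order = rng.permutation(k)
    G = nx.DiGraph()
    G.add_nodes_from(range(k))
    for j_pos in range(1, k):
        v = int(order[j_pos])
        ancestors = [int(order[i]) for i in range(j_pos)]
        n_par = min(len(ancestors), max_parents)
        for u in ancestors:
            if G.in_degree(v) >= n_par:
                break
            if rng.random() < 0.25:
                G.add_edge(u, v)
    return G


def learn_bn(
    data,
    max_parents: int = 3,
    restarts: int = 10,
    seed: int = 0,
) -> QtlNetwork:
    """Best-scoring DAG by hill climbing with random restarts.

    Constant columns are excluded with a warning; fewer than two usable
    columns yields an empty network. Deterministic given ``seed``.
    """
    arr, cols = _as_array(data)
    keep = [j for j in range(arr.shape[1]) if float(np.var(arr[:, j])) > _VAR_FLOOR]
    excluded = [cols[j] for j in range(arr.shape[1]) if j not in keep]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} constant columns from BN learning",
            stacklevel=2,
        )
    node_ids = [cols[j] for j in keep]
    if len(keep) < 2:
        G = nx.DiGraph()
        G.add_nodes_from(node_ids)
        return QtlNetwork(
            graph=G, score=float("nan"), node_ids=node_ids,
            excluded_constant=excluded,
        )
    sub = arr[:, keep]
    climber = _HillClimber(sub, max_parents)
    rng = np.random.default_rng(seed)
    best_G, best_score = None, -np.inf
    for r in range(max(1, restarts)):
        if r == 0:
            start = nx.DiGraph()
            start.add_nodes_from(range(len(keep)))
        else:
            start = _random_dag(rng, len(keep), max_parents)
        G, score = climber.climb(start)
        if score > best_score + 1e-12:
            best_G, best_score = G.copy(), score
    relabeled = nx.relabel_nodes(best_G, dict(enumerate(node_ids)), copy=True)
    assert nx.is_directed_acyclic_graph(relabeled)
    return QtlNetwork(
        graph=relabeled,
        score=float(best_score),
        node_ids=node_ids,
        excluded_constant=excluded,
    )


def hub_qtls(
    net: QtlNetwork | nx.DiGraph,
    quantile: float = 0.90,
    degree_cutoff: float | None = None,
) -> list:
    """Nodes whose total degree strictly exceeds the cutoff.

    Default cutoff is the ``quantile`` of total degree among
    non-isolated nodes (``quantile = 0`` disables it); an absolute
    ``degree_cutoff`` overrides the quantile. Edgeless networks give an
    empty list.
    """
    G = net.graph if isinstance(net, QtlNetwork) else net
    if G.number_of_edges() == 0:
        return []
    deg = dict(G.degree())
    non_isolated = {n: d for n, d in deg.items() if d > 0}
    if degree_cutoff is None:
        degs = np.array(list(non_isolated.values()), dtype=float)
        degree_cutoff = -np.inf if quantile == 0 else float(np.quantile(degs, quantile))
    return sorted((n for n, d in non_isolated.items() if d > degree_cutoff), key=str)


def enumerate_dags(k: int):
    """All labeled DAGs on k nodes as edge tuples (oracle-scale only:
    543 DAGs at k = 4)."""
    pairs = list(itertools.permutations(range(k), 2))
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        edges = tuple(p for p, b in zip(pairs, bits) if b)
        G = nx.DiGraph()
        G.add_nodes_from(range(k))
        G.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(G):
            yield edges
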