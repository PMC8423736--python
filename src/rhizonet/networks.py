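"""Interaction networks, node centralities, and emergent indices.

After thresholding, each host carries one network per interaction type:
mutualism and antagonism as undirected graphs, aggression and altruism
as directed graphs whose edges point from the more abundant to the less
abundant member. All OTUs of the panel stay in the graph, so isolated
nodes count toward network-level averages.

All centralities are computed on the unweighted topology (an edge is
present or absent after thresholding); edge weights are retained only
for export. Conventions for disconnected graphs:

* closeness uses the Wasserman-Faust correction
  ``(r / sum of distances to the r reachable nodes) * (r / (N - 1))``,
  with outward distances on directed graphs and 0 for sink/isolated
  nodes;
* eccentricity is the maximum distance to reachable nodes (0 when none);
* betweenness is the raw shortest-path count (normalization off);
* eigencentrality is the leading eigenvector of the symmetrized
  adjacency scaled to max 1 (all zero for an edgeless graph);
* PageRank uses damping 0.85.

The six emergent indices of a network are its edge density (``Con``)
and the mean of each of the five node centralities; with four
interaction types they form the 24 quantitative phenotypes used for
association mapping.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from rhizonet import descriptors as desc
from rhizonet.errors import UndefinedTestError
from rhizonet.io import AbundanceMatrix

EMERGENT_INDICES = (
    "Con",
    "Closeness",
    "Betweenness",
    "Eccentricity",
    "Eigencentrality",
    "PageRank",
)

CENTRALITY_COLUMNS = (
    "degree",
    "closeness",
    "betweenness",
    "eccentricity",
    "eigencentrality",
    "pagerank",
)

__all__ = [
    "EMERGENT_INDICES",
    "CENTRALITY_COLUMNS",
    "build_network",
    "node_centralities",
    "emergent_indices",
    "index_table",
    "phenotype_columns",
    "kingdom_degree_test",
    "interkingdom_edges",
    "consensus_network",
]


def build_network(
    sparse: desc.SparseInteractionMatrix, taxonomy: pd.DataFrame | None = None
) -> nx.Graph:
    """Graph over the full OTU panel from a thresholded matrix.

    Aggression and altruism give directed graphs (more abundant ->
    less abundant); mutualism and antagonism undirected. Nodes carry
    kingdom/phylum/class attributes where the taxonomy knows them.
    """
    G: nx.Graph = nx.DiGraph() if sparse.type in desc.DIRECTED_TYPES else nx.Graph()
    G.graph["interaction_type"] = sparse.type
    if sparse.host_id is not None:
        G.graph["host_id"] = str(sparse.host_id)
    unknown = []
    for otu in sparse.otu_ids:
        if taxonomy is not None and otu in taxonomy.index:
            row = taxonomy.loc[otu]
            G.add_node(
                otu,
                kingdom=str(row["kingdom"]),
                phylum=str(row["phylum"]),
                taxon_class=str(row["class"]),
            )
        else:
            if taxonomy is not None:
                unknown.append(otu)
            G.add_node(otu, kingdom="unknown", phylum="unknown", taxon_class="unknown")
    if unknown:
        warnings.warn(f"{len(unknown)} OTUs missing from taxonomy", stacklevel=2)
    for u, v, w in sparse.entries.itertuples(index=False):
        if u == v:
            continue
        G.add_edge(u, v, weight=float(w))
    return G


def _eigencentrality(G: nx.Graph, nodelist) -> np.ndarray:
    A = nx.to_numpy_array(G, nodelist=nodelist, weight=None)
    A = ((A + A.T) > 0).astype(float)
    if not A.any():
        return np.zeros(len(nodelist))
    w, V = np.linalg.eigh(A)
    vec = V[:, int(np.argmax(w))]
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    top = vec.max()
    return vec / top if top > 0 else vec


def node_centralities(G: nx.Graph) -> pd.DataFrame:
    """Per-node degree, closeness, betweenness, eccentricity,
    eigencentrality and PageRank (see module docstring for
    conventions)."""
    nodes = list(G.nodes)
    N = len(nodes)
    if N == 0:
        return pd.DataFrame(columns=list(CENTRALITY_COLUMNS))
    degree = dict(G.degree())  # total (in + out) for directed graphs
    closeness, eccentricity = {}, {}
    for n in nodes:
        lengths = nx.single_source_shortest_path_length(G, n)
        lengths.pop(n, None)
        r = len(lengths)
        if r == 0 or N == 1:
            closeness[n] = 0.0
            eccentricity[n] = 0
        else:
            total = sum(lengths.values())
            closeness[n] = (r / total) * (r / (N - 1))
            eccentricity[n] = max(lengths.values())
    betweenness = nx.betweenness_centrality(G, normalized=False, weight=None)
    if G.number_of_edges() or N == 1:
        pagerank = nx.pagerank(G, alpha=0.85, tol=1e-12, max_iter=1000, weight=None)
    else:
        pagerank = {n: 1.0 / N for n in nodes}
    eig = _eigencentrality(G, nodes)
    return pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "eccentricity": [eccentricity[n] for n in nodes],
            "eigencentrality": eig,
            "pagerank": [pagerank[n] for n in nodes],
        },
        index=pd.Index(nodes, name="otu_id"),
    )


def emergent_indices(
    G: nx.Graph, centralities: pd.DataFrame | None = None
) -> dict[str, float]:
    """Six network-level indices: edge density plus the mean of each
    node centrality over all nodes (isolated nodes included)."""
    if centralities is None:
        centralities = node_centralities(G)
    con = nx.density(G) if len(G) > 1 else 0.0
    if centralities.empty:
        means = dict.fromkeys(CENTRALITY_COLUMNS[1:], 0.0)
    else:
        means = centralities.mean()
    return {
        "Con": float(con),
        "Closeness": float(means["closeness"]),
        "Betweenness": float(means["betweenness"]),
        "Eccentricity": float(means["eccentricity"]),
        "Eigencentrality": float(means["eigencentrality"]),
        "PageRank": float(means["pagerank"]),
    }


def phenotype_columns(types=desc.INTERACTION_TYPES) -> list[str]:
    return [f"{t}_{i}" for t in types for i in EMERGENT_INDICES]


def host_network(
    transformed_row: np.ndarray,
    otu_ids,
    type: str,
    tau: float | None = None,
    taxonomy: pd.DataFrame | None = None,
    host_id=None,
    bounds: tuple[float, float] | None = None,
) -> nx.Graph:
    """transform -> interaction -> normalize -> threshold -> graph for
    one host vector (already log-transformed)."""
    M = desc.interaction_matrix(transformed_row, type, otu_ids=otu_ids, host_id=host_id)
    M = desc.normalize_matrix(M, bounds=bounds)
    S = desc.threshold_matrix(M, tau)
    return build_network(S, taxonomy)


def index_table(
    abundance: AbundanceMatrix,
    taxonomy: pd.DataFrame | None = None,
    taus: dict[str, float] | None = None,
    scope: str = "per_host",
    types=desc.INTERACTION_TYPES,
) -> pd.DataFrame:
    """Hosts x (types x 6 indices) phenotype table.

    Each host's raw abundances are log10(x+1)-transformed, turned into
    a descriptor matrix per interaction type, min-max normalized (per
    host by default, or with pooled bounds when ``scope="global"``),
    thresholded, and summarized by the six emergent indices. Hosts with
    fewer than two nonzero OTUs get all-zero indices and are flagged in
    ``df.attrs["degenerate_hosts"]``.
    """
    if scope not in ("per_host", "global"):
        raise ValueError(f"unknown normalization scope {scope!r}")
    taus = {**desc.DEFAULT_TAU, **(taus or {})}
    T = desc.transform_abundance(abundance)
    arr = T.values.to_numpy(dtype=float)
    otu_ids = T.otu_ids
    hosts = T.host_ids
    degenerate = [h for h, row in zip(hosts, arr) if (row > 0).sum() < 2]
    bounds: dict[str, tuple[float, float] | None] = dict.fromkeys(types)
    if scope == "global":
        for t in types:
            raws = (
                desc.interaction_matrix(row, t, otu_ids=otu_ids)
                for row, h in zip(arr, hosts)
                if h not in set(degenerate)
            )
            bounds[t] = desc.global_minmax(raws)
    records = []
    for h, row in zip(hosts, arr):
        rec: dict[str, float] = {}
        for t in types:
            if h in set(degenerate):
                rec.update({f"{t}_{i}": 0.0 for i in EMERGENT_INDICES})
                continue
            G = host_network(
                row, otu_ids, t, tau=taus[t], taxonomy=None, host_id=h, bounds=bounds[t]
            )
            idx = emergent_indices(G)
            rec.update({f"{t}_{i}": v for i, v in idx.items()})
        records.append(rec)
    df = pd.DataFrame(records, index=pd.Index(hosts, name="host_id"))
    df = df[phenotype_columns(types)]
    df.attrs["degenerate_hosts"] = degenerate
    df.attrs["normalization_scope"] = scope
    df.attrs["taus"] = {t: taus[t] for t in types}
    return df


def kingdom_degree_test(G: nx.Graph, taxonomy: pd.DataFrame):
    """Wilcoxon rank-sum comparison of node degree, bacteria vs fungi.

    Normal approximation with tie correction and continuity correction
    (two-sided). Returns (statistic, p_value, median_bacteria,
    median_fungi).
    """
    deg = dict(G.degree())
    groups = {"bacteria": [], "fungi": []}
    for n in G.nodes:
        k = taxonomy.loc[n, "kingdom"] if n in taxonomy.index else G.nodes[n].get(
            "kingdom", "unknown"
        )
        if k in groups:
            groups[k].append(deg[n])
    if not groups["bacteria"] or not groups["fungi"]:
        raise UndefinedTestError("both kingdoms must be present for the degree test")
    res = stats.mannwhitneyu(
        groups["bacteria"],
        groups["fungi"],
        alternative="two-sided",
        use_continuity=True,
        method="asymptotic",
    )
    return (
        float(res.statistic),
        float(res.pvalue),
        float(np.median(groups["bacteria"])),
        float(np.median(groups["fungi"])),
    )


def interkingdom_edges(
    G: nx.Graph, taxonomy: pd.DataFrame, level: str = "class"
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Bacteria-fungi edge counts grouped at a taxonomic level.

    Returns the interkingdom table (bacterial group, fungal group,
    count; sorted by count descending) and within-kingdom edge tallies.
    """
    col = level
    counts: dict[tuple[str, str], int] = {}
    within = {"bacteria": 0, "fungi": 0}
    for u, v in G.edges():
        ku = taxonomy.loc[u, "kingdom"] if u in taxonomy.index else "unknown"
        kv = taxonomy.loc[v, "kingdom"] if v in taxonomy.index else "unknown"
        if ku == kv:
            if ku in within:
                within[ku] += 1
            continue
        if {ku, kv} != {"bacteria", "fungi"}:
            continue
        b, f = (u, v) if ku == "bacteria" else (v, u)
        key = (str(taxonomy.loc[b, col]), str(taxonomy.loc[f, col]))
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        [(b, f, c) for (b, f), c in counts.items()],
        columns=[f"bacterial_{col}", f"fungal_{col}", "count"],
    )
    df = df.sort_values(
        ["count", f"bacterial_{col}", f"fungal_{col}"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
    return df, within


def consensus_network(
    abundance: AbundanceMatrix,
    taxonomy: pd.DataFrame | None,
    type: str,
    tau: float | None = None,
) -> nx.Graph:
    """One network per interaction type from across-host mean
    log-transformed abundances (used for hub calling)."""
    T = desc.transform_abundance(abundance)
    mean_vec = T.values.to_numpy(dtype=float).mean(axis=0)
    return host_network(
        mean_vec, T.otu_ids, type, tau=tau, taxonomy=taxonomy, host_id="consensus"
    )
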