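"""Hub taxon detection and hub-related comparisons.

A hub is a node whose degree AND closeness both strictly exceed their
cutoffs. Cutoffs are either absolute values (as printed on a network's
degree/closeness scatter) or quantiles of the metric among non-isolated
nodes (default 0.90). The field names the hub/non-hub roles per
interaction type: leaders/followers (mutualism), antagonists/agonists
(antagonism), hawks/doves (aggression), beneficiaries/altruists
(altruism).

Hub calling runs on the consensus network of each type (built from
across-host mean log abundances); per-host calling simply reuses
:func:`detect_hubs` on a per-host centrality table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rhizonet.errors import UndefinedTestError
from rhizonet.io import AbundanceMatrix

ROLE_LABELS = {
    "mutualism": ("leaders", "followers"),
    "antagonism": ("antagonists", "agonists"),
    "aggression": ("hawks", "doves"),
    "altruism": ("beneficiaries", "altruists"),
}

__all__ = ["ROLE_LABELS", "HubReport", "detect_hubs", "hub_abundance_test", "shared_hubs"]


@dataclass
class HubReport:
    """Hubs of one network with the cutoffs that produced them."""

    network_type: str
    hubs: pd.DataFrame  # index otu_id; degree, closeness (+ taxonomy cols)
    degree_cutoff: float
    closeness_cutoff: float
    mode: str  # "absolute" or "quantile"
    quantiles: tuple[float, float] | None = None
    hub_label: str = ""
    nonhub_label: str = ""
    non_hub_otus: list = field(default_factory=list)

    @property
    def hub_otus(self) -> list:
        return list(self.hubs.index)


def _quantile_cutoff(values: np.ndarray, q: float) -> float:
    # q = 0 disables the cutoff so that every non-isolated node passes
    # the strict comparison.
    if q == 0:
        return -np.inf
    return float(np.quantile(values, q))


def detect_hubs(
    centralities: pd.DataFrame,
    network_type: str = "mutualism",
    taxonomy: pd.DataFrame | None = None,
    degree_cutoff: float | None = None,
    closeness_cutoff: float | None = None,
    degree_quantile: float = 0.90,
    closeness_quantile: float = 0.90,
) -> HubReport:
    """Nodes strictly exceeding both the degree and closeness cutoffs.

    Absolute cutoffs take precedence; otherwise cutoffs are quantiles
    of each metric among non-isolated nodes.
    """
    non_isolated = centralities[centralities["degree"] > 0]
    if degree_cutoff is not None and closeness_cutoff is not None:
        mode, quantiles = "absolute", None
        dcut, ccut = float(degree_cutoff), float(closeness_cutoff)
    else:
        mode = "quantile"
        quantiles = (degree_quantile, closeness_quantile)
        if non_isolated.empty:
            warnings.warn("all nodes isolated: empty hub set", stacklevel=2)
            dcut = ccut = np.inf
        else:
            dcut = _quantile_cutoff(
                non_isolated["degree"].to_numpy(float), degree_quantile
            )
            ccut = _quantile_cutoff(
                non_isolated["closeness"].to_numpy(float), closeness_quantile
            )
    is_hub = (centralities["degree"] > dcut) & (centralities["closeness"] > ccut)
    # isolated nodes can never be hubs
    is_hub &= centralities["degree"] > 0
    hubs = centralities.loc[is_hub, ["degree", "closeness"]].copy()
    if taxonomy is not None:
        for colname in ("kingdom", "phylum", "class"):
            hubs[colname] = [
                str(taxonomy.loc[o, colname]) if o in taxonomy.index else "unknown"
                for o in hubs.index
            ]
    hub_label, nonhub_label = ROLE_LABELS.get(network_type, ("hubs", "others"))
    return HubReport(
        network_type=network_type,
        hubs=hubs,
        degree_cutoff=dcut,
        closeness_cutoff=ccut,
        mode=mode,
        quantiles=quantiles,
        hub_label=hub_label,
        nonhub_label=nonhub_label,
        non_hub_otus=[o for o in centralities.index if not bool(is_hub.loc[o])],
    )


def hub_abundance_test(report: HubReport, abundance: AbundanceMatrix):
    """Rank-sum comparison of mean log10 abundance, hubs vs non-hubs.

    Returns (statistic, one-sided p for hubs more abundant, two-sided
    p, hub group mean, non-hub group mean).
    """
    mean_log = np.log10(abundance.values.to_numpy(float) + 1.0).mean(axis=0)
    per_otu = pd.Series(mean_log, index=abundance.values.columns)
    hub_vals = per_otu.reindex(report.hub_otus).dropna()
    other_vals = per_otu.reindex(report.non_hub_otus).dropna()
    if hub_vals.empty or other_vals.empty:
        raise UndefinedTestError("hub and non-hub groups must both be non-empty")
    greater = stats.mannwhitneyu(
        hub_vals, other_vals, alternative="greater", method="asymptotic"
    )
    two_sided = stats.mannwhitneyu(
        hub_vals, other_vals, alternative="two-sided", method="asymptotic"
    )
    return (
        float(greater.statistic),
        float(greater.pvalue),
        float(two_sided.pvalue),
        float(hub_vals.mean()),
        float(other_vals.mean()),
    )


def shared_hubs(
    reports: dict[str, HubReport], taxonomy: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-network hub overlap.

    Returns (membership, phylum_overlap): membership is OTU x network
    type 0/1 indicators for every OTU that is a hub somewhere;
    phylum_overlap counts the phyla shared by each pair of network
    types' hub sets (diagonal = own phylum count).
    """
    types = list(reports)
    all_hubs = sorted(
        {o for r in reports.values() for o in r.hub_otus}, key=str
    )
    membership = pd.DataFrame(
        {
            t: [int(o in set(reports[t].hub_otus)) for o in all_hubs]
            for t in types
        },
        index=pd.Index(all_hubs, name="otu_id"),
    )
    phyla: dict[str, set] = {}
    for t in types:
        if taxonomy is not None:
            phyla[t] = {
                str(taxonomy.loc[o, "phylum"])
                for o in reports[t].hub_otus
                if o in taxonomy.index
            }
        else:
            phyla[t] = set()
    overlap = pd.DataFrame(
        [[len(phyla[a] & phyla[b]) for b in types] for a in types],
        index=types,
        columns=types,
    )
    return membership, overlap
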