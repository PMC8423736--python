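"""Behavioral descriptors of pairwise microbial interactions.

For two microbes u and v with log-transformed abundances x_u > x_v > 0
in a given host, four closed-form descriptors quantify the ecological
relationship between them:

* mutualism    ``Z_mu = x_u * x_v / (x_u - x_v)`` — cooperation strength,
* antagonism   ``Z_an = 1 / ((x_u * x_v) * (x_u - x_v))`` — competition,
* aggression   ``Z_ag = x_u / x_v`` — exploitation of the weaker partner,
* altruism     ``Z_al = 1 - x_v / x_u`` — sacrifice toward the weaker
  partner.

Each host yields one m x m matrix per descriptor, stored at
(more-abundant, less-abundant); matrices are min-max normalized to
[0, 1] and sparsified by strict threshold filtering (0.95 for
mutualism/antagonism/aggression, 0.99 for altruism by default).

Pairs with tied or zero abundance are excluded: the denominators vanish
and, with continuous abundances, ties have measure zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rhizonet.errors import ConfigError, FormatError, UndefinedPairError
from rhizonet.io import AbundanceMatrix

INTERACTION_TYPES = ("mutualism", "antagonism", "aggression", "altruism")

#: aggression and altruism are directional (strong -> weak); mutualism
#: and antagonism are analyzed as undirected relations.
DIRECTED_TYPES = frozenset({"aggression", "altruism"})

DEFAULT_TAU = {
    "mutualism": 0.95,
    "antagonism": 0.95,
    "aggression": 0.95,
    "altruism": 0.99,
}

__all__ = [
    "INTERACTION_TYPES",
    "DIRECTED_TYPES",
    "DEFAULT_TAU",
    "InteractionMatrix",
    "SparseInteractionMatrix",
    "transform_abundance",
    "pair_descriptor",
    "interaction_matrix",
    "normalize_matrix",
    "threshold_matrix",
    "global_minmax",
]


@dataclass
class InteractionMatrix:
    """Dense m x m descriptor values for one host and one interaction
    type; undefined pairs are NaN. ``scale`` is ``raw`` or
    ``normalized``."""

    type: str
    host_id: object
    otu_ids: list
    values: np.ndarray
    scale: str = "raw"

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class SparseInteractionMatrix:
    """Thresholded entries ``(u, v, weight)`` with weight > threshold;
    u is always the more abundant member of the pair."""

    type: str
    host_id: object
    otu_ids: list
    entries: pd.DataFrame  # columns: u, v, weight
    threshold: float


def transform_abundance(a: AbundanceMatrix) -> AbundanceMatrix:
    """log10(x + 1) working scale; zeros stay at zero."""
    arr = a.values.to_numpy(dtype=float)
    if arr.size and np.nanmin(arr) < 0:
        raise FormatError("negative abundances cannot be log-transformed")
    return AbundanceMatrix(
        values=pd.DataFrame(
            np.log10(arr + 1.0), index=a.values.index, columns=a.values.columns
        )
    )


def pair_descriptor(xu: float, xv: float, type: str) -> float:
    """Descriptor value for one ordered pair, ``xu > xv > 0``."""
    if type not in INTERACTION_TYPES:
        raise ConfigError(f"unknown interaction type {type!r}")
    if xv <= 0:
        raise UndefinedPairError("zero-abundance member: pair excluded")
    if xu == xv:
        raise UndefinedPairError("tied abundances: descriptor undefined")
    if xu < xv:
        raise UndefinedPairError("xu must be the more abundant member")
    if type == "mutualism":
        return xu * xv / (xu - xv)
    if type == "antagonism":
        return 1.0 / ((xu * xv) * (xu - xv))
    if type == "aggression":
        return xu / xv
    return 1.0 - xv / xu  # altruism


def interaction_matrix(
    host_abundances, type: str, otu_ids=None, host_id=None
) -> InteractionMatrix:
    """Dense descriptor matrix for one host.

    ``host_abundances`` are log-transformed abundances of the m OTUs.
    Entry (u, v) is defined iff the pair has distinct positive values
    and u is the more abundant member; everything else is NaN.
    """
    x = np.asarray(host_abundances, dtype=float)
    m = x.shape[0]
    if m < 2:
        raise ConfigError("need at least two OTUs for interactions")
    if otu_ids is None:
        otu_ids = list(range(m))
    xu = x[:, None]
    xv = x[None, :]
    defined = (xu > xv) & (xv > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if type == "mutualism":
            vals = xu * xv / (xu - xv)
        elif type == "antagonism":
            vals = 1.0 / ((xu * xv) * (xu - xv))
        elif type == "aggression":
            vals = xu / xv
        elif type == "altruism":
            vals = 1.0 - xv / xu
        else:
            raise ConfigError(f"unknown interaction type {type!r}")
    vals = np.where(defined, vals, np.nan)
    return InteractionMatrix(
        type=type, host_id=host_id, otu_ids=list(otu_ids), values=vals, scale="raw"
    )


def normalize_matrix(
    M: InteractionMatrix, bounds: tuple[float, float] | None = None
) -> InteractionMatrix:
    """Min-max normalize the defined entries to [0, 1].

    By default the minimum and maximum are taken over this matrix's own
    defined entries ("per-host" scope); passing ``bounds`` applies an
    externally computed (min, max), e.g. pooled across hosts ("global"
    scope). A degenerate range (max == min) maps every entry to 0.
    """
    mask = M.defined_mask()
    vals = M.values.copy()
    if mask.any():
        if bounds is None:
            lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
        else:
            lo, hi = bounds
        span = hi - lo
        if span > 0:
            vals[mask] = np.clip((vals[mask] - lo) / span, 0.0, 1.0)
        else:
            vals[mask] = 0.0
    return InteractionMatrix(
        type=M.type,
        host_id=M.host_id,
        otu_ids=M.otu_ids,
        values=vals,
        scale="normalized",
    )


def global_minmax(matrices) -> tuple[float, float]:
    """(min, max) over the defined entries of several raw matrices."""
    lo, hi = np.inf, -np.inf
    for M in matrices:
        mask = M.defined_mask()
        if mask.any():
            lo = min(lo, float(np.nanmin(M.values)))
            hi = max(hi, float(np.nanmax(M.values)))
    if not np.isfinite(lo):
        lo = hi = 0.0
    return lo, hi


def threshold_matrix(
    M: InteractionMatrix, tau: float | None = None
) -> SparseInteractionMatrix:
    """Keep entries strictly above ``tau`` (default per-type threshold:
    0.95, or 0.99 for altruism)."""
    if M.scale != "normalized":
        raise ConfigError("threshold_matrix expects a normalized matrix")
    if tau is None:
        tau = DEFAULT_TAU[M.type]
    if not 0.0 < tau < 1.0:
        raise ConfigError(f"threshold must be in (0, 1), got {tau}")
    with np.errstate(invalid="ignore"):
        rows, cols = np.nonzero(M.values > tau)
    otus = np.asarray(M.otu_ids, dtype=object)
    entries = pd.DataFrame(
        {
            "u": otus[rows],
            "v": otus[cols],
            "weight": M.values[rows, cols],
        }
    )
    return SparseInteractionMatrix(
        type=M.type,
        host_id=M.host_id,
        otu_ids=M.otu_ids,
        entries=entries,
        threshold=tau,
    )
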