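"""Weighted gene co-expression network construction and PPI intersection.

The co-expression step is the adjacency stage of weighted correlation
network analysis: pairwise Pearson correlation ``r`` over pairwise-complete
samples, soft-thresholded to an adjacency ``a = |r| ** beta``.  Edges are
kept either above an absolute-adjacency threshold or as the top-N by
adjacency.  The correlation sign is retained as edge metadata; downstream
random-walk transition probabilities use the nonnegative weight.

Intersecting the co-expression network with a protein-protein interaction
network yields the "common network": edges supported by both data types,
weighted by the co-expression adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .types import SeednetError, validate_graph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoexprParams:
    """Parameters of the co-expression adjacency step.

    beta
        Soft-threshold power applied to ``|r|``.  The default 1 uses
        absolute correlations directly as edge weights.
    abs_r_threshold
        Keep edges with adjacency ``>=`` this value.  Mutually exclusive
        with ``target_edge_count``.
    target_edge_count
        Keep the N largest-adjacency edges (ties broken lexicographically
        by endpoint pair), for matching a desired network density.
    """

    beta: float = 1.0
    abs_r_threshold: float | None = 0.5
    target_edge_count: int | None = None

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise SeednetError("beta must be positive")
        if (self.abs_r_threshold is None) == (self.target_edge_count is None):
            raise SeednetError("exactly one of abs_r_threshold / target_edge_count must be set")
        if self.abs_r_threshold is not None and not (0 <= self.abs_r_threshold < 1):
            raise SeednetError("abs_r_threshold must lie in [0, 1)")
        if self.target_edge_count is not None and self.target_edge_count <= 0:
            raise SeednetError("target_edge_count must be positive")


def correlation_adjacency(expr: pd.DataFrame, params: CoexprParams | None = None) -> nx.Graph:
    """Build the soft-thresholded co-expression network.

    Genes with zero variance or more than 50% missing values are excluded
    (logged).  Correlations use pairwise-complete samples; a pair with
    fewer than 3 complete observations is skipped.  Edge weight is
    ``|r| ** beta`` and edge ``sign`` is the sign of ``r``.
    """
    if params is None:
        params = CoexprParams()
    if expr.shape[1] < 3:
        raise SeednetError("at least 3 samples are required for correlations")
    frac_missing = expr.isna().mean(axis=1)
    variances = expr.var(axis=1, ddof=0)
    keep = (frac_missing <= 0.5) & (variances > 0)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning(
            "excluded %d genes (zero variance or >50%% missing): %s",
            n_excluded,
            ", ".join(map(str, expr.index[~keep][:10])),
        )
    expr = expr.loc[keep]
    if expr.empty:
        raise SeednetError("no genes left after variance/missingness filtering")

    # pairwise-complete Pearson; min_periods masks pairs with <3 shared samples
    corr = expr.T.corr(method="pearson", min_periods=3)
    genes = list(corr.index)
    rmat = corr.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    r = rmat[iu, ju]
    ok = np.isfinite(r)
    iu, ju, r = iu[ok], ju[ok], r[ok]
    a = np.abs(r) ** params.beta

    if params.abs_r_threshold is not None:
        keep_edge = a >= params.abs_r_threshold
        sel = np.flatnonzero(keep_edge)
    else:
        order = sorted(
            range(len(a)),
            key=lambda k: (-a[k], genes[iu[k]], genes[ju[k]]),
        )
        sel = order[: params.target_edge_count]

    graph = nx.Graph()
    for k in sel:
        u, v = genes[iu[k]], genes[ju[k]]
        if a[k] <= 0:
            continue
        graph.add_edge(u, v, weight=min(float(a[k]), 1.0), sign=int(np.sign(r[k])) or 1)
    return validate_graph(graph)


def intersect_networks(ppi: nx.Graph, coexpr: nx.Graph) -> nx.Graph:
    """Intersect PPI and co-expression edge sets into the common network.

    The surviving edges carry the co-expression weight (and sign); nodes
    are only the endpoints of retained edges, so degree-0 genes drop out.
    """
    validate_graph(ppi)
    validate_graph(coexpr)
    common = nx.Graph()
    for u, v, data in coexpr.edges(data=True):
        if ppi.has_edge(u, v):
            common.add_edge(u, v, **data)
    if common.number_of_edges() == 0:
        raise SeednetError(
            "PPI and co-expression networks share no edges; "
            "relax abs_r_threshold or the PPI score cutoff"
        )
    return common
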