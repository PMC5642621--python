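"""Shared containers for the network-based candidate-gene pipeline.

Gene networks are plain :class:`networkx.Graph` objects with a ``weight``
attribute in ``(0, 1]`` on every edge, an optional ``sign`` attribute in
``{+1, -1}`` (the sign of the underlying Pearson correlation), and an
optional ``role`` attribute on nodes.  Expression matrices are pandas
DataFrames (genes x samples).  The small dataclasses below carry the
structured results of each pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


class SeednetError(ValueError):
    """Raised for invalid inputs or degenerate pipeline states."""


def validate_graph(graph: nx.Graph) -> nx.Graph:
    """Check the weighted-graph invariants and return the graph.

    Invariants: undirected simple graph; no self-loops; every edge carries
    a ``weight`` strictly in ``(0, 1]``; ``sign``, when present, is +1/-1.
    """
    if graph.is_directed() or graph.is_multigraph():
        raise SeednetError("gene networks must be simple undirected graphs")
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise SeednetError(f"self-loop on node {u!r}")
        w = data.get("weight")
        if w is None or not (0.0 < w <= 1.0):
            raise SeednetError(f"edge ({u!r}, {v!r}) weight {w!r} not in (0, 1]")
        s = data.get("sign")
        if s is not None and s not in (1, -1):
            raise SeednetError(f"edge ({u!r}, {v!r}) sign {s!r} not in {{+1, -1}}")
    return graph


@dataclass(frozen=True)
class SeedSet:
    """Seed genes present in a network, plus those dropped as absent."""

    genes: tuple[str, ...]
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.genes) & set(self.dropped):
            raise SeednetError("seed set and dropped set overlap")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class RelevanceScores:
    """Expected-passage relevances from the limited k-walks algorithm.

    ``edge_relevance`` maps sorted node pairs to the mean (over start
    seeds with positive absorption) conditional expected number of times
    a length-limited absorbed walk traverses the edge.  ``node_relevance``
    is half the sum of incident edge relevances, plus one for start seeds.
    ``absorption_mass`` maps each start seed to the probability its walk
    is absorbed by another seed within ``L`` steps.
    """

    edge_relevance: dict[tuple[str, str], float]
    node_relevance: dict[str, float]
    absorption_mass: dict[str, float]
    L: int


@dataclass
class Subnetwork:
    """An extracted subgraph with a role label on every node."""

    graph: nx.Graph
    roles: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.graph.nodes) - set(self.roles)
        if missing:
            raise SeednetError(f"nodes without a role: {sorted(missing)}")

    def nodes_with_role(self, role: str) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.roles[n] == role)


@dataclass(frozen=True)
class RankedGene:
    gene: str
    rs: float
    rank: int


@dataclass(frozen=True)
class PairStat:
    """A test statistic for a gene pair or a gene-by-covariate contrast."""

    gene_a: str
    gene_b: str
    statistic: float
    p: float
    p_adj: float | None = None
    n: int = 0


@dataclass
class RiskStratification:
    """Median-split survival stratification of a cohort."""

    labels: dict[str, str]
    n_retained: int
    n_excluded: int
    threshold: float
    logrank_chisq: float
    logrank_p: float
    km_curves: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
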