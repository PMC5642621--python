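"""Limited k-walks subnetwork extraction.

A random walker starts at one seed gene and moves along edges with
probability proportional to edge weight until it is absorbed by any other
seed; walks longer than a budget ``L`` are discarded.  The relevance of an
edge is the expected number of times such an absorbed walk traverses it,
conditioned on absorption within ``L`` steps.  Relevances are computed by
a forward/backward recursion over the absorbing Markov chain, averaged
over all start seeds that can reach another seed, and the subnetwork is
assembled greedily from the highest-relevance edges until the seeds are
connected.

``brute_force_relevance`` recomputes the same quantities by exhaustive
enumeration of every admissible walk; it is restricted to tiny graphs and
exists to verify the recursion.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .types import RelevanceScores, SeednetError, Subnetwork, validate_graph

logger = logging.getLogger(__name__)


def build_transition(graph: nx.Graph, start: str, absorbing: set[str]):
    """Build the row-stochastic transition matrix of the absorbing chain.

    Returns ``(nodes, P)`` where ``nodes`` is the sorted node list and
    ``P`` is a sparse matrix with ``P[i, j] = w_ij / sum_k w_ik`` for
    transient ``i`` and all-zero rows for absorbing states.
    """
    validate_graph(graph)
    if start not in graph:
        raise SeednetError(f"start seed {start!r} not in graph")
    if not absorbing:
        raise SeednetError("absorbing set is empty")
    if start in absorbing:
        raise SeednetError("start seed cannot be absorbing")
    if not set(absorbing) <= set(graph.nodes):
        raise SeednetError("absorbing states must be graph nodes")
    if graph.degree(start) == 0:
        raise SeednetError(f"start seed {start!r} is isolated")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    absorbing_idx = {index[a] for a in absorbing}
    rows, cols, vals = [], [], []
    for u in nodes:
        i = index[u]
        if i in absorbing_idx:
            continue
        total = sum(graph[u][v]["weight"] for v in graph[u])
        if total <= 0:
            continue
        for v in graph[u]:
            rows.append(i)
            cols.append(index[v])
            vals.append(graph[u][v]["weight"] / total)
    P = sp.csr_array((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    return nodes, P


def _per_start_relevance(graph: nx.Graph, start: str, absorbing: set[str], L: int):
    """Forward/backward passage expectations for one start seed.

    Returns ``(edge_relevance, Z)`` where ``Z`` is the probability of
    absorption within ``L`` steps and the edge relevances are conditional
    on that event (empty dict when ``Z == 0``).
    """
    nodes, P = build_transition(graph, start, absorbing)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    abs_mask = np.zeros(n, dtype=bool)
    for a in absorbing:
        abs_mask[index[a]] = True

    # beta[m, j] = P(absorbed within m further steps | currently at j)
    beta = np.zeros((L + 1, n))
    beta[0, abs_mask] = 1.0
    for m in range(1, L + 1):
        beta[m] = P @ beta[m - 1]
        beta[m, abs_mask] = 1.0

    Z = float(beta[L, index[start]])
    if Z <= 0.0:
        return {}, 0.0

    # alpha[l, i] = P(walk occupies i after l steps without prior absorption);
    # absorbing rows of P are zero, so absorbed mass never propagates.
    alpha = np.zeros(n)
    alpha[index[start]] = 1.0
    PT = P.T.tocsr()
    Pcoo = P.tocoo()
    ei, ej, pv = Pcoo.row, Pcoo.col, Pcoo.data

    directed = np.zeros(len(pv))  # expected traversals of each directed edge i->j
    for l in range(L):
        directed += alpha[ei] * pv * beta[L - l - 1, ej]
        alpha = PT @ alpha

    edge_relevance: dict[tuple[str, str], float] = {}
    for k in range(len(pv)):
        u, v = nodes[ei[k]], nodes[ej[k]]
        key = (u, v) if u < v else (v, u)
        edge_relevance[key] = edge_relevance.get(key, 0.0) + float(directed[k]) / Z
    return edge_relevance, Z


def _aggregate(per_start: dict[str, dict], masses: dict[str, float], seeds, L: int) -> RelevanceScores:
    live = [s for s in seeds if masses.get(s, 0.0) > 0.0]
    if not live:
        raise SeednetError(
            f"no start seed can reach another seed within L={L} steps; increase L"
        )
    edge_relevance: dict[tuple[str, str], float] = {}
    for s in live:
        for e, r in per_start[s].items():
            edge_relevance[e] = edge_relevance.get(e, 0.0) + r
    edge_relevance = {e: r / len(live) for e, r in edge_relevance.items()}

    node_relevance: dict[str, float] = {}
    for (u, v), r in edge_relevance.items():
        node_relevance[u] = node_relevance.get(u, 0.0) + 0.5 * r
        node_relevance[v] = node_relevance.get(v, 0.0) + 0.5 * r
    for s in live:
        node_relevance[s] = node_relevance.get(s, 0.0) + 1.0
    return RelevanceScores(
        edge_relevance=edge_relevance,
        node_relevance=node_relevance,
        absorption_mass=dict(masses),
        L=L,
    )


def limited_kwalks_relevance(graph: nx.Graph, seeds, L: int = 50) -> RelevanceScores:
    """Expected-passage relevances of edges and nodes, averaged over seeds.

    For each seed ``s`` in turn, the remaining seeds absorb a walk started
    at ``s``; the conditional expected traversal count of every edge is
    computed by the forward/backward recursion and normalized by the
    absorption mass ``Z_s``.  The final relevance is the arithmetic mean
    over start seeds with ``Z_s > 0``.
    """
    seed_list = list(seeds)
    if len(seed_list) < 2:
        raise SeednetError("at least 2 seeds are required")
    if any(s not in graph for s in seed_list):
        missing = [s for s in seed_list if s not in graph]
        raise SeednetError(f"seeds not in graph: {missing}")
    if L < 1:
        raise SeednetError("L must be >= 1")
    per_start: dict[str, dict] = {}
    masses: dict[str, float] = {}
    for s in seed_list:
        if graph.degree(s) == 0:
            per_start[s], masses[s] = {}, 0.0
            continue
        per_start[s], masses[s] = _per_start_relevance(graph, s, set(seed_list) - {s}, L)
    return _aggregate(per_start, masses, seed_list, L)


def brute_force_relevance(graph: nx.Graph, seeds, L: int) -> RelevanceScores:
    """Exhaustive-walk oracle for :func:`limited_kwalks_relevance`.

    Enumerates every walk from each start seed that first reaches another
    seed at step ``<= L``, accumulating probability-weighted edge passage
    counts.  Guarded to ``<= 8`` nodes and ``L <= 8``.
    """
    validate_graph(graph)
    if graph.number_of_nodes() > 8 or L > 8:
        raise SeednetError("brute-force guard: at most 8 nodes and L <= 8")
    seed_list = list(seeds)
    if len(seed_list) < 2:
        raise SeednetError("at least 2 seeds are required")

    step_prob = {
        u: {v: graph[u][v]["weight"] / sum(graph[u][w]["weight"] for w in graph[u]) for v in graph[u]}
        for u in graph.nodes
    }

    per_start: dict[str, dict] = {}
    masses: dict[str, float] = {}
    for s in seed_list:
        absorbers = set(seed_list) - {s}
        counts: dict[tuple[str, str], float] = {}
        total_prob = 0.0
        # stack entries: (node, prob, steps, traversed edge multiset)
        stack = [(s, 1.0, 0, ())]
        while stack:
            node, prob, steps, edges = stack.pop()
            if node in absorbers:
                total_prob += prob
                for e in edges:
                    counts[e] = counts.get(e, 0.0) + prob
                continue
            if steps == L:
                continue
            for nxt, p in step_prob.get(node, {}).items():
                key = (node, nxt) if node < nxt else (nxt, node)
                stack.append((nxt, prob * p, steps + 1, edges + (key,)))
        masses[s] = total_prob
        per_start[s] = (
            {e: c / total_prob for e, c in counts.items()} if total_prob > 0 else {}
        )
    return _aggregate(per_start, masses, seed_list, L)


def extract_subnetwork(
    graph: nx.Graph,
    relevance: RelevanceScores,
    seeds,
    max_edges: int | None = None,
) -> Subnetwork:
    """Assemble the seed-connecting subnetwork from ranked edge relevances.

    Edges are added in decreasing relevance order (lexicographic
    tie-break) until every group of mutually reachable seeds shares one
    connected component; edges tied with the relevance at the moment of
    connection are then also included (plateau rule), up to ``max_edges``.
    Seeds unreachable from every other seed appear as isolated nodes with
    a warning.
    """
    validate_graph(graph)
    seed_list = [s for s in seeds if s in graph]
    ranked = sorted(
        ((e, r) for e, r in relevance.edge_relevance.items() if r > 0),
        key=lambda item: (-item[1], item[0]),
    )

    # seeds are "connected" when each parent-graph component's seeds
    # occupy a single component of the subnetwork
    parent_comp: dict[str, int] = {}
    for ci, comp in enumerate(nx.connected_components(graph)):
        for node in comp:
            parent_comp[node] = ci
    seed_groups: dict[int, list[str]] = {}
    for s in seed_list:
        seed_groups.setdefault(parent_comp[s], []).append(s)
    if len(seed_groups) > 1:
        logger.warning(
            "seeds span %d disconnected components of the parent graph", len(seed_groups)
        )

    sub = nx.Graph()
    sub.add_nodes_from(seed_list)

    def seeds_connected() -> bool:
        for group in seed_groups.values():
            if len(group) < 2:
                continue
            comps = {frozenset(c) for c in nx.connected_components(sub)}
            first = next(c for c in comps if group[0] in c)
            if not all(g in first for g in group):
                return False
        return True

    plateau: float | None = None
    for (u, v), r in ranked:
        if plateau is not None and r < plateau:
            break
        if max_edges is not None and sub.number_of_edges() >= max_edges:
            break
        sub.add_edge(u, v, **graph[u][v])
        if plateau is None and seeds_connected():
            plateau = r
    if plateau is None and ranked:
        logger.warning("edge budget exhausted before the seeds were connected")

    roles = {n: ("seed" if n in set(seed_list) else "linker") for n in sub.nodes}
    return Subnetwork(graph=sub, roles=roles)
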