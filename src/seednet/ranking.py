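"""Ranking-score prioritization of linker genes.

For a linker gene ``g`` in the extracted subnetwork, the ranking score is
the sum of the weights of its subnetwork edges, with edges to seed genes
counted twice (a seed-linker link carries more evidence than a
linker-linker link):

    RS(g) = sum over edges (g, h) of m * w(g, h),  m = 2 if h is a seed

Candidates are linkers whose RS strictly exceeds a cutoff (the published
analysis used RS > 1), or the top-k by rank.  The module also extracts
the smallest subnetwork connecting a chosen candidate set, via a
shortest-path Steiner approximation with edge length ``1 - w``.
"""

from __future__ import annotations

import heapq
import logging

import networkx as nx

from .types import RankedGene, SeednetError, Subnetwork, validate_graph

logger = logging.getLogger(__name__)

MIN_EDGE_LENGTH = 1e-6


def ranking_score(sub: Subnetwork, seeds=None) -> list[RankedGene]:
    """Score every linker gene in the subnetwork.

    ``seeds`` defaults to the nodes whose subnetwork role is ``seed``.
    Output is sorted by RS descending, ties broken alphabetically; ranks
    start at 1.  Seeds themselves are not scored.
    """
    seed_set = set(seeds) if seeds is not None else {
        n for n, role in sub.roles.items() if role == "seed"
    }
    linkers = [n for n in sub.graph.nodes if n not in seed_set]
    if not linkers:
        logger.warning("subnetwork contains no linker genes to rank")
        return []
    scored = []
    for g in linkers:
        rs = 0.0
        for h in sub.graph[g]:
            m = 2.0 if h in seed_set else 1.0
            rs += m * sub.graph[g][h]["weight"]
        scored.append((g, rs))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return [RankedGene(gene=g, rs=rs, rank=i + 1) for i, (g, rs) in enumerate(scored)]


def select_candidates(ranked: list[RankedGene], rs_cutoff: float | None = 1.0,
                      top_k: int | None = None) -> list[str]:
    """Select candidate genes from a ranked linker list.

    Exactly one rule applies: ``rs_cutoff`` keeps genes with RS strictly
    greater than the cutoff (so genes exactly at the cutoff are excluded),
    ``top_k`` keeps the first k ranks.
    """
    if not ranked:
        raise SeednetError("ranked list is empty")
    if (rs_cutoff is None) == (top_k is None):
        raise SeednetError("exactly one of rs_cutoff / top_k must be given")
    if top_k is not None:
        return [rg.gene for rg in ranked[:top_k]]
    return [rg.gene for rg in ranked if rg.rs > rs_cutoff]


def _dijkstra(graph: nx.Graph, source: str):
    """Deterministic Dijkstra over lengths 1 - w (floored at 1e-6).

    Ties are broken toward the lexicographically smaller predecessor so
    realized paths are reproducible across runs and platforms.
    """
    dist = {source: 0.0}
    pred: dict[str, str | None] = {source: None}
    heap = [(0.0, source)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in sorted(graph[u]):
            length = max(1.0 - graph[u][v]["weight"], MIN_EDGE_LENGTH)
            nd = d + length
            if v not in dist or nd < dist[v] - 1e-15 or (
                abs(nd - dist[v]) <= 1e-15 and pred.get(v) is not None and u < pred[v]
            ):
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    return dist, pred


def _path_to(pred: dict, target: str) -> list[str]:
    path = [target]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    return path[::-1]


def minimal_connecting_subnetwork(graph: nx.Graph, targets) -> Subnetwork:
    """Smallest subnetwork connecting a set of target genes (approximate).

    Steiner-style heuristic: shortest paths between all target pairs with
    edge length ``1 - w``, a minimum spanning tree over the resulting
    target-pair distances (Kruskal, lexicographic tie-breaks), and the
    union of the realized paths.  Targets in different components yield a
    partial result with a warning.
    """
    validate_graph(graph)
    target_list = sorted(set(targets))
    missing = [t for t in target_list if t not in graph]
    if missing:
        raise SeednetError(f"targets not in graph: {missing}")

    dists: dict[str, dict] = {}
    preds: dict[str, dict] = {}
    for t in target_list:
        dists[t], preds[t] = _dijkstra(graph, t)

    pair_edges = []
    for i, a in enumerate(target_list):
        for b in target_list[i + 1:]:
            if b in dists[a]:
                pair_edges.append((dists[a][b], a, b))
    pair_edges.sort()

    # Kruskal MST over target-pair distances
    parent = {t: t for t in target_list}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sub = nx.Graph()
    sub.add_nodes_from(target_list)
    n_joined = 0
    for _, a, b in pair_edges:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        parent[ra] = rb
        n_joined += 1
        path = _path_to(preds[a], b)
        for u, v in zip(path, path[1:]):
            sub.add_edge(u, v, **graph[u][v])

    n_components = len({find(t) for t in target_list})
    if n_components > 1:
        logger.warning("targets span %d disconnected components; result is partial", n_components)

    roles = {n: ("target" if n in set(target_list) else "steiner") for n in sub.nodes}
    return Subnetwork(graph=sub, roles=roles)


def format_ranked_table(ranked: list[RankedGene]) -> str:
    """Human-readable ranked table; RS rounded to one decimal for display."""
    lines = ["rank\tgene\trs"]
    for rg in ranked:
        lines.append(f"{rg.rank}\t{rg.gene}\t{round(rg.rs, 1):g}")
    return "\n".join(lines) + "\n"
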