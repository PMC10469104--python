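"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by a route different from the package
implementation: exhaustive enumeration, closed forms, or textbook
algorithms written directly here.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Graph oracles (adjacency given as dict node -> dict neighbor -> weight)


def floyd_warshall(nodes: list, lengths: dict) -> dict:
    """All-pairs shortest path lengths; lengths[(u, v)] = edge length."""
    dist = {(u, v): (0.0 if u == v else math.inf) for u in nodes for v in nodes}
    for (u, v), ell in lengths.items():
        dist[(u, v)] = min(dist[(u, v)], ell)
        dist[(v, u)] = min(dist[(v, u)], ell)
    for k in nodes:
        for i in nodes:
            for j in nodes:
                alt = dist[(i, k)] + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return dist


def enumerate_simple_paths(adj: dict, source, target, max_len=None):
    """All simple paths source -> target by DFS."""
    paths = []
    stack = [(source, [source])]
    while stack:
        node, path = stack.pop()
        if node == target:
            paths.append(path)
            continue
        if max_len is not None and len(path) > max_len:
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))
    return paths


def brute_betweenness(nodes: list, adj: dict, lengths: dict) -> dict:
    """Unnormalized betweenness by exhaustive simple-path enumeration.

    For each unordered pair (s, t), all shortest paths are found by
    enumerating every simple path and keeping those of minimal total
    length; each interior node of a shortest path earns the fraction of
    shortest paths through it.
    """
    dist = floyd_warshall(nodes, lengths)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if math.isinf(dist[(s, t)]):
            continue
        paths = enumerate_simple_paths(adj, s, t)
        plens = [
            sum(lengths.get((a, b), lengths.get((b, a)))
                for a, b in zip(p, p[1:]))
            for p in paths
        ]
        best = min(plens)
        assert abs(best - dist[(s, t)]) < 1e-9
        shortest = [p for p, ell in zip(paths, plens) if abs(ell - best) < 1e-9]
        sigma = len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / sigma
    return bc


def brute_harmonic(nodes: list, lengths: dict) -> dict:
    dist = floyd_warshall(nodes, lengths)
    return {
        v: sum(
            1.0 / dist[(u, v)]
            for u in nodes
            if u != v and not math.isinf(dist[(u, v)])
        )
        for v in nodes
    }


def random_weighted_graph(rng, n, p=0.4, weights=(0.25, 0.5, 1.0)):
    """Random graph with weights whose reciprocals are exact integers."""
    nodes = [f"n{i}" for i in range(n)]
    adj = {v: {} for v in nodes}
    lengths = {}
    sims = {}
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            w = float(rng.choice(weights))
            u, v = nodes[i], nodes[j]
            adj[u][v] = w
            adj[v][u] = w
            lengths[(u, v)] = 1.0 / w
            sims[(u, v)] = w
    return nodes, adj, lengths, sims


# ---------------------------------------------------------------------------
# Partitions of a small node set (for exhaustive modularity maximization)


def all_partitions(items: list):
    """Every set partition of the items (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in all_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] + [first]] + partition[i + 1:]
        yield partition + [[first]]


# ---------------------------------------------------------------------------
# Alignment enumeration oracle


def enumerate_global_score(a: str, b: str, score_fn, gap_open: float,
                           gap_extend: float) -> float:
    """Best global alignment score by enumerating all alignments.

    Alignments are sequences of moves (match/insert/delete); gap runs in
    either sequence cost open + (L-1)*extend.  Exponential — only for
    very short sequences.
    """
    best = -math.inf

    def rec(i, j, score, gap_state):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + score_fn(a[i], b[j]), 0)
        if i < len(a):  # gap in b
            cost = gap_extend if gap_state == 1 else gap_open
            rec(i + 1, j, score - cost, 1)
        if j < len(b):  # gap in a
            cost = gap_extend if gap_state == 2 else gap_open
            rec(i, j + 1, score - cost, 2)

    rec(0, 0, 0.0, 0)
    return best


def enumerate_local_score(a: str, b: str, score_fn, gap_open: float,
                          gap_extend: float) -> float:
    """Best local score: max global score over all substring pairs, or 0."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    s = enumerate_global_score(
                        a[i0:i1], b[j0:j1], score_fn, gap_open, gap_extend
                    )
                    best = max(best, s)
    return best


# ---------------------------------------------------------------------------
# Weighted mean (Choquet additive-case oracle)


def weighted_mean(x, g):
    x = np.asarray(x, float)
    g = np.asarray(g, float)
    return float((x * g).sum() / g.sum())
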