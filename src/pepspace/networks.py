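"""Builders for the three peptide network types.

* CSN  — chemical space network: nodes are peptides, an edge joins every
  pair whose similarity is at least a user-chosen cutoff theta.
* HSPN — half-space proximal network: a parameter-free proximity graph.
  From each node, repeatedly connect to the nearest remaining point and
  discard every remaining point lying strictly closer to that neighbor
  than to the source; the undirected union of the per-node selections is
  the network.  No similarity threshold needs tuning, and the HSPN edge
  set is always a subset of the complete CSN at theta = 0.
* METN — metadata network: a bipartite knowledge graph joining peptide
  nodes to annotation-term nodes (term node id "relation:term").

All builders return a ``networkx.Graph`` whose ``graph`` dict records the
build provenance (builder, metric, conversion, cutoff).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np

from .core import PeptideSet
from .descriptors import DescriptorMatrix
from .simmetrics import (
    NONNEGATIVE_METRICS,
    MetricSpec,
    SimilarityMatrix,
    pairwise_distances,
    to_similarity,
)

logger = logging.getLogger(__name__)


def build_csn(S: SimilarityMatrix, theta: float) -> nx.Graph:
    """Threshold network: edge (i, j) iff S[i][j] >= theta, weight S[i][j].

    Every peptide is a node, including isolated ones.  theta = 0 yields
    the complete graph; edge sets are monotone non-increasing in theta.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"cutoff theta must lie in [0, 1], got {theta}")
    g = nx.Graph(builder="csn", metric=S.metric, conversion=S.conversion,
                 cutoff=theta)
    g.add_nodes_from(S.ids)
    n = len(S.ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(S.S[i, j])
            if w >= theta:
                g.add_edge(S.ids[i], S.ids[j], weight=w)
    logger.info("build_csn: theta=%.3f -> %d nodes, %d edges",
                theta, g.number_of_nodes(), g.number_of_edges())
    return g


def hsp_neighbors(D: np.ndarray, u: int) -> list[int]:
    """Half-space proximal neighbor selection for one source node.

    Candidates are visited in ascending distance from ``u`` (ties broken
    by node index).  Each selected neighbor ``v`` eliminates every
    remaining candidate ``w`` with ``d(w, v) < d(w, u)`` (strict: points
    equidistant to source and neighbor stay candidates).
    """
    n = D.shape[0]
    remaining = sorted((i for i in range(n) if i != u),
                       key=lambda i: (D[u, i], i))
    selected: list[int] = []
    while remaining:
        v = remaining.pop(0)
        selected.append(v)
        remaining = [w for w in remaining if not (D[w, v] < D[w, u])]
    return selected


def build_hspn(
    matrix: DescriptorMatrix,
    spec: MetricSpec = MetricSpec(),
    theta_min: float | None = None,
) -> nx.Graph:
    """Half-space proximal network over descriptor rows.

    Directed selections from every node are merged by union into an
    undirected graph; edge weights are similarities of the underlying
    distances.  ``theta_min``, if given, drops edges below that
    similarity afterwards (off by default: the HSPN needs no threshold).
    """
    if len(matrix.ids) < 2:
        raise ValueError("need at least two points")
    if spec.name in NONNEGATIVE_METRICS and (matrix.as_array() < 0).any():
        matrix = matrix.normalized()
    X = matrix.as_array()
    D = pairwise_distances(X, spec.name)
    ids = matrix.ids
    n = len(ids)
    off = D[~np.eye(n, dtype=bool)]
    d_max = float(off.max()) if off.size else 0.0

    g = nx.Graph(builder="hspn", metric=spec.name, conversion=spec.conversion,
                 cutoff=theta_min if theta_min is not None else "none")
    g.add_nodes_from(ids)
    for u in range(n):
        for v in hsp_neighbors(D, u):
            w = to_similarity(D[u, v], spec.conversion, d_max)
            g.add_edge(ids[u], ids[v], weight=w)
    if theta_min is not None:
        drop = [(a, b) for a, b, d in g.edges(data=True)
                if d["weight"] < theta_min]
        g.remove_edges_from(drop)
    logger.info("build_hspn: metric=%s -> %d nodes, %d edges",
                spec.name, g.number_of_nodes(), g.number_of_edges())
    return g


def build_metn(
    peptides: PeptideSet,
    annotations: list[tuple[str, str, str]] | None = None,
) -> nx.Graph:
    """Bipartite metadata network: peptides vs "relation:term" nodes.

    One unit-weight edge per distinct (peptide, relation, term) triple.
    Triples naming unknown peptides are skipped with a logged warning.
    If ``annotations`` is None, the peptides' attached annotations are
    used.
    """
    g = nx.Graph(builder="metn", metric="none", conversion="none", cutoff=0.0)
    for p in peptides:
        g.add_node(p.id, kind="peptide")
    if annotations is None:
        annotations = [
            (p.id, rel, term) for p in peptides for rel, term in p.annotations
        ]
    for pid, relation, term in annotations:
        if pid not in peptides:
            logger.warning("build_metn: unknown peptide %r skipped", pid)
            continue
        term_node = f"{relation}:{term}"
        if term_node not in g:
            g.add_node(term_node, kind="term")
        g.add_edge(pid, term_node, weight=1.0)
    logger.info("build_metn: %d nodes, %d edges",
                g.number_of_nodes(), g.number_of_edges())
    return g
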