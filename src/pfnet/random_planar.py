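"""Random maximal planar graphs grown by triangular node insertion.

The null model for cluster compactness and hub connectivity is a random
planar triangulation grown by T2 moves: starting from a triangle, a new
node is repeatedly inserted into a (uniformly chosen) triangular face and
wired to the face's three corners.  Every intermediate graph is a planar
triangulation, the final edge count is exactly 3(n-2), and the degree
distribution develops a heavy tail as n grows.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

__all__ = ["t2_random_planar", "t2_edge_arrays", "shuffle_weights"]


def t2_edge_arrays(n_nodes: int, rng, degree_biased: bool = False):
    """Edge arrays (eu, ev) of a T2-grown triangulation on 0..n_nodes-1.

    ``degree_biased=True`` picks the insertion face with probability
    proportional to the summed degrees of its corners instead of
    uniformly, which skews the tail of the degree distribution further.
    """
    n = int(n_nodes)
    if n < 3:
        raise ValueError("a triangulation needs at least 3 nodes")
    m = 3 * (n - 2)
    eu = np.empty(m, dtype=np.int64)
    ev = np.empty(m, dtype=np.int64)
    eu[0], ev[0] = 0, 1
    eu[1], ev[1] = 0, 2
    eu[2], ev[2] = 1, 2
    ne = 3
    # faces as a growing array of triples; one face is replaced by three
    # per insertion, so after all insertions there are 2n - 4 faces
    faces = np.empty((2 * n, 3), dtype=np.int64)
    faces[0] = (0, 1, 2)
    faces[1] = (0, 1, 2)  # outer face of the triangle
    nf = 2
    if degree_biased:
        deg = np.zeros(n, dtype=np.int64)
        deg[:3] = 2
    for v in range(3, n):
        if degree_biased:
            wts = deg[faces[:nf, 0]] + deg[faces[:nf, 1]] + deg[faces[:nf, 2]]
            f = int(rng.choice(nf, p=wts / wts.sum()))
        else:
            f = int(rng.integers(nf))
        a, b, c = faces[f]
        eu[ne], ev[ne] = a, v
        eu[ne + 1], ev[ne + 1] = b, v
        eu[ne + 2], ev[ne + 2] = c, v
        ne += 3
        faces[f] = (a, b, v)
        faces[nf] = (a, c, v)
        faces[nf + 1] = (b, c, v)
        nf += 2
        if degree_biased:
            deg[[a, b, c]] += 1
            deg[v] = 3
    return eu, ev


def t2_random_planar(
    n_nodes: int,
    seed: int | np.random.Generator = 0,
    weights=None,
    degree_biased: bool = False,
) -> nx.Graph:
    """Random maximal planar graph with 3(n-2) edges, grown by T2 moves.

    ``weights``, if given, is a pool of edge weights assigned to the
    generated edges by sampling (without replacement when the pool is at
    least as large as the edge count, with replacement otherwise).
    Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eu, ev = t2_edge_arrays(n_nodes, rng, degree_biased=degree_biased)
    g = nx.Graph()
    g.add_nodes_from(range(int(n_nodes)))
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        m = eu.shape[0]
        if w.size >= m:
            w = rng.permutation(w)[:m]
        else:
            w = rng.choice(w, size=m, replace=True)
        for k in range(m):
            g.add_edge(int(eu[k]), int(ev[k]), weight=float(w[k]))
    else:
        g.add_edges_from(zip(eu.tolist(), ev.tolist()))
    return g


def shuffle_weights(network: nx.Graph, seed: int | np.random.Generator = 0) -> nx.Graph:
    """Copy of ``network`` with edge weights permuted over the same topology.

    The multiset of weights is preserved exactly; only their placement on
    edges changes.  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = network.copy()
    edges = list(g.edges)
    w = np.array([g.edges[e].get("weight", 1.0) for e in edges], dtype=float)
    perm = rng.permutation(len(edges))
    for e, k in zip(edges, perm):
        g.edges[e]["weight"] = float(w[k])
    return g
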