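"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value along a completely different
route from the library implementation (exhaustive search, naive loops,
closed forms), so agreement is meaningful.
"""

from itertools import combinations

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# planarity via Kuratowski subdivision search (exact for small graphs)
# ---------------------------------------------------------------------------


def _disjoint_paths_exist(G, pairs, branch, interior_free):
    """Backtracking search for internally-disjoint paths joining ``pairs``.

    Interior vertices must come from ``interior_free`` and may be used by
    at most one path; branch vertices serve only as endpoints.
    """
    if not pairs:
        return True
    (a, b), rest = pairs[0], pairs[1:]

    # enumerate simple a-b paths whose interior lies in interior_free
    def walk(u, used):
        if G.has_edge(u, b):
            yield used
        for w in G.neighbors(u):
            if w in interior_free and w not in used and w not in branch:
                yield from walk(w, used | {w})

    for used in walk(a, frozenset()):
        if _disjoint_paths_exist(G, rest, branch, interior_free - used):
            return True
    return False


def _has_subdivision(G, k: int, parts) -> bool:
    """Subdivision of K5 (parts=None) or K3,3 (parts=(3,3)) in G."""
    degs = dict(G.degree())
    min_deg = 4 if parts is None else 3
    candidates = [v for v in G.nodes if degs[v] >= min_deg]
    nodes = set(G.nodes)
    for branch in combinations(candidates, k):
        bset = set(branch)
        free = frozenset(nodes - bset)
        if parts is None:
            pairs = list(combinations(branch, 2))
        else:
            pairs = None
            for left in combinations(branch, 3):
                right = tuple(v for v in branch if v not in left)
                pairs = [(u, v) for u in left for v in right]
                if _disjoint_paths_exist(G, pairs, bset, free):
                    return True
            continue
        if _disjoint_paths_exist(G, pairs, bset, free):
            return True
    return False


def kuratowski_planar(G: nx.Graph) -> bool:
    """Planarity by exhaustive Kuratowski subdivision search.

    A graph is planar iff it contains no subdivision of K5 or K3,3.
    Exponential; intended for graphs of at most ~12 nodes.
    """
    if G.number_of_nodes() <= 4:
        return True
    if _has_subdivision(G, 5, None):
        return False
    if _has_subdivision(G, 6, (3, 3)):
        return False
    return True


# ---------------------------------------------------------------------------
# serial PMFG via the networkx planarity checker
# ---------------------------------------------------------------------------


def networkx_pmfg(pairs) -> nx.Graph:
    """Reference PMFG: test-every-pair-in-order with nx.check_planarity."""
    g = nx.Graph()
    nodes = set()
    for _, row in pairs.iterrows():
        nodes.add(row["node1"])
        nodes.add(row["node2"])
    g.add_nodes_from(sorted(nodes, key=str))
    emax = 3 * (len(nodes) - 2)
    for _, row in pairs.iterrows():
        g.add_edge(row["node1"], row["node2"], weight=row["similarity"])
        ok, _ = nx.check_planarity(g, counterexample=False)
        if not ok:
            g.remove_edge(row["node1"], row["node2"])
        if g.number_of_edges() >= emax:
            break
    return g


# ---------------------------------------------------------------------------
# numeric oracles
# ---------------------------------------------------------------------------


def floyd_warshall(D0: np.ndarray) -> np.ndarray:
    """Naive O(n^3) all-pairs shortest paths from a direct-length matrix."""
    D = D0.copy()
    n = D.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def plugin_mi(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Plug-in mutual information on equal-frequency bins (nats)."""
    from scipy.stats import rankdata

    m = x.size
    cx = np.minimum(((rankdata(x, method="average") - 0.5) * n_bins / m), n_bins - 1).astype(int)
    cy = np.minimum(((rankdata(y, method="average") - 0.5) * n_bins / m), n_bins - 1).astype(int)

    def ent(codes):
        p = np.bincount(codes) / m
        p = p[p > 0]
        return -(p * np.log(p)).sum()

    return ent(cx) + ent(cy) - ent(cx * n_bins + cy)


def silhouette_by_hand(D: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width from the per-point a/b definition."""
    n = D.shape[0]
    vals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            vals.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == l].mean() for l in np.unique(labels) if l != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U, ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    u = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (pos.size * neg.size)


def exhaustive_k_medoids_cost(D: np.ndarray, k: int) -> float:
    """Optimal k-medoids objective by enumerating all medoid subsets."""
    n = D.shape[0]
    best = np.inf
    for med in combinations(range(n), k):
        cost = D[:, med].min(axis=1).sum()
        best = min(best, cost)
    return float(best)


def hypergeometric_tail_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration."""
    from math import comb

    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def prob(x):
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total
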