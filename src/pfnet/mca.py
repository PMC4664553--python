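"""Multiscale clustering of a planar filtered network.

The PFN is decomposed divisively.  Each cluster is split by k-medoids on
within-cluster shortest-path distances, the split boundaries are repaired
with a local-path-index (LPI) reassignment sweep, and the number of
clusters k is chosen by Newman modularity.  A split survives at a
resolution alpha when at least one child is more compact than its parent
under

    nu_l(alpha) = mean-SPD(V_l) / log(|V_l|)^alpha,

and each surviving child is tested for significance against random planar
triangulations carrying the parent's shuffled edge weights.  Recursion
stops when no child improves compactness at any admissible alpha or no
child is significantly compact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .random_planar import t2_edge_arrays

__all__ = [
    "MCAConfig",
    "Cluster",
    "ClusterHierarchy",
    "shortest_path_matrix",
    "compactness",
    "lpi",
    "k_medoids_partition",
    "boundary_update",
    "modularity",
    "k_split",
    "characteristic_alpha",
    "split_decision",
    "compactness_significance",
    "run_mca",
]

_MIN_LENGTH = 1e-12  # zero-length edges would vanish from the sparse graph


def default_alpha_grid() -> np.ndarray:
    """Geometric resolution grid, 50 points spanning 0.02 .. 10."""
    return np.geomspace(0.02, 10.0, 50)


@dataclass
class MCAConfig:
    """Tunable parameters of the multiscale decomposition.

    alpha_grid          resolution values scanned for characteristic alpha
    n_rand              Monte-Carlo draws for compactness significance
    dk                  Q-search look-ahead: exploration continues until
                        k reaches (best k) + dk
    epsilon             LPI 3-walk weight in A^2 + epsilon * A^3
    sig_level           compactness significance threshold
    min_split_size      clusters smaller than this are leaves
    length_transform    similarity -> edge length map for shortest paths
    use_bellman_ford    route shortest paths through Bellman-Ford instead
                        of Dijkstra (identical output on nonnegative
                        lengths, retained for fidelity)
    """

    alpha_grid: np.ndarray = field(default_factory=default_alpha_grid)
    n_rand: int = 100
    dk: int = 10
    epsilon: float = 0.01
    sig_level: float = 0.05
    min_split_size: int = 4
    length_transform: str = "one_minus_abs"
    use_bellman_ford: bool = False
    max_bdp_iter: int = 100
    seed: int = 0


@dataclass
class Cluster:
    """One node set in the hierarchy with its compactness summary."""

    id: str
    parent: str | None
    nodes: tuple
    spd_mean: float = float("nan")
    alpha_char: float | None = None
    nu: float | None = None
    p_value: float | None = None
    kind: str = "cluster"  # "root", "cluster", or "component"
    children: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.nodes)


class ClusterHierarchy:
    """Forest of clusters produced by the multiscale decomposition."""

    def __init__(self, alpha_grid, sig_level: float = 0.05):
        self.clusters: dict[str, Cluster] = {}
        self.roots: list[str] = []
        self.alpha_grid = np.asarray(alpha_grid, dtype=float)
        self.sig_level = sig_level

    def add(self, cluster: Cluster):
        self.clusters[cluster.id] = cluster
        if cluster.parent is None:
            self.roots.append(cluster.id)
        else:
            self.clusters[cluster.parent].children.append(cluster.id)

    def __len__(self):
        return len(self.clusters)

    def leaves(self) -> list[str]:
        return [cid for cid, c in self.clusters.items() if not c.children]

    def _descend(self, cid: str, alpha: float) -> bool:
        """Whether cluster ``cid``'s split is in effect at scale alpha."""
        c = self.clusters[cid]
        if not c.children:
            return False
        for k in c.children:
            ch = self.clusters[k]
            if ch.kind == "component":
                return True
            if (
                ch.alpha_char is not None
                and ch.alpha_char >= alpha
                and ch.p_value is not None
                and ch.p_value <= self.sig_level
            ):
                return True
        return False

    def partition_at_alpha(self, alpha: float) -> dict:
        """node -> cluster id of the partition in effect at scale alpha."""
        out: dict = {}
        stack = list(self.roots)
        while stack:
            cid = stack.pop()
            c = self.clusters[cid]
            if self._descend(cid, alpha):
                stack.extend(c.children)
            else:
                for v in c.nodes:
                    out[v] = cid
        return out

    def significant_alphas(self) -> np.ndarray:
        """Scales at which at least one significant split is in effect."""
        keep = [
            a
            for a in self.alpha_grid
            if any(self._descend(r, a) for r in self.roots)
            and any(
                c.parent is not None
                and c.alpha_char is not None
                and c.alpha_char >= a
                and c.p_value is not None
                and c.p_value <= self.sig_level
                for c in self.clusters.values()
            )
        ]
        return np.asarray(keep, dtype=float)

    def to_frame(self):
        import pandas as pd

        rows = []
        for cid in self.clusters:
            c = self.clusters[cid]
            rows.append(
                {
                    "cluster_id": c.id,
                    "parent_id": c.parent if c.parent is not None else "",
                    "kind": c.kind,
                    "size": c.size,
                    "spd_mean": c.spd_mean,
                    "alpha_char": c.alpha_char if c.alpha_char is not None else np.nan,
                    "nu": c.nu if c.nu is not None else np.nan,
                    "p_value": c.p_value if c.p_value is not None else np.nan,
                    "node_list": ",".join(map(str, sorted(map(str, c.nodes)))),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def edge_lengths(weights: np.ndarray, transform: str = "one_minus_abs") -> np.ndarray:
    """Map similarity weights to nonnegative path lengths."""
    w = np.asarray(weights, dtype=float)
    if transform == "one_minus_abs":
        d = 1.0 - np.abs(w)
    elif transform == "inverse":
        with np.errstate(divide="ignore"):
            d = 1.0 / np.abs(w)
    elif transform == "unit":
        d = np.ones_like(w)
    else:
        raise ValueError(f"unknown length transform: {transform!r}")
    if (d < 0).any():
        raise ValueError("negative edge lengths; weights outside expected range")
    return np.maximum(d, _MIN_LENGTH)


def shortest_path_matrix(
    network: nx.Graph,
    transform: str = "one_minus_abs",
    use_bellman_ford: bool = False,
):
    """All-pairs shortest-path distances on the weighted network.

    Returns (D, node_order); unreachable pairs are +inf.  Dijkstra is the
    default route (lengths are nonnegative by construction); Bellman-Ford
    produces identical distances and is kept behind a flag.
    """
    order = sorted(network.nodes, key=str)
    idx = {u: i for i, u in enumerate(order)}
    n = len(order)
    rows, cols, data = [], [], []
    for u, v, w in network.edges(data="weight", default=1.0):
        rows.append(idx[u])
        cols.append(idx[v])
        data.append(w)
    lengths = edge_lengths(np.asarray(data, dtype=float), transform) if data else np.array([])
    g = csr_matrix((lengths, (rows, cols)), shape=(n, n))
    method = "BF" if use_bellman_ford else "D"
    D = _csgraph_shortest_path(g, method=method, directed=False)
    return D, order


def compactness(spd_submatrix: np.ndarray, alpha: float) -> float:
    """nu = mean within-cluster SPD / log(|V|)^alpha (natural log)."""
    D = np.asarray(spd_submatrix, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("compactness requires a cluster of size >= 2")
    iu = np.triu_indices(n, 1)
    spd_bar = float(np.mean(D[iu]))
    return spd_bar / math.log(n) ** alpha


def lpi(network, epsilon: float = 0.01):
    """Local path index A^2 + epsilon * A^3 on the binary adjacency.

    Accepts a networkx graph (returns (matrix, node_order)) or a dense
    0/1 adjacency matrix (returns the matrix).  The diagonal is zeroed:
    closed walks carry no information about pair affinity.
    """
    if isinstance(network, nx.Graph):
        order = sorted(network.nodes, key=str)
        A = nx.to_numpy_array(network, nodelist=order, weight=None)
        L = _lpi_from_adjacency(A, epsilon)
        return L, order
    A = (np.asarray(network, dtype=float) != 0).astype(float)
    return _lpi_from_adjacency(A, epsilon)


def _lpi_from_adjacency(A: np.ndarray, epsilon: float) -> np.ndarray:
    A2 = A @ A
    L = A2 + epsilon * (A2 @ A)
    np.fill_diagonal(L, 0.0)
    return L


def k_medoids_partition(D: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """PAM k-medoids on a precomputed distance matrix.

    Initialization is the deterministic greedy BUILD step, followed by
    steepest-descent swaps until no swap lowers the total distance to the
    nearest medoid.  All ties break toward smaller indices, so the result
    is reproducible regardless of ``seed`` (kept for interface symmetry).
    Returns labels in 0..k-1 (label = index of the assigned medoid in the
    sorted medoid list).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    # SWAP (steepest descent)
    cost = D[:, medoids].min(axis=1).sum()
    ar = np.arange(n)
    while True:
        dm = D[:, medoids]
        nearest = dm.argmin(axis=1)
        d1 = dm[ar, nearest]
        dm2 = dm.copy()
        dm2[ar, nearest] = np.inf
        d2 = dm2.min(axis=1)
        best_delta = 1e-9
        best = None
        for j in range(k):
            fallback = np.where(nearest == j, d2, d1)
            newcost = np.minimum(fallback[:, None], D).sum(axis=0)
            newcost[medoids] = np.inf
            h = int(np.argmin(newcost))
            delta = cost - newcost[h]
            if delta > best_delta:
                best_delta = delta
                best = (j, h)
        if best is None:
            break
        j, h = best
        medoids[j] = h
        medoids = sorted(medoids)
        cost = D[:, medoids].min(axis=1).sum()
    labels = D[:, medoids].argmin(axis=1)
    return labels.astype(np.int64)


def boundary_update(
    labels: np.ndarray,
    adjacency: np.ndarray,
    lpi_matrix: np.ndarray,
    max_iter: int = 100,
) -> np.ndarray:
    """LPI boundary-repair sweep over a partition.

    Boundary nodes (nodes adjacent to at least two clusters) are
    reassigned to the cluster maximizing their summed LPI affinity.
    Sweeps visit nodes in index order with immediate updates and repeat
    until a full sweep changes nothing; a node moves only on a strict
    affinity improvement, so the output is a fixed point (idempotent).
    If the sweep has not stabilized after ``max_iter`` rounds the current
    labels are returned with a warning.
    """
    labels = np.asarray(labels, dtype=np.int64).copy()
    A = (np.asarray(adjacency, dtype=float) != 0).astype(float)
    n = labels.shape[0]
    deg = A.sum(axis=1)
    nk = int(labels.max()) + 1
    for _ in range(max_iter):
        changed = False
        for i in range(n):
            if deg[i] == 0:
                continue
            neigh_labels = labels[A[i] > 0]
            if np.all(neigh_labels == labels[i]):
                continue  # not a boundary node
            scores = np.bincount(labels, weights=lpi_matrix[i], minlength=nk)
            best = int(scores.argmax())
            if scores[best] > scores[labels[i]]:
                labels[i] = best
                changed = True
        if not changed:
            return labels
    warnings.warn("boundary update did not converge; returning current labels", stacklevel=2)
    return labels


def modularity(network, labels) -> float:
    """Newman modularity of a partition on the unweighted graph.

    Q = sum_l (e_ll / m - (d_l / 2m)^2) with e_ll the within-cluster edge
    count and d_l the summed degree of cluster l.
    """
    if isinstance(network, nx.Graph):
        order = sorted(network.nodes, key=str)
        A = nx.to_numpy_array(network, nodelist=order, weight=None)
    else:
        A = (np.asarray(network, dtype=float) != 0).astype(float)
    labels = np.asarray(labels, dtype=np.int64)
    m2 = A.sum()  # = 2m
    if m2 == 0:
        raise ValueError("modularity undefined on an empty graph")
    nk = int(labels.max()) + 1
    q = 0.0
    for l in range(nk):
        mask = labels == l
        e_ll = A[np.ix_(mask, mask)].sum() / m2  # fraction of edge ends
        d_l = A[mask].sum() / m2
        q += e_ll - d_l**2
    return float(q)


def _compress_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber labels to consecutive 0..K-1, ordered by first occurrence."""
    _, inv = np.unique(labels, return_inverse=True)
    return inv.astype(np.int64)


def k_split(
    D: np.ndarray,
    adjacency: np.ndarray,
    lpi_matrix: np.ndarray,
    dk: int = 10,
    seed: int = 0,
    max_bdp_iter: int = 100,
):
    """One divisive step: scan k, pick the modularity-optimal partition.

    For k = 2, 3, ... the cluster is partitioned by k-medoids on D, the
    boundary sweep is applied, and Newman modularity Q_k is recorded.  The
    scan stops once k exceeds (best k so far) + dk.  Returns
    ``(labels, profile)`` where profile maps k -> Q_k; labels is None when
    no partition achieves Q > 0 (no meaningful split).
    """
    n = D.shape[0]
    if n < 4:
        return None, {}
    profile: dict[int, float] = {}
    best_q = -np.inf
    best_labels = None
    best_k = None
    k = 2
    while k < n:
        raw = k_medoids_partition(D, k, seed=seed)
        lab = boundary_update(raw, adjacency, lpi_matrix, max_iter=max_bdp_iter)
        lab = _compress_labels(lab)
        if lab.max() == 0:  # collapsed to a single cluster
            profile[k] = -np.inf
        else:
            q = modularity(adjacency, lab)
            profile[k] = q
            if q > best_q:
                best_q = q
                best_labels = lab
                best_k = k
        if best_k is not None and k >= best_k + dk:
            break
        k += 1
    if best_labels is None or best_q <= 0:
        return None, profile
    return best_labels, profile


def split_decision(nu_parent: float, child_nus, alpha: float) -> bool:
    """Accept a split iff at least one child is strictly more compact."""
    del alpha  # the nu values must already be evaluated at a common alpha
    return any(nu_l < nu_parent for nu_l in child_nus)


def characteristic_alpha(
    spd_mean_parent: float,
    n_parent: int,
    spd_mean_child: float,
    n_child: int,
    alpha_parent: float,
    alpha_grid,
) -> float | None:
    """Largest admissible resolution at which the child beats its parent.

    The admissible set is {alpha in grid : alpha <= alpha_parent and
    nu_child(alpha) < nu_parent(alpha)}, with both compactness values
    evaluated at the same alpha; the characteristic alpha is its maximum,
    or None when the set is empty (the child never improves on the
    parent within the allowed range).
    """
    if n_child < 3 or n_child >= n_parent:
        return None
    grid = np.asarray(alpha_grid, dtype=float)
    grid = grid[grid <= alpha_parent + 1e-12]
    if grid.size == 0:
        return None
    nu_p = spd_mean_parent / np.log(n_parent) ** grid
    nu_c = spd_mean_child / np.log(n_child) ** grid
    ok = nu_c < nu_p
    if not ok.any():
        return None
    return float(grid[ok].max())


def _snowball_sample(adj_list, n_nodes: int, size: int, rng) -> np.ndarray:
    """Connected node subset grown from a uniformly chosen seed node."""
    start = int(rng.integers(n_nodes))
    chosen = np.zeros(n_nodes, dtype=bool)
    chosen[start] = True
    frontier = list(adj_list[start])
    in_frontier = np.zeros(n_nodes, dtype=bool)
    for x in frontier:
        in_frontier[x] = True
    picked = [start]
    while len(picked) < size and frontier:
        i = int(rng.integers(len(frontier)))
        v = frontier[i]
        frontier[i] = frontier[-1]
        frontier.pop()
        in_frontier[v] = False
        if chosen[v]:
            continue
        chosen[v] = True
        picked.append(v)
        for w in adj_list[v]:
            if not chosen[w] and not in_frontier[w]:
                frontier.append(w)
                in_frontier[w] = True
    return np.array(picked, dtype=np.int64)


def compactness_significance(
    parent_weights,
    n_parent: int,
    n_child: int,
    nu_child: float,
    alpha: float,
    n_rand: int = 100,
    seed: int | np.random.Generator = 0,
    transform: str = "one_minus_abs",
) -> float:
    """Monte-Carlo p-value of a child cluster's compactness.

    The null is a random planar triangulation of the parent's size whose
    edges carry the parent's shuffled weights; ``n_rand`` connected
    subsets of the child's size are sampled by snowball growth, their
    compactness nu' computed from the random network's shortest paths,
    and p = (1 + #{nu' <= nu_child}) / (1 + n_rand) (add-one estimator,
    small p = observed cluster more compact than random).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_child < 3:
        warnings.warn("cluster too small for a compactness null; p = 1", stacklevel=2)
        return 1.0
    n_parent = max(int(n_parent), 4)
    eu, ev = t2_edge_arrays(n_parent, rng)
    m = eu.shape[0]
    w = np.asarray(parent_weights, dtype=float)
    if w.size >= m:
        wl = rng.permutation(w)[:m]
    else:
        wl = rng.choice(w, size=m, replace=True)
    lengths = edge_lengths(wl, transform)
    g = csr_matrix((lengths, (eu, ev)), shape=(n_parent, n_parent))
    D = _csgraph_shortest_path(g, method="D", directed=False)
    adj_list = [[] for _ in range(n_parent)]
    for a, b in zip(eu, ev):
        adj_list[a].append(int(b))
        adj_list[b].append(int(a))
    size = min(n_child, n_parent)
    log_term = math.log(size) ** alpha
    count = 0
    for _ in range(n_rand):
        sel = _snowball_sample(adj_list, n_parent, size, rng)
        sub = D[np.ix_(sel, sel)]
        iu = np.triu_indices(sel.size, 1)
        nu_prime = float(np.mean(sub[iu])) / log_term
        if nu_prime <= nu_child:
            count += 1
    return (1 + count) / (1 + n_rand)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_mca(pfn: nx.Graph, config: MCAConfig | None = None) -> ClusterHierarchy:
    """Divisive multiscale decomposition of a PFN.

    Roots are the connected components.  Each cluster of at least
    ``min_split_size`` nodes is split with :func:`k_split`; children get
    characteristic alphas against their parent's compactness, the split
    is kept iff at least one child has one, and surviving children are
    tested against the random-triangulation null.  Recursion continues
    into significant children.  Disconnected clusters (possible after a
    boundary sweep) are first divided into their connected components,
    recorded as ``kind="component"`` pass-through children.
    """
    cfg = config or MCAConfig()
    rng = np.random.default_rng(cfg.seed)
    alpha_max = float(np.max(cfg.alpha_grid))
    hier = ClusterHierarchy(cfg.alpha_grid, sig_level=cfg.sig_level)

    comps = sorted(nx.connected_components(pfn), key=lambda c: (-len(c), str(min(map(str, c)))))
    counter = 0
    queue: list[str] = []
    for comp in comps:
        counter += 1
        cid = f"c{counter}"
        nodes = tuple(sorted(comp, key=str))
        root = Cluster(id=cid, parent=None, nodes=nodes, alpha_char=alpha_max, kind="root")
        hier.add(root)
        queue.append(cid)

    while queue:
        cid = queue.pop(0)
        clus = hier.clusters[cid]
        if clus.size < max(cfg.min_split_size, 4):
            continue
        sub = pfn.subgraph(clus.nodes)
        if not nx.is_connected(sub):
            for comp in sorted(
                nx.connected_components(sub), key=lambda c: (-len(c), str(min(map(str, c))))
            ):
                counter += 1
                kid = f"c{counter}"
                child = Cluster(
                    id=kid,
                    parent=cid,
                    nodes=tuple(sorted(comp, key=str)),
                    alpha_char=clus.alpha_char,
                    p_value=clus.p_value,
                    kind="component",
                )
                hier.add(child)
                queue.append(kid)
            continue
        D, order = shortest_path_matrix(
            sub, transform=cfg.length_transform, use_bellman_ford=cfg.use_bellman_ford
        )
        n_o = len(order)
        iu = np.triu_indices(n_o, 1)
        spd_o = float(np.mean(D[iu]))
        clus.spd_mean = spd_o
        if clus.nu is None and clus.alpha_char is not None:
            clus.nu = spd_o / math.log(n_o) ** clus.alpha_char
        A = nx.to_numpy_array(sub, nodelist=order, weight=None)
        L = _lpi_from_adjacency(A, cfg.epsilon)
        labels, _profile = k_split(
            D, A, L, dk=cfg.dk, seed=cfg.seed, max_bdp_iter=cfg.max_bdp_iter
        )
        if labels is None:
            continue
        order_arr = np.array(order, dtype=object)
        child_sets = []
        for l in range(int(labels.max()) + 1):
            members = np.where(labels == l)[0]
            child_sets.append(members)
        # deterministic child ordering: by size desc then first node label
        child_sets.sort(key=lambda m: (-m.size, str(order_arr[m[0]])))
        parent_alpha = clus.alpha_char if clus.alpha_char is not None else alpha_max
        infos = []
        any_accepted = False
        for members in child_sets:
            n_l = members.size
            if n_l >= 2:
                sub_d = D[np.ix_(members, members)]
                iu_l = np.triu_indices(n_l, 1)
                spd_l = float(np.mean(sub_d[iu_l]))
            else:
                spd_l = float("nan")
            a_c = characteristic_alpha(
                spd_o, n_o, spd_l, n_l, parent_alpha, cfg.alpha_grid
            )
            if a_c is not None:
                any_accepted = True
            infos.append((members, spd_l, a_c))
        if not any_accepted:
            continue  # split rejected at every alpha: leaf
        parent_w = np.array(
            [d.get("weight", 1.0) for _, _, d in sub.edges(data=True)], dtype=float
        )
        for members, spd_l, a_c in infos:
            counter += 1
            kid = f"c{counter}"
            nu_l = None
            p_val = None
            if a_c is not None:
                nu_l = spd_l / math.log(members.size) ** a_c
                p_val = compactness_significance(
                    parent_w,
                    n_o,
                    members.size,
                    nu_l,
                    a_c,
                    n_rand=cfg.n_rand,
                    seed=np.random.default_rng(rng.integers(2**31)),
                    transform=cfg.length_transform,
                )
            child = Cluster(
                id=kid,
                parent=cid,
                nodes=tuple(order_arr[members]),
                spd_mean=spd_l,
                alpha_char=a_c,
                nu=nu_l,
                p_value=p_val,
            )
            hier.add(child)
            if (
                a_c is not None
                and p_val is not None
                and p_val <= cfg.sig_level
                and child.size >= max(cfg.min_split_size, 4)
            ):
                queue.append(kid)
    return hier
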