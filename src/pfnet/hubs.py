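"""Multiscale hub analysis.

Resolution scales that produced at least one significant split are
characterized by the within-cluster connectivity profile of every node
(sum of edge weights to same-cluster neighbours).  Scales with similar
profiles are grouped by k-medoids on inter-profile Euclidean distances,
with the number of groups chosen by a committee of internal validity
indices.  Within each scale, a node's connectivity is compared against
random planar triangulations of its cluster's size; per-scale p-values
are combined over a scale group as S_i = sum(-log10 p_i(alpha)), whose
significance comes from a shuffled null, Bonferroni-corrected over the
network's nodes.  Nodes significant in every scale group are the
multiscale hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.metrics import silhouette_score

from .mca import ClusterHierarchy, k_medoids_partition
from .random_planar import t2_edge_arrays

__all__ = [
    "within_cluster_connectivity",
    "validity_indices",
    "combined_rank_score",
    "group_scales",
    "hub_pvalue_per_scale",
    "multiscale_hub_statistic",
    "hub_significance",
    "intersect_multiscale_hubs",
    "run_mha",
    "MHAConfig",
    "MHAResult",
]


@dataclass
class MHAConfig:
    n_s: int = 100  # random networks per cluster for connectivity nulls
    N_s: int = 100  # shuffles for the combined-statistic null
    sig_level: float = 0.05
    seed: int = 0


def within_cluster_connectivity(pfn: nx.Graph, membership: dict) -> pd.Series:
    """Per-node sum of |edge weight| to neighbours in the same cluster.

    ``membership`` maps node -> cluster id; nodes missing from the map or
    in singleton clusters get connectivity 0.
    """
    out = {}
    for v in pfn.nodes:
        cl = membership.get(v)
        total = 0.0
        if cl is not None:
            for _, u, w in pfn.edges(v, data="weight", default=1.0):
                if membership.get(u) == cl:
                    total += abs(w)
        out[v] = total
    return pd.Series(out, name="cw")


def _hubert_gamma(D: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices(D.shape[0], 1)
    x = (labels[iu[0]] != labels[iu[1]]).astype(float)
    return float((D[iu] * x).sum())


def validity_indices(labels, distance_matrix, n_perm: int = 100, seed: int = 0) -> dict:
    """Internal validity of a partition on a precomputed distance matrix.

    Returns average silhouette width, normalized (permutation-scaled)
    Hubert gamma, Dunn's index and a separation index; all are oriented
    so that larger means better-separated clusters.

    Normalized gamma is (gamma - mean_perm) / sd_perm of the raw Hubert
    statistic sum(D_ij * 1[different cluster]) over ``n_perm`` label
    permutations.  Dunn is min between-cluster distance over max
    within-cluster diameter.  Separation is the mean over clusters of the
    minimal distance from the cluster to any outside point, scaled by the
    mean within-cluster pairwise distance so that merging well-separated
    clusters is penalized.
    """
    D = np.asarray(distance_matrix, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("validity indices require at least 2 clusters")
    if (counts == 1).all():
        raise ValueError("validity indices undefined for singleton-only clusterings")
    sil = float(silhouette_score(D, labels, metric="precomputed"))
    rng = np.random.default_rng(seed)
    gamma = _hubert_gamma(D, labels)
    perm_vals = np.empty(n_perm)
    for t in range(n_perm):
        perm_vals[t] = _hubert_gamma(D, rng.permutation(labels))
    sd = perm_vals.std()
    norm_gamma = float((gamma - perm_vals.mean()) / sd) if sd > 0 else 0.0
    max_diam = 0.0
    min_between = np.inf
    seps = []
    within_sums, within_counts = 0.0, 0
    for l in uniq:
        mask = labels == l
        if mask.sum() > 1:
            sub = D[np.ix_(mask, mask)]
            max_diam = max(max_diam, float(sub.max()))
            within_sums += sub.sum() / 2.0
            within_counts += mask.sum() * (mask.sum() - 1) // 2
        between = D[np.ix_(mask, ~mask)]
        if between.size:
            min_between = min(min_between, float(between.min()))
            seps.append(float(between.min()))
    dunn = float(min_between / max_diam) if max_diam > 0 else float("inf")
    mean_within = within_sums / within_counts if within_counts else 0.0
    raw_sep = float(np.mean(seps)) if seps else 0.0
    separation = raw_sep / mean_within if mean_within > 0 else float("inf")
    return {
        "silhouette": sil,
        "normalized_gamma": norm_gamma,
        "dunn": dunn,
        "separation": separation,
    }


def combined_rank_score(index_table: pd.DataFrame, n_phi: int | None = None):
    """Choose k by summed log normalized ranks across validity indices.

    ``index_table`` is indexed by candidate k with one column per index
    (all oriented larger-is-better).  Each index ranks the candidates
    (dense ranks, rank 1 = best); score(k) = sum_m log(rank / (n_phi-1))
    and the chosen k minimizes the score, smallest k on ties.  Returns
    ``(chosen_k, scores)``.
    """
    if n_phi is None:
        n_phi = len(index_table) + 1
    denom = max(n_phi - 1, 1)
    ranks = pd.DataFrame(index=index_table.index, columns=index_table.columns, dtype=float)
    for col in index_table.columns:
        vals = index_table[col].to_numpy(dtype=float)
        ranks[col] = rankdata(-vals, method="dense")
    scores = np.log(ranks / denom).sum(axis=1)
    chosen = int(scores.index[np.argmin(scores.to_numpy())])
    return chosen, scores


def group_scales(cw: pd.DataFrame, seed: int = 0):
    """Group resolution scales by their connectivity-profile similarity.

    ``cw`` is nodes x alpha; columns are compared by Euclidean distance
    and clustered with k-medoids for k in [2, n_alpha - 1]; k is chosen by
    :func:`combined_rank_score`.  Fewer than 3 scales form a single
    group.  Returns a list of lists of column labels.
    """
    cols = list(cw.columns)
    if len(cols) < 3:
        return [cols]
    X = cw.to_numpy(dtype=float).T  # scales x nodes
    D = squareform(pdist(X, metric="euclidean"))
    rows = {}
    cache = {}
    for k in range(2, len(cols)):
        labels = k_medoids_partition(D, k, seed=seed)
        if np.unique(labels).size < 2:
            continue
        try:
            rows[k] = validity_indices(labels, D, seed=seed)
            cache[k] = labels
        except ValueError:
            continue
    if not rows:
        return [cols]
    table = pd.DataFrame(rows).T
    chosen, _ = combined_rank_score(table, n_phi=len(cols))
    labels = cache[chosen]
    groups = []
    for l in np.unique(labels):
        groups.append([cols[i] for i in np.where(labels == l)[0]])
    groups.sort(key=lambda g: cols.index(g[0]))
    return groups


def hub_pvalue_per_scale(
    cluster_connectivity: np.ndarray,
    cluster_weights,
    n_s: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Connectivity p-values for all members of one cluster at one scale.

    ``cluster_connectivity`` holds the observed within-cluster
    connectivity of the |V_l| member nodes; the null draws ``n_s`` random
    planar triangulations of the same size carrying the cluster's
    shuffled weights, and p_i = (1 + mean #{null nodes with connectivity
    >= c_i}) / (1 + |V_l|).  Clusters below 3 nodes get p = 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = np.asarray(cluster_connectivity, dtype=float)
    n_l = c.size
    if n_l < 3:
        return np.ones(n_l)
    w = np.abs(np.asarray(cluster_weights, dtype=float))
    m = 3 * (n_l - 2)
    null_degrees = np.empty(n_s * n_l)
    for t in range(n_s):
        eu, ev = t2_edge_arrays(n_l, rng)
        if w.size >= m:
            wl = rng.permutation(w)[:m]
        else:
            wl = rng.choice(w, size=m, replace=True)
        deg = np.bincount(eu, weights=wl, minlength=n_l) + np.bincount(
            ev, weights=wl, minlength=n_l
        )
        null_degrees[t * n_l : (t + 1) * n_l] = deg
    null_degrees.sort()
    # mean over nets of #{nodes >= c_i} = total count / n_s
    counts = null_degrees.size - np.searchsorted(null_degrees, c, side="left")
    mean_counts = counts / n_s
    return (1.0 + mean_counts) / (1.0 + n_l)


def multiscale_hub_statistic(p_values) -> float:
    """Combined evidence S = sum over scales of -log10 p."""
    p = np.asarray(p_values, dtype=float)
    if (p <= 0).any():
        warnings.warn("p = 0 clipped to machine minimum", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    return float(-np.log10(p).sum())


def hub_significance(
    p_matrix: np.ndarray,
    n_network_nodes: int,
    N_s: int = 100,
    seed: int | np.random.Generator = 0,
    sig_level: float = 0.05,
):
    """Significance of combined hub statistics within one scale group.

    ``p_matrix`` is nodes x scales (the per-scale connectivity p-values
    restricted to one scale group).  Observed S_i are compared against a
    null built by shuffling the matrix entries over both nodes and scales
    ``N_s`` times; nominal exceedance p-values (add-one estimator) are
    Bonferroni-corrected by the number of nodes in the whole network.
    Returns ``(S, corrected_p, hub_mask)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = np.maximum(np.asarray(p_matrix, dtype=float), np.finfo(float).tiny)
    n, k = P.shape
    S = -np.log10(P).sum(axis=1)
    flat = P.reshape(-1)
    null = np.empty(N_s * n)
    for t in range(N_s):
        shuf = rng.permutation(flat).reshape(n, k)
        null[t * n : (t + 1) * n] = -np.log10(shuf).sum(axis=1)
    null.sort()
    exceed = null.size - np.searchsorted(null, S, side="left")
    nominal = (1.0 + exceed) / (1.0 + null.size)
    corrected = np.minimum(nominal * n_network_nodes, 1.0)
    return S, corrected, corrected < sig_level


def intersect_multiscale_hubs(hub_sets) -> set:
    """Nodes flagged as hubs in every scale group."""
    sets = [set(s) for s in hub_sets]
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


@dataclass
class MHAResult:
    table: pd.DataFrame
    cw: pd.DataFrame
    phi: np.ndarray
    scale_groups: list = field(default_factory=list)
    hubs_per_group: dict = field(default_factory=dict)
    multiscale_hubs: set = field(default_factory=set)


def run_mha(
    pfn: nx.Graph,
    hierarchy: ClusterHierarchy,
    config: MHAConfig | None = None,
) -> MHAResult:
    """Full multiscale hub analysis of a clustered PFN."""
    cfg = config or MHAConfig()
    rng = np.random.default_rng(cfg.seed)
    nodes = sorted(pfn.nodes, key=str)
    phi = hierarchy.significant_alphas()
    empty = pd.DataFrame(index=nodes)
    if phi.size == 0:
        return MHAResult(
            table=pd.DataFrame(
                columns=["node", "scale_group", "S", "corrected_p", "is_hub", "is_multiscale_hub"]
            ),
            cw=empty,
            phi=phi,
        )
    # per-scale memberships, connectivity, and per-cluster p-values
    cw = pd.DataFrame(index=nodes, dtype=float)
    pvals = pd.DataFrame(index=nodes, dtype=float)
    cluster_p_cache: dict[str, dict] = {}
    for a in phi:
        membership = hierarchy.partition_at_alpha(a)
        col = within_cluster_connectivity(pfn, membership)
        cw[a] = col.reindex(nodes)
        pcol = pd.Series(1.0, index=nodes)
        for cid in sorted(set(membership.values())):
            members = sorted((v for v in membership if membership[v] == cid), key=str)
            if cid not in cluster_p_cache:
                wlist = [
                    abs(d.get("weight", 1.0))
                    for u, v, d in pfn.subgraph(members).edges(data=True)
                ]
                conn = cw[a].loc[members].to_numpy()
                p = hub_pvalue_per_scale(
                    conn,
                    np.asarray(wlist) if wlist else np.ones(1),
                    n_s=cfg.n_s,
                    seed=np.random.default_rng(rng.integers(2**31)),
                )
                cluster_p_cache[cid] = dict(zip(members, p))
            pmap = cluster_p_cache[cid]
            for v in members:
                pcol[v] = pmap[v]
        pvals[a] = pcol
    groups = group_scales(cw, seed=cfg.seed)
    rows = []
    hubs_per_group = {}
    for gi, group in enumerate(groups):
        P = pvals[group].to_numpy(dtype=float)
        S, corrected, is_hub = hub_significance(
            P,
            n_network_nodes=len(nodes),
            N_s=cfg.N_s,
            seed=np.random.default_rng(rng.integers(2**31)),
            sig_level=cfg.sig_level,
        )
        hubs_per_group[gi] = {nodes[i] for i in np.where(is_hub)[0]}
        for i, v in enumerate(nodes):
            rows.append(
                {
                    "node": v,
                    "scale_group": gi,
                    "cw_mean": float(cw[group].loc[v].mean()),
                    "S": float(S[i]),
                    "corrected_p": float(corrected[i]),
                    "is_hub": bool(is_hub[i]),
                }
            )
    multiscale = intersect_multiscale_hubs(hubs_per_group.values()) if hubs_per_group else set()
    table = pd.DataFrame(rows)
    if len(table):
        table["is_multiscale_hub"] = table["node"].isin(multiscale)
    return MHAResult(
        table=table,
        cw=cw,
        phi=phi,
        scale_groups=groups,
        hubs_per_group=hubs_per_group,
        multiscale_hubs=multiscale,
    )
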