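"""Linear-time planarity testing (left-right criterion).

The planar-embedding loop tests tens of thousands of candidate edges per
network, so the test is compiled with numba and operates on flat edge
arrays.  The left-right (de Fraysseix–Rosenstiehl) criterion is an exact
linear-time planarity characterization; it accepts and rejects exactly the
same graphs as any other exact test (e.g. Boyer–Myrvold), so the embedding
it gates is unchanged by the choice of algorithm.

Only the planar/non-planar decision is computed; no combinatorial embedding
is extracted.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = ["lr_planarity_edgelist", "is_planar_graph"]

_NONE = np.int64(-1)


@njit(cache=True)
def _lr_planar(n, eu, ev):  # noqa: C901 - single hot kernel, kept monolithic
    m = eu.shape[0]
    if n >= 3 and m > 3 * (n - 2):
        return False
    if m <= 2 or n < 3:
        return True

    # --- undirected CSR adjacency -------------------------------------
    deg = np.zeros(n + 1, dtype=np.int64)
    for k in range(m):
        deg[eu[k] + 1] += 1
        deg[ev[k] + 1] += 1
    adj_start = np.cumsum(deg)
    fill = adj_start[:-1].copy()
    adj_v = np.empty(2 * m, dtype=np.int64)
    adj_e = np.empty(2 * m, dtype=np.int64)
    for k in range(m):
        u = eu[k]
        v = ev[k]
        adj_v[fill[u]] = v
        adj_e[fill[u]] = k
        fill[u] += 1
        adj_v[fill[v]] = u
        adj_e[fill[v]] = k
        fill[v] += 1

    # --- phase 1: orientation DFS -------------------------------------
    height = np.full(n, -1, dtype=np.int64)
    parent_edge = np.full(n, -1, dtype=np.int64)
    oriented = np.zeros(m, dtype=np.uint8)
    esrc = np.full(m, -1, dtype=np.int64)
    edst = np.full(m, -1, dtype=np.int64)
    lowpt = np.zeros(m, dtype=np.int64)
    lowpt2 = np.zeros(m, dtype=np.int64)
    nesting = np.zeros(m, dtype=np.int64)

    st_v = np.empty(n + 1, dtype=np.int64)
    st_i = np.empty(n + 1, dtype=np.int64)

    for root in range(n):
        if height[root] != -1:
            continue
        height[root] = 0
        sp = 0
        st_v[0] = root
        st_i[0] = adj_start[root]
        while sp >= 0:
            v = st_v[sp]
            i = st_i[sp]
            if i < adj_start[v + 1]:
                st_i[sp] += 1
                e = adj_e[i]
                if oriented[e]:
                    continue
                w = adj_v[i]
                oriented[e] = 1
                esrc[e] = v
                edst[e] = w
                lowpt[e] = height[v]
                lowpt2[e] = height[v]
                if height[w] == -1:  # tree edge; finish after subtree
                    parent_edge[w] = e
                    height[w] = height[v] + 1
                    sp += 1
                    st_v[sp] = w
                    st_i[sp] = adj_start[w]
                else:  # back edge
                    lowpt[e] = height[w]
                    # finish immediately
                    nesting[e] = 2 * lowpt[e]
                    if lowpt2[e] < height[v]:
                        nesting[e] += 1
                    pe = parent_edge[v]
                    if pe != -1:
                        if lowpt[e] < lowpt[pe]:
                            lowpt2[pe] = min(lowpt[pe], lowpt2[e])
                            lowpt[pe] = lowpt[e]
                        elif lowpt[e] > lowpt[pe]:
                            lowpt2[pe] = min(lowpt2[pe], lowpt[e])
                        else:
                            lowpt2[pe] = min(lowpt2[pe], lowpt2[e])
            else:
                sp -= 1
                e = parent_edge[v]
                if e != -1 and v != root:
                    u = esrc[e]
                    nesting[e] = 2 * lowpt[e]
                    if lowpt2[e] < height[u]:
                        nesting[e] += 1
                    pe = parent_edge[u]
                    if pe != -1:
                        if lowpt[e] < lowpt[pe]:
                            lowpt2[pe] = min(lowpt[pe], lowpt2[e])
                            lowpt[pe] = lowpt[e]
                        elif lowpt[e] > lowpt[pe]:
                            lowpt2[pe] = min(lowpt2[pe], lowpt[e])
                        else:
                            lowpt2[pe] = min(lowpt2[pe], lowpt2[e])

    # --- phase 2: out-adjacency ordered by nesting depth --------------
    # stable counting over key = src * (2n + 2) + nesting
    key = np.empty(m, dtype=np.int64)
    for e in range(m):
        key[e] = esrc[e] * (2 * n + 2) + nesting[e]
    order = np.argsort(key, kind="mergesort")
    out_start = np.zeros(n + 1, dtype=np.int64)
    for e in range(m):
        out_start[esrc[e] + 1] += 1
    out_start = np.cumsum(out_start)

    # --- phase 3: testing DFS -----------------------------------------
    lowpt_edge = np.full(m, -1, dtype=np.int64)
    stack_bottom = np.full(m, -1, dtype=np.int64)
    ref = np.full(m, -1, dtype=np.int64)

    # conflict-pair stack: (L.low, L.high, R.low, R.high)
    s_ll = np.empty(m + 1, dtype=np.int64)
    s_lh = np.empty(m + 1, dtype=np.int64)
    s_rl = np.empty(m + 1, dtype=np.int64)
    s_rh = np.empty(m + 1, dtype=np.int64)
    ssize = 0

    f_v = np.empty(n + 1, dtype=np.int64)
    f_i = np.empty(n + 1, dtype=np.int64)
    f_pend = np.empty(n + 1, dtype=np.int64)

    for root in range(n):
        if parent_edge[root] != -1:
            continue
        sp = 0
        f_v[0] = root
        f_i[0] = out_start[root]
        f_pend[0] = -1
        while sp >= 0:
            v = f_v[sp]
            ei = -1
            if f_pend[sp] != -1:
                ei = f_pend[sp]
                f_pend[sp] = -1
            else:
                i = f_i[sp]
                if i < out_start[v + 1]:
                    f_i[sp] += 1
                    ei = order[i]
                    stack_bottom[ei] = ssize
                    w = edst[ei]
                    if parent_edge[w] == ei:  # tree edge: recurse first
                        f_pend[sp] = ei
                        sp += 1
                        f_v[sp] = w
                        f_i[sp] = out_start[w]
                        f_pend[sp] = -1
                        continue
                    # back edge
                    lowpt_edge[ei] = ei
                    s_ll[ssize] = -1
                    s_lh[ssize] = -1
                    s_rl[ssize] = ei
                    s_rh[ssize] = ei
                    ssize += 1
                else:
                    # vertex epilogue
                    e = parent_edge[v]
                    if e != -1:
                        u = esrc[e]
                        hu = height[u]
                        # drop pairs whose lowest return point is u
                        while ssize > 0:
                            tll = s_ll[ssize - 1]
                            trl = s_rl[ssize - 1]
                            if tll != -1 and trl != -1:
                                low = min(lowpt[tll], lowpt[trl])
                            elif tll != -1:
                                low = lowpt[tll]
                            else:
                                low = lowpt[trl]
                            if low != hu:
                                break
                            ssize -= 1
                        if ssize > 0:
                            ssize -= 1
                            pll = s_ll[ssize]
                            plh = s_lh[ssize]
                            prl = s_rl[ssize]
                            prh = s_rh[ssize]
                            # trim left interval
                            while plh != -1 and edst[plh] == u:
                                plh = ref[plh]
                            if plh == -1 and pll != -1:
                                ref[pll] = prl
                                pll = -1
                            # trim right interval
                            while prh != -1 and edst[prh] == u:
                                prh = ref[prh]
                            if prh == -1 and prl != -1:
                                ref[prl] = pll
                                prl = -1
                            s_ll[ssize] = pll
                            s_lh[ssize] = plh
                            s_rl[ssize] = prl
                            s_rh[ssize] = prh
                            ssize += 1
                    sp -= 1
                    continue

            # integrate-constraints step for edge ei out of v
            if lowpt[ei] < height[v]:  # ei has a return edge
                e = parent_edge[v]
                first = order[out_start[v]]
                if ei == first:
                    if e != -1:
                        lowpt_edge[e] = lowpt_edge[ei]
                else:
                    # merge return edges of ei into P.R
                    pll = np.int64(-1)
                    plh = np.int64(-1)
                    prl = np.int64(-1)
                    prh = np.int64(-1)
                    while True:
                        ssize -= 1
                        qll = s_ll[ssize]
                        qlh = s_lh[ssize]
                        qrl = s_rl[ssize]
                        qrh = s_rh[ssize]
                        if qll != -1:
                            qll, qrl = qrl, qll
                            qlh, qrh = qrh, qlh
                        if qll != -1:
                            return False
                        if qrl != -1:
                            if lowpt[qrl] > lowpt[e]:
                                # merge into P.R
                                if prh == -1:
                                    prh = qrh
                                else:
                                    ref[prl] = qrh
                                prl = qrl
                            else:
                                # align under lowpt(e)
                                ref[qrl] = lowpt_edge[e]
                        if ssize == stack_bottom[ei]:
                            break
                    # merge conflicting return edges of earlier siblings
                    while ssize > 0:
                        tll = s_ll[ssize - 1]
                        tlh = s_lh[ssize - 1]
                        trl = s_rl[ssize - 1]
                        trh = s_rh[ssize - 1]
                        confl_l = tlh != -1 and lowpt[tlh] > lowpt[ei]
                        confl_r = trh != -1 and lowpt[trh] > lowpt[ei]
                        if not (confl_l or confl_r):
                            break
                        ssize -= 1
                        qll = tll
                        qlh = tlh
                        qrl = trl
                        qrh = trh
                        if qrh != -1 and lowpt[qrh] > lowpt[ei]:
                            qll, qrl = qrl, qll
                            qlh, qrh = qrh, qlh
                        if qrh != -1 and lowpt[qrh] > lowpt[ei]:
                            return False
                        # merge Q.R (below lowpt(ei)) into P.R
                        if qrh != -1:
                            if prl != -1:
                                ref[prl] = qrh
                            elif prh == -1:
                                prh = qrh
                        if qrl != -1:
                            prl = qrl
                        # merge Q.L into P.L
                        if qlh != -1:
                            if plh == -1:
                                plh = qlh
                            else:
                                ref[pll] = qlh
                        if qll != -1:
                            pll = qll
                    if pll != -1 or plh != -1 or prl != -1 or prh != -1:
                        s_ll[ssize] = pll
                        s_lh[ssize] = plh
                        s_rl[ssize] = prl
                        s_rh[ssize] = prh
                        ssize += 1
    return True


def lr_planarity_edgelist(n_nodes: int, edges_u, edges_v) -> bool:
    """Planarity of the simple undirected graph on ``n_nodes`` vertices.

    Parameters are integer vertex labels in ``[0, n_nodes)``; parallel
    edges and self-loops must have been removed by the caller.
    """
    eu = np.ascontiguousarray(edges_u, dtype=np.int64)
    ev = np.ascontiguousarray(edges_v, dtype=np.int64)
    return bool(_lr_planar(int(n_nodes), eu, ev))


def is_planar_graph(graph) -> bool:
    """Planarity of a networkx graph via the compiled left-right test."""
    nodes = list(graph.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    m = graph.number_of_edges()
    eu = np.empty(m, dtype=np.int64)
    ev = np.empty(m, dtype=np.int64)
    for k, (u, v) in enumerate(graph.edges):
        eu[k] = index[u]
        ev[k] = index[v]
    return bool(_lr_planar(len(nodes), eu, ev))
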