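"""Planar filtered network (PFN) construction.

A PFN is grown by visiting candidate gene pairs in rank order and keeping
each pair only if the graph stays planar — the planar maximally filtered
graph (PMFG) recipe.  Because any subgraph of a planar graph is planar,
an edge rejected against the current graph can never be accepted later,
which enables two accelerations without changing the result:

* batch screening (PCP): a block of upcoming candidates is pre-tested,
  each independently, against a frozen snapshot of the current graph;
  survivors are then embedded serially in their original rank order;
* early termination: construction stops once the edge count approaches
  the Euler bound 3(|V|-2) or the rejection budget is exhausted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._planarity import _lr_planar, is_planar_graph

__all__ = [
    "TerminationConfig",
    "euler_max_edges",
    "is_planar",
    "serial_embed",
    "pcp_screen",
    "build_pfn",
    "degree_diagnostics",
]


def euler_max_edges(n_nodes: int) -> int:
    """Maximal edge count of a planar graph on ``n_nodes`` >= 3 vertices.

    From Euler's polyhedron relation, a simple planar graph has at most
    3(|V| - 2) edges, attained exactly by planar triangulations.
    """
    n = int(n_nodes)
    if n < 3:
        raise ValueError("the Euler bound 3(|V|-2) requires |V| >= 3")
    return 3 * (n - 2)


def is_planar(graph) -> bool:
    """True iff ``graph`` (a networkx graph) is planar."""
    return is_planar_graph(graph)


@dataclass
class TerminationConfig:
    """Early-termination and screening policy for PFN construction.

    saturation_fraction
        Stop once |E| >= saturation_fraction * 3(|V|-2).  1.0 disables the
        saturation stop (full PMFG); the recommended operating range is
        0.90-0.95.
    reject_budget_multiplier
        Stop once the cumulative number of rejected pairs reaches
        multiplier * |V|.  Screening rejections count toward the budget.
        ``None`` disables the budget.
    pcp_trigger
        Switch from serial embedding to batch screening once the
        sliding-window acceptance rate (accepted / tested over the last
        ``window`` tests) drops below this value.  0 starts screening
        immediately, 1 effectively from the first full window.
    batch_size
        Number of candidates screened per batch; the customary size is
        1000 per worker.
    """

    saturation_fraction: float = 0.95
    reject_budget_multiplier: float | None = 20.0
    pcp_trigger: float = 0.10
    window: int = 1000
    batch_size: int = 1000
    n_jobs: int = 1

    def __post_init__(self):
        if not (0.0 < self.saturation_fraction <= 1.0):
            raise ValueError("saturation_fraction must be in (0, 1]")
        if self.reject_budget_multiplier is not None and self.reject_budget_multiplier <= 0:
            raise ValueError("reject_budget_multiplier must be positive or None")


def _pairs_to_arrays(pairs):
    """Normalize a ranked pair list to (node labels, i-idx, j-idx, weights)."""
    import pandas as pd

    if isinstance(pairs, pd.DataFrame):
        a = pairs["node1"].to_numpy(dtype=object)
        b = pairs["node2"].to_numpy(dtype=object)
        w = pairs["similarity"].to_numpy(dtype=float)
    else:
        rows = list(pairs)
        a = np.array([r[0] for r in rows], dtype=object)
        b = np.array([r[1] for r in rows], dtype=object)
        w = np.array([r[2] for r in rows], dtype=float)
    labels: list = []
    index: dict = {}
    for x in np.concatenate([a, b]):
        if x not in index:
            index[x] = len(labels)
            labels.append(x)
    ai = np.fromiter((index[x] for x in a), dtype=np.int64, count=len(a))
    bi = np.fromiter((index[x] for x in b), dtype=np.int64, count=len(b))
    return labels, ai, bi, w


class _Embedder:
    """Mutable planar-embedding state over integer node indices."""

    def __init__(self, n_nodes: int):
        self.n = n_nodes
        cap = max(euler_max_edges(max(n_nodes, 3)), 1) + 1
        self.eu = np.empty(cap, dtype=np.int64)
        self.ev = np.empty(cap, dtype=np.int64)
        self.ew = np.empty(cap, dtype=float)
        self.m = 0
        self.accepted = 0
        self.rejected = 0

    def try_edge(self, i: int, j: int, w: float) -> bool:
        self.eu[self.m] = i
        self.ev[self.m] = j
        ok = bool(_lr_planar(self.n, self.eu[: self.m + 1], self.ev[: self.m + 1]))
        if ok:
            self.ew[self.m] = w
            self.m += 1
            self.accepted += 1
        else:
            self.rejected += 1
        return ok

    def would_keep_planar(self, i: int, j: int) -> bool:
        """Planarity of the current graph plus edge (i, j), without mutation."""
        self.eu[self.m] = i
        self.ev[self.m] = j
        return bool(_lr_planar(self.n, self.eu[: self.m + 1], self.ev[: self.m + 1]))

    def to_graph(self, labels) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(labels)
        for k in range(self.m):
            g.add_edge(labels[self.eu[k]], labels[self.ev[k]], weight=float(self.ew[k]))
        return g


def serial_embed(pairs, termination: TerminationConfig | None = None) -> nx.Graph:
    """Grow a PFN by strictly serial rank-order embedding.

    With default-constructed ``TerminationConfig(saturation_fraction=1.0,
    reject_budget_multiplier=None)`` this is the exact PMFG of the input
    ranking.  Returns a weighted undirected planar graph; bookkeeping
    (pairs tested/accepted/rejected, the termination condition that fired)
    is stored in ``graph.graph``.
    """
    cfg = termination or TerminationConfig(
        saturation_fraction=1.0, reject_budget_multiplier=None, pcp_trigger=0.0
    )
    labels, ai, bi, w = _pairs_to_arrays(pairs)
    emb = _Embedder(len(labels))
    emax = euler_max_edges(max(len(labels), 3))
    stop_edges = int(math.ceil(cfg.saturation_fraction * emax))
    budget = (
        None
        if cfg.reject_budget_multiplier is None
        else cfg.reject_budget_multiplier * len(labels)
    )
    condition = "exhausted"
    for k in range(len(ai)):
        emb.try_edge(ai[k], bi[k], w[k])
        if emb.m >= emax:
            condition = "maximal"
            break
        if emb.m >= stop_edges:
            condition = "saturation"
            break
        if budget is not None and emb.rejected >= budget:
            condition = "reject_budget"
            break
    g = emb.to_graph(labels)
    g.graph.update(
        tested=emb.accepted + emb.rejected,
        accepted=emb.accepted,
        rejected=emb.rejected,
        termination=condition,
        max_edges=emax,
    )
    return g


def pcp_screen(network: nx.Graph, candidates, n_jobs: int = 1):
    """Batch screening of candidate pairs against a planar graph.

    Returns, in input order, exactly those candidate pairs (u, v) for
    which ``network + {uv}`` remains planar.  Each candidate is tested
    independently against the same frozen graph, so the outcome does not
    depend on evaluation order or on how the batch is split across
    workers — the contract that makes screening parallelizable.
    """
    labels = list(network.nodes)
    index = {u: i for i, u in enumerate(labels)}
    cand = list(candidates)
    m = network.number_of_edges()
    eu = np.empty(m + 1, dtype=np.int64)
    ev = np.empty(m + 1, dtype=np.int64)
    for k, (u, v) in enumerate(network.edges):
        eu[k] = index[u]
        ev[k] = index[v]
    n = len(labels)
    extra = [x for uv in cand for x in uv[:2] if x not in index]
    for x in extra:
        if x not in index:
            index[x] = n
            n += 1

    def _test(u, v):
        eu[m] = index[u]
        ev[m] = index[v]
        return bool(_lr_planar(n, eu[: m + 1], ev[: m + 1]))

    if n_jobs > 1 and len(cand) > 1:
        from joblib import Parallel, delayed

        chunks = np.array_split(np.arange(len(cand)), n_jobs)

        def _run(idx):
            e1 = eu.copy()
            e2 = ev.copy()
            out = []
            for t in idx:
                u, v = cand[t][0], cand[t][1]
                e1[m] = index[u]
                e2[m] = index[v]
                out.append(bool(_lr_planar(n, e1[: m + 1], e2[: m + 1])))
            return out

        flags_parts = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(_run)(idx) for idx in chunks
        )
        flags = [f for part in flags_parts for f in part]
    else:
        flags = [_test(uv[0], uv[1]) for uv in cand]
    return [uv for uv, ok in zip(cand, flags) if ok]


def build_pfn(pairs, config: TerminationConfig | None = None) -> nx.Graph:
    """Construct a PFN with serial start-up, batch screening, termination.

    Embedding begins serially; once the sliding-window acceptance rate
    falls below ``config.pcp_trigger`` it switches to screened batches of
    ``config.batch_size`` candidates.  Construction stops at the first
    satisfied condition: (i) candidate list exhausted or maximal planar
    embedding reached; (ii) saturation |E| >= fraction * 3(|V|-2);
    (iii) cumulative rejections >= multiplier * |V|.  The output edge set
    equals :func:`serial_embed` run with the same termination settings.
    """
    cfg = config or TerminationConfig()
    labels, ai, bi, w = _pairs_to_arrays(pairs)
    if len(ai) == 0:
        raise ValueError("empty candidate pair list")
    nn = len(labels)
    emb = _Embedder(nn)
    emax = euler_max_edges(max(nn, 3))
    stop_edges = int(math.ceil(cfg.saturation_fraction * emax))
    budget = (
        None if cfg.reject_budget_multiplier is None else cfg.reject_budget_multiplier * nn
    )
    window = max(int(cfg.window), 1)
    recent = np.ones(window, dtype=np.int8)  # outcome ring buffer
    wpos = 0
    wsum = window
    condition = "exhausted"
    cursor = 0
    total = len(ai)
    screening = cfg.pcp_trigger >= 1.0
    done = False

    def _record(ok: bool):
        nonlocal wpos, wsum
        wsum += (1 if ok else 0) - int(recent[wpos])
        recent[wpos] = 1 if ok else 0
        wpos = (wpos + 1) % window

    def _stop() -> str | None:
        if emb.m >= emax:
            return "maximal"
        if emb.m >= stop_edges:
            return "saturation"
        if budget is not None and emb.rejected >= budget:
            return "reject_budget"
        return None

    while cursor < total and not done:
        if not screening:
            ok = emb.try_edge(ai[cursor], bi[cursor], w[cursor])
            _record(ok)
            cursor += 1
            cond = _stop()
            if cond:
                condition = cond
                done = True
            elif emb.accepted + emb.rejected >= window and wsum / window < cfg.pcp_trigger:
                screening = True
        else:
            hi = min(cursor + cfg.batch_size * max(int(cfg.n_jobs), 1), total)
            batch = np.arange(cursor, hi)
            # screen every candidate against the frozen snapshot; a pair
            # failing here fails against any supergraph, so its rejection
            # is exact, not heuristic
            keep = np.empty(batch.size, dtype=bool)
            snap = emb.m
            for t, k in enumerate(batch):
                keep[t] = emb.would_keep_planar(ai[k], bi[k])
            assert emb.m == snap
            # replay the batch in rank order so counters, budget and stop
            # conditions advance exactly as in serial embedding
            for t, k in enumerate(batch):
                if keep[t]:
                    ok = emb.try_edge(ai[k], bi[k], w[k])
                else:
                    emb.rejected += 1
                    ok = False
                _record(ok)
                cursor = k + 1
                cond = _stop()
                if cond:
                    condition = cond
                    done = True
                    break
    if not done and emb.m >= emax:
        condition = "maximal"
    g = emb.to_graph(labels)
    g.graph.update(
        tested=emb.accepted + emb.rejected,
        accepted=emb.accepted,
        rejected=emb.rejected,
        termination=condition,
        max_edges=emax,
        saturation=emb.m / emax,
    )
    return g


def degree_diagnostics(network: nx.Graph) -> dict:
    """Topological diagnostics: tail exponent of the degree law, diameter.

    The inverse cumulative degree distribution P(k' > k) of a network with
    degree law P(k) ~ k^(-gamma) behaves as k^(1-gamma); an ordinary
    least-squares fit of log P(k' > k) on log k over the observed degrees
    gives slope s and the reported exponent gamma = 1 - s.  Degenerate
    degree sequences (fewer than 3 distinct positive degrees) yield
    gamma = NaN with ``degenerate=True``.

    The diameter is the maximum unweighted eccentricity over the largest
    connected component.
    """
    degrees = np.array([d for _, d in network.degree()], dtype=float)
    out: dict = {}
    pos = degrees[degrees > 0]
    uniq = np.unique(pos)
    if uniq.size < 3:
        out["gamma"] = float("nan")
        out["degenerate"] = True
    else:
        # P(k' > k) at each observed degree k (strictly greater)
        ks = uniq[:-1]  # last degree has P = 0
        surv = np.array([(pos > k).mean() for k in ks])
        x = np.log(ks)
        y = np.log(surv)
        slope, intercept = np.polyfit(x, y, 1)
        out["gamma"] = float(1.0 - slope)
        out["degenerate"] = False
        out["fit_points"] = (x, y)
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    comp = max(nx.connected_components(network), key=len)
    sub = network.subgraph(comp)
    if len(comp) > 1:
        out["diameter"] = nx.diameter(sub)
    else:
        out["diameter"] = 0
    out["n_components"] = nx.number_connected_components(network)
    return out
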