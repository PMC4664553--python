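"""Synthetic expression data with planted co-expression structure.

A latent-factor model generates gene expression with known module
membership, optional two-level (super-module / sub-module) hierarchy,
planted hub genes and simulated survival, so that every pipeline stage
can be validated against ground truth.  For a gene in sub-module m of
super-module s,

    x_g = lambda * F_s + mu * G_m + sigma_g * eps,

with independent standard-normal factors and noise; the within-sub-module
correlation has the closed form (lambda^2 + mu^2) / (lambda^2 + mu^2 +
sigma^2), which the tests exploit.  By default sigma is chosen so each
gene has unit variance, making the squared loadings directly the expected
correlations.  Hub genes receive inflated loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "PlantedDesign",
    "SyntheticDataset",
    "generate_expression",
    "generate_survival",
    "evaluate_against_gold",
]


@dataclass
class PlantedDesign:
    """Specification of a planted co-expression dataset.

    module_sizes
        Sizes of the (sub-)modules; genes beyond their sum are pure
        noise background.
    loading
        Module-factor loading in (0, 1); with the default unit-variance
        noise the expected within-module correlation is loading^2.
    super_groups
        Optional grouping of module indices into super-modules, e.g.
        ((0, 1, 2), (3, 4, 5)); genes then load ``super_loading`` on the
        shared super-factor and ``loading`` on their sub-factor.
    hub_genes_per_module / hub_loading
        The first ``hub_genes_per_module`` genes of each module get the
        (higher) ``hub_loading`` on the module factor, making them the
        planted hubs.
    noise_sd
        Residual standard deviation; None selects the unit-variance
        choice sqrt(1 - total squared loading) per gene.
    """

    n_genes: int = 100
    n_samples: int = 200
    module_sizes: tuple = (25, 25, 25, 25)
    loading: float = 0.8
    super_groups: tuple | None = None
    super_loading: float = 0.6
    hub_genes_per_module: int = 0
    hub_loading: float = 0.95
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self):
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the number of genes")
        if not 0.0 <= self.loading < 1.0:
            raise ValueError("loading must be in [0, 1)")
        if self.super_groups is not None:
            flat = [m for g in self.super_groups for m in g]
            if sorted(flat) != list(range(len(self.module_sizes))):
                raise ValueError("super_groups must partition the module indices")


@dataclass
class SyntheticDataset:
    expr: pd.DataFrame  # genes x samples
    module_labels: pd.Series  # gene -> module id (0 = background)
    super_labels: pd.Series  # gene -> super-module id (0 = background)
    hub_genes: list
    module_factors: pd.DataFrame  # samples x modules (latent truths)
    gold_edges: set = field(default_factory=set)


def generate_expression(design: PlantedDesign) -> SyntheticDataset:
    """Draw a dataset from the planted latent-factor design.

    Returns expression (genes x samples), gold module and super-module
    labels, the planted hub list, the latent module factors (one column
    per module, usable as survival truth), and the gold-standard edge set
    (all within-module pairs).  Bit-reproducible for a fixed seed.
    """
    d = design
    rng = np.random.default_rng(d.seed)
    n_mod = len(d.module_sizes)
    genes = [f"g{i:04d}" for i in range(d.n_genes)]
    samples = [f"s{j:03d}" for j in range(d.n_samples)]
    sub_f = rng.standard_normal((n_mod, d.n_samples))
    if d.super_groups is not None:
        super_of = {}
        for si, grp in enumerate(d.super_groups):
            for m in grp:
                super_of[m] = si
        sup_f = rng.standard_normal((len(d.super_groups), d.n_samples))
    else:
        super_of = {m: m for m in range(n_mod)}
        sup_f = None
    X = np.empty((d.n_genes, d.n_samples))
    labels = np.zeros(d.n_genes, dtype=np.int64)
    super_labels = np.zeros(d.n_genes, dtype=np.int64)
    hubs = []
    g = 0
    for m, size in enumerate(d.module_sizes):
        for t in range(size):
            lam = d.hub_loading if t < d.hub_genes_per_module else d.loading
            if t < d.hub_genes_per_module:
                hubs.append(genes[g])
            if sup_f is not None:
                l_sup = d.super_loading
                total2 = lam**2 + l_sup**2
            else:
                l_sup = 0.0
                total2 = lam**2
            if d.noise_sd is None:
                sigma = float(np.sqrt(max(1.0 - total2, 1e-6)))
            else:
                sigma = d.noise_sd
            x = lam * sub_f[m]
            if sup_f is not None:
                x = x + l_sup * sup_f[super_of[m]]
            X[g] = x + sigma * rng.standard_normal(d.n_samples)
            labels[g] = m + 1
            super_labels[g] = super_of[m] + 1
            g += 1
    for i in range(g, d.n_genes):  # background noise genes
        sigma = 1.0 if d.noise_sd is None else d.noise_sd
        X[i] = sigma * rng.standard_normal(d.n_samples)
    gold = set()
    for m in range(1, n_mod + 1):
        members = [genes[i] for i in np.where(labels == m)[0]]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                gold.add((a, b) if a <= b else (b, a))
    return SyntheticDataset(
        expr=pd.DataFrame(X, index=genes, columns=samples),
        module_labels=pd.Series(labels, index=genes, name="module"),
        super_labels=pd.Series(super_labels, index=genes, name="super_module"),
        hub_genes=hubs,
        module_factors=pd.DataFrame(
            sub_f.T, index=samples, columns=[f"m{m + 1}" for m in range(n_mod)]
        ),
        gold_edges=gold,
    )


def generate_survival(
    factor: pd.Series,
    hazard_ratio: float = 1.0,
    censoring_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with log-hazard linear in a latent factor.

    Event time T ~ Exp(rate = HR^z) for factor value z, so a one-unit
    increase multiplies the hazard by ``hazard_ratio``.  Censoring is an
    independent exponential clock whose rate is set so a fraction
    ``censoring_rate`` of a neutral (z = 0) population is censored;
    ``censoring_rate=0`` disables it.  Returns a (time, event) frame.
    """
    rng = np.random.default_rng(seed)
    z = np.asarray(factor, dtype=float)
    rate = np.power(hazard_ratio, z)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        c_rate = censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=z.size)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(z.size, dtype=int)
    return pd.DataFrame({"time": time, "event": event}, index=factor.index)


def evaluate_against_gold(network: nx.Graph, gold_edges, node_universe=None) -> float:
    """AUC-ROC of weighted shortest-path proximity against gold edges.

    Every unordered node pair in the universe is scored by the negative
    weighted shortest-path distance in the inferred network (unreachable
    pairs score worst); pairs present in the gold standard are positives.
    The AUC is the Mann-Whitney rank statistic of the scores.
    """
    from .mca import shortest_path_matrix

    if node_universe is None:
        nodes = sorted(network.nodes, key=str)
    else:
        nodes = sorted(node_universe, key=str)
    D, order = shortest_path_matrix(network.subgraph(nodes))
    idx = {u: i for i, u in enumerate(order)}
    gold = {tuple(sorted(map(str, e))) for e in gold_edges}
    y, scores = [], []
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            a, b = str(order[i]), str(order[j])
            key = (a, b) if a <= b else (b, a)
            y.append(1 if key in gold else 0)
            d = D[idx[order[i]], idx[order[j]]]
            scores.append(-d if np.isfinite(d) else -1e18)
    y = np.asarray(y)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("AUC undefined: need both gold and non-gold pairs")
    return float(roc_auc_score(y, np.asarray(scores)))
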