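"""Model/Results interface over the full pipeline.

:class:`MultiscaleNetworkModel` holds the expression data and the run
configuration; :meth:`fit` executes similarity -> planar filtering ->
multiscale clustering -> hub analysis and returns a
:class:`MultiscaleNetworkResults` carrying the network, the cluster
hierarchy, the hub table and diagnostics, with trait and survival
association available as methods on the results.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pfio
from .hubs import MHAConfig, MHAResult, run_mha
from .mca import MCAConfig, ClusterHierarchy, run_mca
from .planar import TerminationConfig, build_pfn, degree_diagnostics
from .similarity import (
    ExpressionMatrix,
    compute_similarity,
    filter_and_rank,
    fisher_z_pvalue,
    permutation_fdr,
)
from .traits import associate_clusters

__all__ = ["RunConfig", "MultiscaleNetworkModel", "MultiscaleNetworkResults"]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with the standard defaults."""

    method: str = "pcc"
    fdr_threshold: float = 0.05
    rank_by: str = "abs"
    n_perm: int = 20  # permutation FDR draws (mi / euclidean routes)
    saturation_fraction: float = 0.95
    reject_budget_multiplier: float | None = 20.0
    pcp_trigger: float = 0.10
    batch_size: int = 1000
    n_jobs: int = 1
    alpha_grid: np.ndarray = field(default_factory=lambda: np.geomspace(0.02, 10.0, 50))
    n_rand: int = 100
    dk: int = 10
    epsilon: float = 0.01
    sig_level: float = 0.05
    min_split_size: int = 4
    length_transform: str = "one_minus_abs"
    n_s: int = 100
    N_s: int = 100
    seed: int = 0

    def termination(self) -> TerminationConfig:
        return TerminationConfig(
            saturation_fraction=self.saturation_fraction,
            reject_budget_multiplier=self.reject_budget_multiplier,
            pcp_trigger=self.pcp_trigger,
            batch_size=self.batch_size,
            n_jobs=self.n_jobs,
        )

    def mca(self, seed: int) -> MCAConfig:
        return MCAConfig(
            alpha_grid=self.alpha_grid,
            n_rand=self.n_rand,
            dk=self.dk,
            epsilon=self.epsilon,
            sig_level=self.sig_level,
            min_split_size=self.min_split_size,
            length_transform=self.length_transform,
            seed=seed,
        )

    def mha(self, seed: int) -> MHAConfig:
        return MHAConfig(n_s=self.n_s, N_s=self.N_s, sig_level=self.sig_level, seed=seed)


class MultiscaleNetworkModel:
    """Planar filtered co-expression network analysis of one dataset.

    Parameters
    ----------
    expr
        Genes x samples expression, as a DataFrame or
        :class:`~pfnet.similarity.ExpressionMatrix`.
    config
        :class:`RunConfig`; individual keyword overrides are applied on
        top of the defaults.
    """

    def __init__(self, expr, config: RunConfig | None = None, **overrides):
        if isinstance(expr, ExpressionMatrix):
            self.expr = expr.to_dataframe()
        else:
            self.expr = pd.DataFrame(expr).copy()
            self.expr.index = self.expr.index.map(str)
            self.expr.columns = self.expr.columns.map(str)
        cfg = config or RunConfig()
        if overrides:
            cfg = RunConfig(**{**asdict(cfg), **overrides})
        self.config = cfg

    @classmethod
    def from_expression_file(cls, path, **kwargs) -> "MultiscaleNetworkModel":
        return cls(pfio.read_expression(path), **kwargs)

    def rank_pairs(self, seed: int | None = None) -> pd.DataFrame:
        """Similarity + significance filtering, without embedding."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        sim = compute_similarity(self.expr, cfg.method)
        gene_ids = list(self.expr.index)
        n_samples = self.expr.shape[1]
        if cfg.method == "pcc":
            iu = np.triu_indices(len(gene_ids), 1)
            pmat = np.full(sim.shape, np.nan)
            pv = fisher_z_pvalue(sim[iu], n_samples)
            pmat[iu] = pv
            pmat[(iu[1], iu[0])] = pv
            return filter_and_rank(
                sim, gene_ids, pvals=pmat, fdr_threshold=cfg.fdr_threshold, rank_by=cfg.rank_by
            )
        fdrs = permutation_fdr(self.expr, cfg.method, n_perm=cfg.n_perm, seed=seed)
        return filter_and_rank(
            sim, gene_ids, fdrs=fdrs, fdr_threshold=cfg.fdr_threshold, rank_by=cfg.rank_by
        )

    def fit(self, seed: int | None = None) -> "MultiscaleNetworkResults":
        """Run the full pipeline and return the results object."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        pairs = self.rank_pairs(seed=int(rng.integers(2**31)))
        network = build_pfn(pairs, cfg.termination())
        hierarchy = run_mca(network, cfg.mca(int(rng.integers(2**31))))
        mha = run_mha(network, hierarchy, cfg.mha(int(rng.integers(2**31))))
        return MultiscaleNetworkResults(
            model=self,
            seed=seed,
            pairs=pairs,
            network=network,
            hierarchy=hierarchy,
            mha=mha,
        )


@dataclass
class MultiscaleNetworkResults:
    """Fitted pipeline state: network, hierarchy, hubs, associations."""

    model: MultiscaleNetworkModel
    seed: int
    pairs: pd.DataFrame
    network: "object"
    hierarchy: ClusterHierarchy
    mha: MHAResult

    @property
    def hub_table(self) -> pd.DataFrame:
        return self.mha.table

    @property
    def multiscale_hubs(self) -> set:
        return self.mha.multiscale_hubs

    def modules(self, min_size: int = 3, significant_only: bool = True) -> dict:
        """Cluster id -> gene tuple for reporting-grade clusters."""
        out = {}
        for cid, c in self.hierarchy.clusters.items():
            if c.parent is None or c.size < min_size:
                continue
            if significant_only and not (
                c.p_value is not None and c.p_value <= self.model.config.sig_level
            ):
                continue
            out[cid] = c.nodes
        return out

    def associate_traits(self, traits: pd.DataFrame, min_size: int = 3) -> pd.DataFrame:
        return associate_clusters(self.model.expr, self.modules(min_size), traits=traits)

    def associate_survival(self, survival: pd.DataFrame, min_size: int = 3) -> pd.DataFrame:
        return associate_clusters(self.model.expr, self.modules(min_size), survival=survival)

    def diagnostics(self) -> dict:
        return degree_diagnostics(self.network)

    def summary(self) -> str:
        g = self.network
        n_sig = sum(
            1
            for c in self.hierarchy.clusters.values()
            if c.parent is not None
            and c.p_value is not None
            and c.p_value <= self.model.config.sig_level
        )
        lines = [
            "Multiscale planar co-expression network",
            "=" * 44,
            f"genes / samples        {self.model.expr.shape[0]} / {self.model.expr.shape[1]}",
            f"candidate pairs        {len(self.pairs)}",
            f"pairs tested           {g.graph.get('tested', 'n/a')}",
            f"edges embedded         {g.number_of_edges()} "
            f"(Euler bound {g.graph.get('max_edges', 'n/a')})",
            f"termination            {g.graph.get('termination', 'n/a')}",
            f"clusters (total/sig)   {len(self.hierarchy)} / {n_sig}",
            f"significant scales     {len(self.mha.phi)}",
            f"scale groups           {len(self.mha.scale_groups)}",
            f"multiscale hubs        {len(self.multiscale_hubs)}",
        ]
        return "\n".join(lines)

    def save(self, outdir, traits: pd.DataFrame | None = None, survival=None) -> Path:
        """Write network, hierarchy, hub table, associations and manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pfio.write_pair_list(self.pairs, out / "pairs.tsv")
        pfio.write_network(self.network, out / "network")
        pfio.write_table(
            self.hierarchy.to_frame(),
            out / "hierarchy.tsv",
            "cluster hierarchy: id, parent, kind, size, mean SPD, "
            "characteristic alpha, compactness nu, significance p, members",
        )
        pfio.write_table(
            self.hub_table,
            out / "hubs.tsv",
            "per-node hub calls: node, scale group, mean within-cluster "
            "connectivity, combined S, Bonferroni p, hub flags",
        )
        stage_log = [
            {"stage": "pfn", "termination": self.network.graph.get("termination")},
            {"stage": "mca", "clusters": len(self.hierarchy)},
            {"stage": "mha", "groups": len(self.mha.scale_groups)},
        ]
        if traits is not None or survival is not None:
            assoc = associate_clusters(
                self.model.expr, self.modules(), traits=traits, survival=survival
            )
            pfio.write_table(
                assoc,
                out / "associations.tsv",
                "cluster-trait association: cluster, trait, statistic "
                "(Pearson r or logrank chi2), p, test, BH q",
            )
            stage_log.append({"stage": "cta", "rows": len(assoc)})
        cfg = asdict(self.model.config)
        pfio.write_manifest(out / "manifest.json", cfg, self.seed, stage_log)
        return out
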