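"""Cluster-trait association.

Each cluster is summarized by its module eigengene — the first principal
component of the standardized expression submatrix — which is then
correlated with sample traits (Pearson r, Fisher-Z p) and, for survival
data, used to define two molecular subtypes by a median split whose
survival curves are compared with the logrank test.  P-values are
adjusted with Benjamini-Hochberg across clusters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .similarity import fisher_z_pvalue

__all__ = [
    "module_eigengene",
    "trait_association",
    "median_split_logrank",
    "bh_fdr",
    "cluster_signature_enrichment",
    "associate_clusters",
]


def module_eigengene(expr: pd.DataFrame, cluster_nodes) -> pd.Series:
    """First principal component of a cluster's standardized expression.

    ``expr`` is genes x samples.  Gene profiles are z-scored across
    samples, the first right singular vector gives one score per sample,
    and the sign is fixed so the eigengene correlates positively with the
    mean cluster expression profile.
    """
    genes = [g for g in cluster_nodes if g in expr.index]
    if len(genes) < 2:
        raise ValueError("module eigengene requires >= 2 cluster genes in the matrix")
    X = expr.loc[genes].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    pc1 = vt[0]
    ref = Z.mean(axis=0)
    if np.dot(pc1, ref) < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=expr.columns, name="eigengene")


def trait_association(eigengene: pd.Series, trait: pd.Series):
    """Pearson correlation of an eigengene with a trait, Fisher-Z p.

    Samples are matched on the index; pairs with missing values are
    dropped (pairwise-complete).  A constant trait has no defined
    correlation and returns (nan, nan).
    """
    joined = pd.concat([eigengene, trait], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("trait association requires >= 3 paired samples")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.std(y) == 0 or np.std(x) == 0:
        warnings.warn("constant eigengene or trait; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    p = fisher_z_pvalue(r, len(joined)) if len(joined) >= 4 else float("nan")
    return r, p


def median_split_logrank(eigengene: pd.Series, survival: pd.DataFrame):
    """Two-group logrank test on a median split of the eigengene.

    ``survival`` has columns ``time`` and ``event`` indexed by sample.
    Samples at or below the median eigengene form the "low" group (ties
    go low, deterministically).  Returns (chi-square statistic, p-value);
    with no events at all the test is vacuous and (0, 1) is returned with
    a warning.
    """
    from lifelines.statistics import logrank_test

    common = eigengene.index.intersection(survival.index)
    if len(common) < 2:
        raise ValueError("no overlapping samples between eigengene and survival")
    e = eigengene.loc[common]
    surv = survival.loc[common]
    med = float(e.median())
    low = e <= med
    if low.all():
        low = e < med  # everything at/below the median: fall back to strict split
    if low.all() or not low.any():
        warnings.warn("median split produced an empty group; p = 1", stacklevel=2)
        return 0.0, 1.0
    if surv["event"].sum() == 0:
        warnings.warn("no events observed; logrank p = 1", stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(
        surv.loc[low.values, "time"],
        surv.loc[~low.values, "time"],
        event_observed_A=surv.loc[low.values, "event"],
        event_observed_B=surv.loc[~low.values, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def bh_fdr(pvals):
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def cluster_signature_enrichment(cluster_nodes, gene_set, universe):
    """Fisher exact test of cluster / gene-set overlap.

    Builds the 2x2 table (in-cluster & in-set, in-cluster only, in-set
    only, neither) over ``universe`` and returns (odds_ratio, p) from the
    two-sided exact test.  Multiply p by the number of tests for a
    Bonferroni correction across (clusters x sets).
    """
    uni = set(universe)
    cl = set(cluster_nodes) & uni
    gs = set(gene_set) & uni
    if not gs:
        raise ValueError("empty gene set after intersecting with the universe")
    a = len(cl & gs)
    b = len(cl - gs)
    c = len(gs - cl)
    d = len(uni) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def associate_clusters(
    expr: pd.DataFrame,
    clusters: dict,
    traits: pd.DataFrame | None = None,
    survival: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Eigengene-based association table for a set of clusters.

    ``clusters`` maps cluster id -> iterable of gene ids.  For each
    cluster and numeric trait column the Pearson r and Fisher-Z p are
    reported; if survival (time, event) is given, the median-split
    logrank statistic and p are added.  BH-adjusted q-values are computed
    per trait across clusters.
    """
    rows = []
    for cid, genes in clusters.items():
        try:
            eig = module_eigengene(expr, genes)
        except ValueError:
            continue
        if traits is not None:
            for tname in traits.columns:
                tr = pd.to_numeric(traits[tname], errors="coerce")
                try:
                    r, p = trait_association(eig, tr)
                except ValueError:
                    r, p = float("nan"), float("nan")
                rows.append(
                    {"cluster_id": cid, "trait": tname, "statistic": r, "p": p, "test": "pearson"}
                )
        if survival is not None:
            chi2, p = median_split_logrank(eig, survival)
            rows.append(
                {
                    "cluster_id": cid,
                    "trait": "survival",
                    "statistic": chi2,
                    "p": p,
                    "test": "logrank",
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = np.nan
        for tname in table["trait"].unique():
            mask = table["trait"] == tname
            table.loc[mask, "q"] = bh_fdr(table.loc[mask, "p"].to_numpy())
    return table
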