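"""Pairwise co-expression similarity, significance and pair ranking.

The planar filter consumes a rank-ordered list of candidate gene pairs.
This module computes the similarity matrix (Pearson correlation, mutual
information, or a Euclidean-distance similarity), attaches nominal
p-values and false-discovery rates, and emits the ranked pair list.

Significance routes differ by measure: Pearson correlations get exact
Fisher-Z p-values followed by Benjamini–Hochberg adjustment; mutual
information and Euclidean similarity, which have no comparable closed-form
null, use a global permutation FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "compute_similarity",
    "fisher_z_pvalue",
    "permutation_fdr",
    "filter_and_rank",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with identifiers.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``.  Gene identifiers must be unique and at least three
    samples are required for correlations to be defined.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-d matrix")
        n, m = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(n)]
        if not self.sample_ids:
            self.sample_ids = [f"s{j}" for j in range(m)]
        if len(self.gene_ids) != n or len(self.sample_ids) != m:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.gene_ids)) != n:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes}")
        if m < 3:
            raise ValueError("at least 3 samples are required")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(map(str, df.index)), list(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _as_expression(expr) -> ExpressionMatrix:
    if isinstance(expr, ExpressionMatrix):
        return expr
    if isinstance(expr, pd.DataFrame):
        return ExpressionMatrix.from_dataframe(expr)
    return ExpressionMatrix(np.asarray(expr, dtype=float))


def _discretize_equal_frequency(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-row equal-frequency binning into integer codes 0..n_bins-1."""
    n, m = values.shape
    codes = np.empty((n, m), dtype=np.int64)
    # rank-based: ties get the same code deterministically
    for i in range(n):
        ranks = stats.rankdata(values[i], method="average")
        codes[i] = np.minimum((ranks - 0.5) * n_bins / m, n_bins - 1).astype(np.int64)
    return codes


def _mutual_information_matrix(values: np.ndarray) -> np.ndarray:
    """Plug-in MI between all gene pairs after equal-frequency binning.

    Binning uses ceil(sqrt(M)) bins per gene; entropies are plug-in
    (maximum-likelihood) estimates in nats.
    """
    n, m = values.shape
    b = int(np.ceil(np.sqrt(m)))
    codes = _discretize_equal_frequency(values, b)
    # marginal entropies
    h = np.empty(n)
    for i in range(n):
        p = np.bincount(codes[i], minlength=b) / m
        p = p[p > 0]
        h[i] = -np.sum(p * np.log(p))
    mi = np.zeros((n, n))
    for i in range(n):
        ci = codes[i] * b
        for j in range(i + 1, n):
            joint = np.bincount(ci + codes[j], minlength=b * b) / m
            joint = joint[joint > 0]
            hij = -np.sum(joint * np.log(joint))
            val = h[i] + h[j] - hij
            mi[i, j] = mi[j, i] = max(val, 0.0)
    return mi


def compute_similarity(expr, method: str = "pcc") -> np.ndarray:
    """Symmetric similarity matrix between gene expression profiles.

    method
        ``"pcc"``  - Pearson correlation, in [-1, 1].
        ``"mi"``   - plug-in mutual information (nats), >= 0.
        ``"euclidean"`` - 1 / (1 + d) with d the Euclidean distance, so
        similarity is in (0, 1] and strictly decreasing in distance (only
        the ranking matters downstream).

    Genes with zero variance have undefined correlation; under ``pcc``
    their pairs are returned as NaN and a warning is emitted, and they are
    dropped later by :func:`filter_and_rank`.
    """
    ex = _as_expression(expr)
    v = ex.values
    method = method.lower()
    if method == "pcc":
        sd = v.std(axis=1)
        flat = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.corrcoef(v)
        s = (s + s.T) / 2.0  # enforce exact (bitwise) symmetry
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} zero-variance gene(s); their pairs are excluded",
                stacklevel=2,
            )
            s[flat, :] = np.nan
            s[:, flat] = np.nan
        else:
            s = np.clip(s, -1.0, 1.0)
        np.fill_diagonal(s, np.nan)
        # numerical symmetrization guard (corrcoef is symmetric already)
        return s
    if method == "mi":
        return _mutual_information_matrix(v)
    if method in ("euclidean", "euclid"):
        d = squareform(pdist(v, metric="euclidean"))
        s = 1.0 / (1.0 + d)
        np.fill_diagonal(s, np.nan)
        return s
    raise ValueError(f"unknown similarity method: {method!r}")


def fisher_z_pvalue(r, n_samples: int):
    """Two-sided p-value for H0: rho = 0 via the Fisher Z-transform.

    z = atanh(r) * sqrt(n - 3) is compared against the standard normal.
    Accepts scalars or arrays.  ``|r| = 1`` maps to the smallest positive
    float (with a warning) rather than an exact zero.
    """
    if n_samples < 4:
        raise ValueError("Fisher-Z p-value requires n_samples >= 4")
    r_arr = np.asarray(r, dtype=float)
    scalar = r_arr.ndim == 0
    r_arr = np.atleast_1d(r_arr)
    out = np.ones_like(r_arr)
    saturated = np.abs(r_arr) >= 1.0
    if np.any(saturated & np.isfinite(r_arr)):
        warnings.warn("|r| = 1 encountered; p clipped to machine minimum", stacklevel=2)
    ok = np.isfinite(r_arr) & ~saturated
    z = np.arctanh(r_arr[ok]) * np.sqrt(n_samples - 3)
    out[ok] = 2.0 * stats.norm.sf(np.abs(z))
    out[saturated] = np.finfo(float).tiny
    out[~np.isfinite(r_arr)] = np.nan
    out = np.clip(out, np.finfo(float).tiny, 1.0)
    out[~np.isfinite(r_arr)] = np.nan
    return float(out[0]) if scalar else out.reshape(np.shape(r))


def permutation_fdr(expr, method: str = "pcc", n_perm: int = 20, seed: int = 0) -> np.ndarray:
    """Global permutation FDR for every gene pair.

    Each permutation independently shuffles every gene's profile across
    samples, destroying co-expression while preserving marginals.  For an
    observed similarity s, FDR(s) = (mean permuted count of similarities
    >= s) / (observed count >= s), clipped to [0, 1].  Similarities are
    compared by absolute value so that strong negative correlations are
    also deemed significant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 10:
        warnings.warn(
            f"n_perm={n_perm} gives coarse FDR resolution; consider >= 10", stacklevel=2
        )
    ex = _as_expression(expr)
    rng = np.random.default_rng(seed)
    obs = compute_similarity(ex, method)
    iu = np.triu_indices(ex.n_genes, 1)
    obs_v = np.abs(obs[iu])
    valid = np.isfinite(obs_v)
    obs_sorted = np.sort(obs_v[valid])
    n_obs = obs_sorted.size
    null_counts = np.zeros(n_obs)
    for _ in range(n_perm):
        perm = ex.values.copy()
        for i in range(perm.shape[0]):
            rng.shuffle(perm[i])
        ps = compute_similarity(ExpressionMatrix(perm), method)
        pv = np.abs(ps[iu])
        pv = np.sort(pv[np.isfinite(pv)])
        # for each observed value: count of permuted >= value
        null_counts += pv.size - np.searchsorted(pv, obs_sorted, side="left")
    mean_null = null_counts / n_perm
    obs_count = n_obs - np.searchsorted(obs_sorted, obs_sorted, side="left")
    fdr_sorted = np.clip(mean_null / obs_count, 0.0, 1.0)
    # map back to pair positions
    fdr_flat = np.full(obs_v.shape, np.nan)
    pos = np.searchsorted(obs_sorted, obs_v[valid], side="left")
    fdr_flat[valid] = fdr_sorted[pos]
    out = np.full(obs.shape, np.nan)
    out[iu] = fdr_flat
    out[(iu[1], iu[0])] = fdr_flat
    return out


def filter_and_rank(
    sim_matrix: np.ndarray,
    gene_ids,
    pvals=None,
    fdrs=None,
    fdr_threshold: float = 0.05,
    rank_by: str = "abs",
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Filter pairs by FDR and emit the ranked candidate-pair list.

    Exactly one significance route must be available: either ``fdrs`` (a
    symmetric per-pair FDR matrix, e.g. from :func:`permutation_fdr`) or
    ``pvals`` (symmetric nominal p-values, adjusted here with
    Benjamini–Hochberg).  If ``pvals`` is None and ``n_samples`` is given,
    Fisher-Z p-values are derived from the similarity matrix itself
    (correlation input assumed).

    Returns a DataFrame with columns ``node1, node2, similarity, p, fdr``,
    sorted by descending ranking key (``|similarity|`` when ``rank_by`` is
    "abs", signed similarity for "signed"), ties broken by the
    lexicographic (min_id, max_id) pair so the order is bit-reproducible.
    """
    s = np.asarray(sim_matrix, dtype=float)
    n = s.shape[0]
    gene_ids = [str(g) for g in gene_ids]
    if s.shape != (n, n) or len(gene_ids) != n:
        raise ValueError("similarity matrix and gene_ids shapes disagree")
    iu = np.triu_indices(n, 1)
    sim = s[iu]
    if fdrs is not None:
        fdr_v = np.asarray(fdrs, dtype=float)[iu]
        p_v = np.full_like(fdr_v, np.nan) if pvals is None else np.asarray(pvals, float)[iu]
    else:
        if pvals is None:
            if n_samples is None:
                raise ValueError("provide pvals, fdrs, or n_samples for Fisher-Z")
            p_v = np.asarray(fisher_z_pvalue(sim, n_samples), dtype=float)
        else:
            p_v = np.asarray(pvals, dtype=float)[iu]
        fdr_v = np.full_like(p_v, np.nan)
        ok = np.isfinite(p_v)
        if ok.any():
            fdr_v[ok] = multipletests(p_v[ok], method="fdr_bh")[1]
    keep = np.isfinite(sim) & np.isfinite(fdr_v) & (fdr_v < fdr_threshold)
    if not keep.any():
        raise ValueError(
            f"no gene pair passed FDR < {fdr_threshold}; relax the threshold "
            "or check the input data"
        )
    i_idx = iu[0][keep]
    j_idx = iu[1][keep]
    ids = np.asarray(gene_ids, dtype=object)
    a = ids[i_idx]
    b = ids[j_idx]
    lo = np.where(a <= b, a, b)
    hi = np.where(a <= b, b, a)
    key = np.abs(sim[keep]) if rank_by == "abs" else sim[keep]
    order = np.lexsort((hi, lo, -key))
    return pd.DataFrame(
        {
            "node1": lo[order],
            "node2": hi[order],
            "similarity": sim[keep][order],
            "p": p_v[keep][order],
            "fdr": fdr_v[keep][order],
        }
    ).reset_index(drop=True)
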