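# pfnet — planar filtered co-expression networks with multiscale analysis

`pfnet` builds co-expression networks from gene expression matrices under a
planarity constraint and decomposes them into a multiscale module hierarchy
with per-scale hub calls and cluster–trait associations.

## The method

Given an expression matrix (genes × samples), gene pairs are scored by a
co-expression similarity (Pearson correlation with Fisher-Z significance and
Benjamini–Hochberg FDR; mutual information or Euclidean similarity with a
global permutation FDR), filtered at FDR < 0.05, and rank-ordered.  Pairs are
then embedded greedily into a growing graph, keeping each edge only if the
graph remains planar — the planar maximally filtered graph (PMFG)
construction.  A planar graph on |V| nodes carries at most

    |E|_max = 3(|V| − 2)

edges (Euler relation), so the result — a planar filtered network (PFN) — is
a sparse, hierarchy-friendly backbone that provably contains the maximum
spanning tree of the similarity ranking.  Construction is accelerated by a
parallelizable screening step (candidates are pre-tested against a frozen
snapshot; safe because subgraphs of planar graphs are planar, so rejections
are permanent) and by early termination at a saturation fraction of the
Euler bound or a rejection budget.

The PFN is decomposed divisively.  Each cluster is split by k-medoids (PAM)
on shortest-path distances, boundaries are repaired by reassigning boundary
nodes to the cluster maximizing their local path index affinity
(LPI = A² + εA³, ε = 0.01), and the number of clusters is chosen by Newman
modularity Q.  A split survives at resolution α when some child improves the
compactness

    ν_l(α) = mean-SPD(V_l) / log(|V_l|)^α ,

and each surviving child is kept only if ν_l is significantly smaller than
in random planar triangulations (grown by T2 node-insertion moves, carrying
the parent's shuffled edge weights).  Scales with similar within-cluster
connectivity profiles c^w(v, α) are grouped; per-scale connectivity p-values
are combined per scale group as S_i = Σ_α −log10 p_i(α) and assessed against
a shuffled null with Bonferroni correction, yielding per-scale hubs and
multiscale hubs.  Clusters are summarized by their first principal component
(module eigengene) for trait correlation and median-split logrank survival
analysis.

The planarity test itself is a numba-compiled left-right (de
Fraysseix–Rosenstiehl) criterion — a linear-time exact test, roughly two
orders of magnitude faster here than a pure-Python test, which makes
whole-construction runs with tens of thousands of planarity tests cheap.

## Worked example

```python
from pfnet import MultiscaleNetworkModel
from pfnet.synthetic import PlantedDesign, generate_expression

data = generate_expression(PlantedDesign(
    n_genes=100, n_samples=200, module_sizes=(25, 25, 25, 25),
    loading=0.8, seed=3))
res = MultiscaleNetworkModel(data.expr, seed=3).fit()
print(res.summary())
```

prints

```
Multiscale planar co-expression network
============================================
genes / samples        100 / 200
candidate pairs        1209
pairs tested           1207
edges embedded         280 (Euler bound 294)
termination            saturation
clusters (total/sig)   5 / 4
significant scales     42
scale groups           1
multiscale hubs        27
```

1209 gene pairs passed FDR < 0.05; embedding stopped at the default 95%
saturation of the Euler bound (280 of 294 possible edges).  The hierarchy
contains 4 significantly compact clusters — exactly the four planted
25-gene modules (`res.modules()`).  Trait and
survival associations are available as `res.associate_traits(traits)` and
`res.associate_survival(survival)`.

The same pipeline is scriptable from the shell:

```bash
pfnet fixtures demo/ --n-genes 100 --modules 25,25,25,25 --seed 3
pfnet pipeline demo/expression.tsv out/ --seed 3 \
      --traits demo/traits.tsv --survival demo/survival.tsv
```

which writes the ranked pair list, the network (TSV edge list + GML), the
cluster hierarchy, the hub table, the association table, and a manifest
sufficient to reproduce the run byte-for-byte.

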