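# Methods

This note records the model, the numerical and design choices, and the
limits of what the test suite demonstrates.

## Similarity and significance

Pearson correlation is the default similarity.  Its nominal p-value is the
exact Fisher-Z transform, z = atanh(r)·√(n−3) against a standard normal,
and per-pair FDR is Benjamini–Hochberg across all candidate pairs.  Mutual
information (plug-in estimator on ⌈√M⌉ equal-frequency bins; the estimator
is not specified by convention, and the plug-in choice keeps a closed-form
oracle available) and Euclidean similarity (s = 1/(1+d), chosen bounded;
only the ranking matters downstream) have no comparable closed-form null
and use a global permutation FDR: each permutation shuffles every gene
independently across samples, and FDR(s) = mean permuted count ≥ s over
observed count ≥ s.

Pairs are ranked by |r| with the sign retained as an edge attribute
(`rank_by="signed"` switches to signed ranking); ties break on the
lexicographic (min id, max id) pair, making the ranking bit-reproducible.
Zero-variance genes have undefined correlation; their pairs are excluded.

## Planar embedding

Candidates are embedded in rank order, each kept only if the graph stays
planar.  The planarity test is the left-right criterion compiled with
numba; it is exact and linear-time, so the choice of algorithm affects
only speed, never the embedded edge set.  Because any subgraph of a planar
graph is planar, a rejected edge stays rejected — this justifies both
permanent rejection and batch screening: when the sliding-window (1000
tests) acceptance rate drops below 10%, blocks of upcoming candidates
(1000 per worker by default) are pre-tested independently against a frozen
snapshot, and survivors are re-tested serially in rank order.  The final
edge set is therefore identical to pure serial construction for every
batch size and worker count (asserted exactly in the tests), including
under early termination, because the batch is replayed in rank order when
counting rejections.

Termination fires on the first of: candidate list exhausted / maximal
embedding; saturation |E| ≥ 0.95·3(|V|−2) (the 0.90–0.95 range is the
recommended operating band; 1.0 disables it); or a cumulative rejection
budget of 20·|V|.  The budget is read as a cumulative count — the two
available phrasings (per-embedded-link vs total) conflict, and the
cumulative reading matches the stated constant.  Screening rejections
count toward the budget.  Two acceptance-rate notions coexist: the
sliding-window accepted/tested ratio drives the screening trigger, and
|E|/|E|_max is the saturation measure reported in summaries.

## Multiscale clustering

Edge lengths for shortest paths are d = 1 − |w| (configurable to 1/|w| or
unit lengths); lengths are floored at 1e-12 so that perfect similarities
do not vanish from the sparse graph.  Dijkstra is the default route;
Bellman-Ford is available behind a flag and produces identical distances
on these nonnegative lengths.

Each cluster is split by PAM k-medoids on its own induced-subgraph
distance matrix: deterministic greedy BUILD initialization, then
steepest-descent swaps; all ties break toward smaller indices so results
are seed-independent.  The boundary sweep reassigns nodes adjacent to a
foreign cluster to the cluster maximizing Σ LPI_ij over members, visiting
nodes in index order with immediate updates until a full sweep changes
nothing; moves require strict improvement, so the output is idempotent.
A capped iteration count guards against oscillation.  k is scanned from 2
upward and exploration stops once k exceeds the best-Q k by dk = 10;
a partition is meaningful only if Q > 0.

Compactness is ν_l(α) = mean within-cluster SPD / ln(|V_l|)^α (natural
log, consistent with network diameters scaling like ln |V|).  A child's
mean SPD is measured on its parent's distance matrix, so disconnected
children remain finite; when a cluster's own induced subgraph is
disconnected it is first divided into connected components, recorded as
pass-through children.  The characteristic α of a child is the largest
grid α ≤ the parent's characteristic α at which ν_child(α) < ν_parent(α),
both evaluated at the same α; with both sides sharing the factor
spd/log^α, this is equivalent to comparing spd ratios against
(ln n_l / ln n_o)^α, which tightens as α grows — coarse structure
therefore survives to large α, fine structure only to small α.  The grid
is geometric, 50 points over 0.02–10, and the roots' bound is the grid
maximum.  Size-2 clusters are retained as leaves but never α-scored (the
log normalization is degenerate below e).

Significance of a child at its characteristic α: one random planar
triangulation of the parent's size is grown by T2 moves (uniform face
choice; degree-biased choice available), its edges carry the parent's
shuffled weights (resampled with replacement when the parent has fewer
edges than the triangulation's 3(n−2)), and 100 connected subsets of the
child's size are drawn by snowball growth from uniform seed nodes; the
add-one estimator p = (1 + #{ν′ ≤ ν_l})/(1 + 100) avoids exact zeros.
Recursion descends only into significant (p ≤ 0.05) children of at least
4 nodes.

The ambiguity of "max vs min" over admissible α is resolved toward max
(the printed form); the admissible set itself is logged per cluster via
the characteristic-α computation, so the alternative convention is a
one-line change of reduction.

## Hub analysis

Φ is the set of grid scales at which at least one significant split is in
effect; the partition at scale α is obtained by descending the hierarchy
while some child's characteristic α covers α and is significant.
Within-cluster connectivity uses |weight| so that strong negative
correlations count as connectivity.  Scales are grouped by PAM on the
Euclidean distances between connectivity columns; k ∈ [2, |Φ|−1] is
chosen by a committee of four internal validity indices — average
silhouette width, permutation-normalized Hubert gamma (100 permutations),
Dunn's index, and a separation index (mean over clusters of the minimal
outward distance, scaled by the mean within-cluster distance so merging
well-separated groups is penalized; the literature names but does not fix
these last two, and the definitions here are the documented choice) —
combined as score(k) = Σ_m log(rank_m(k)/(|Φ|−1)), argmin with
smallest-k ties.

Per-scale hub p-values compare a node's within-cluster connectivity with
weighted degrees in 100 T2 triangulations of the cluster's size carrying
the cluster's shuffled weights: p = (1 + mean #{null ≥ c})/(1 + |V_l|).
The combined statistic per scale group is S_i = Σ_α −log10 p_i(α),
implemented literally in base-10 form rather than as the classical
−2·ln χ² combination.  Its null shuffles the (node × scale) p-matrix
entries 100 times; nominal exceedance p-values (add-one) are Bonferroni
corrected by the number of network nodes, hubs are corrected p < 0.05,
and multiscale hubs are the intersection across scale groups.

## Cluster–trait association

The module eigengene is the first right singular vector of the z-scored
cluster submatrix, signed to correlate positively with mean cluster
expression.  Trait association is Pearson r with the Fisher-Z p; survival
association is the two-group logrank test on a median split of the
eigengene (ties at the median go to the low group, deterministically),
with Benjamini–Hochberg adjustment across clusters per trait.
Multivariate Cox regression is deliberately out of scope — it is a
standard model with no method-specific content; the eigengene it would
consume is exactly the one produced here, so it plugs in directly via
lifelines if needed.  A generic Fisher-exact enrichment utility is
provided; curated gene-set databases are not shipped.

## Synthetic data

The generator draws from a latent-factor model: gene g in sub-module m of
super-module s is λ·F_s + μ·G_m + σ_g·ε with independent standard-normal
factors and noise, σ_g defaulting to the unit-variance choice, so the
expected within-sub-module correlation is exactly λ² + μ² and the
cross-sub-module (within-super) correlation λ² — closed forms the tests
verify directly.  Hub genes take an inflated loading.  Survival is
exponential with hazard HR^z in the latent factor z and independent
exponential censoring calibrated to the requested censoring fraction.
Gold-standard edges are all within-module pairs, and network recovery is
scored by the AUC of negative weighted shortest-path distances against
that gold standard.

Default study conditions: four 25-gene modules, loading 0.8, 200 samples
(flat designs); two super-modules of three 12-gene sub-modules, super
loading 0.6, sub loading 0.5, 300 samples (two-level designs).  In the
two-level design the super-modules share no factor, so after FDR
filtering they appear as separate network components (the hierarchy's
root level) and each splits into its sub-modules.  This is deliberate:
when super-modules are instead tied together by a shared weak factor, the
modularity-guided first split jumps directly to the finest level — on a
planarity-capped graph the within-sub-module edge share is always large
enough that the fine split's Q dominates any 2-way split — and the
intermediate level never materializes as a separate tier.  Multiscale
structure in this framework is therefore expressed through component
structure plus α-gating of nested splits, not through successive
coarse-to-fine Q optima.

What the synthetic model does not emulate: heavy-tailed expression,
sample covariates and batch structure, dependence between censoring and
risk, and regulatory-network dynamics.  Passing recovery tests shows the
pipeline detects block-correlation structure planted under its own
assumptions at realistic sizes; it does not certify performance on real
cohorts.

## Problem sizes and numerical details

The test and validation suites run at desk scale by design: networks of
50–200 genes (the screened-vs-serial equivalence suite uses twenty
200-node complete inputs, ~19k planarity tests each), triangulation nulls
of 100 draws, 500-replicate logrank calibration.  The compiled planarity
kernel makes a full 200-node PMFG build take under a second, so these
sizes exercise every code path, including the screening phase, without
shortcuts.  Monte-Carlo p-values use add-one estimators everywhere; all
randomness flows from explicit seeds through numpy Generators, and every
pipeline stage is bit-reproducible given the manifest.

Known limitations: cluster significance at very small parent sizes
(≲ 40 nodes) is conservative — snowball subsets of a small triangulation
are themselves compact, so borderline modules can fail the null
comparison; the boundary sweep can merge planted blocks in very dense
toy graphs where binary-adjacency LPI carries little locality signal;
and embedding on surfaces of higher genus is out of scope.
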