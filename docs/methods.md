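# Methods

## Propagation model

The package implements random walk with restart (RWR) on an undirected,
simple, connected interaction graph. With restart probability `α ∈ (0, 1]`
and a column-stochastic transition matrix `W`, the walk

    p_k = α p_0 + (1 − α) W p_{k−1}

converges to `p = α (I − (1 − α) W)^{−1} p_0` whenever the graph is
connected and `W` is stochastic. Both routes are implemented and
cross-checked: a sparse direct solve of the linear system (the default;
no explicit inverse is formed) and power iteration with a convergence
tolerance of 1e-8 on the maximum absolute change and a cap of 10,000
iterations. The tolerance/cap are chosen so the two solvers agree well
below any reporting precision; the test suite asserts element-wise
agreement within 1e-6. Because `W` is column-stochastic, total weight is
conserved (`Σp = Σp_0`), which the suite checks to 1e-8.

Matrix convention: columns are "from" nodes, so `W[:, j]` is the
distribution over the neighbors a walker at `j` moves to, and vectors are
propagated as `W p`. The node ordering is fixed once (sorted node
identifiers) and shared by the matrix, all weight vectors and all output
tables, making runs bit-reproducible.

### Normalization schemes

Given degrees `d` and cores `k` (k-shell indices), column `j` assigns its
neighbor `i` a raw weight of `1` (degree), `k_i` (core),
`1/((d_i − k_i) + 1)` (diff) or `k_i/d_i` (ratio), and each column is
divided by its own sum. For `degree` and `core` this reproduces the
closed forms `1/d_j` and `k_i / Σ_{l∈N(j)} k_l` exactly; for `diff` and
`ratio` the explicit rescale is what makes the matrix stochastic. On a
connected simple graph every core is ≥ 1, so no column sum can vanish;
a zero sum is still guarded by a defensive error. The core-based schemes
exist to counter degree bias: a bait/prey hub has high degree but low
core, so `core` starves it of transition mass and `diff`/`ratio`
penalize it explicitly.

Coreness is computed by standard k-shell decomposition (networkx
`core_number`); an independent brute-force oracle (largest `k` such that
the node survives iterated deletion of degree < k nodes) verifies it in
the tests. Degrees always refer to the original graph.

## Permutation significance

Null weights come from random degree-preserving networks (RDPN) produced
by double-edge swaps — replace `(u,v),(x,y)` by `(u,x),(v,y)` — with a
per-swap connectivity check and rollback. The attempt budget is
`swap_factor × |E|` attempts (attempts, not accepted swaps, so runtime is
bounded); swaps creating self-loops or existing edges are rejected
outright. The connectivity check exploits a local property: after a swap
every node remains attached to one of the four endpoints, and the new
edges join `u–x` and `v–y`, so the graph stays connected iff `u` still
reaches `v`; this is tested with a bidirectional BFS rather than a full
connectivity scan. Graphs too small or too rigid to swap (acceptance
rate < 1%, e.g. near-trees) are returned best-effort with a warning; a
triangle is returned unchanged since no valid swap exists.

Each ensemble member's RNG stream derives from
`SeedSequence(master_seed, spawn_key=(index,))` (kept below 2^31), so the
ensemble is identical at any worker count. Cores are recomputed for every
random network — swaps preserve degrees, not cores. Ensembles are cached
on disk keyed by (network hash, master seed, swap factor), since they
depend only on the network, not on the input weights.

The empirical p-value uses add-one smoothing,
`p_v = (#{w_i(v) ≥ w(v)} + 1)/(n + 1)`, with ties counting against the
observed value; the floor is `1/(n+1)`, i.e. 0.0099 at the default
`n = 100`, which motivates the default significance threshold of
p < 0.01: only nodes beating every randomization pass.

## Module identification

Defaults: p-threshold 0.01 (strict), weight percentile 75 with linear
interpolation between order statistics (configurable; chosen for
reproducibility since the percentile convention is otherwise ambiguous),
`w > w_min` strict. Candidates must neighbor at least one seed; admitted
candidates contribute only their edges to seeds — edges between two
candidates are behind an off-by-default flag, because either reading of
the extension rule is defensible and the conservative one keeps modules
anchored at prior knowledge. Seeds are never filtered by significance:
they are prior knowledge, not predictions. When no seed list is given,
the 100 highest input weights serve as seeds (boundary ties broken
lexicographically). If no significant non-seed node exists, `w_min` is
+∞ and the extension is empty by construction, with a warning.

Connectedness uses natural logarithms (ratios of connectedness values
are base-invariant): `E = −Σ p_Mi ln p_Mi` over per-module seed counts,
uncovered seeds counting as singletons, `E_max = ln n`. Extension can
only merge seed components, so connectedness is monotone non-decreasing
under extension — asserted as an invariant.

## Evaluation

Cross-validation splits the gene set into k = 5 folds (validation :
training ≈ 1 : 4), binary-seeds the training genes, propagates, assigns
permutation p-values, and scores the ROC with validation genes as
positives against an equal number of degree-matched negatives (the 1:1
ratio is a configurable choice; nothing forces it). Negatives are drawn
without replacement from outside the gene set by nearest-degree matching
with a ±10% tolerance that widens ×1.5 until a candidate is found. ROC
curves sweep the achievable p-value thresholds, are vertically averaged
at 100 evenly spaced FPR points, and fold AUROCs are trapezoid areas of
the grid-interpolated curves, so the consensus AUROC (their mean) always
lies between the fold extremes. A paired Wilcoxon signed-rank utility
compares schemes across gene sets.

Over-representation analysis is the exact hypergeometric tail
`P(X ≥ overlap)` for each pathway against a caller-supplied background
universe, Benjamini–Hochberg corrected across the whole collection, then
filtered (overlap ≥ 2, p < 0.01, module size ≥ 10 by default). BH is used
because the q-value procedure of typical web services is unspecified.

## Synthetic benchmark generator

The generator emulates what matters for this method and nothing more: a
preferential-attachment backbone (heavy-tailed degrees, n = 1000 nodes,
m = 2 edges per arrival), optional star motifs (a hub wired to fresh
degree-1 leaves — high degree, low core, the signature of bait/prey
bias), and a planted dense community (80 nodes at internal density 0.15,
i.e. mean internal degree ≈ 12 against a backbone mean of ≈ 4) whose
members carry elevated weights. Background weights are −log10 of a
uniform p-value (Exponential, scale 1/ln 10 ≈ 0.43); planted members add
1 + Exponential(scale 2). Seeds are a random 30% of the community. All
draws flow from one seed; identical seeds give byte-identical fixtures.

What the generator does **not** emulate: edge confidence structure,
overlapping pathways, correlated measurement noise between neighboring
genes, and the size (10⁴ nodes, 10⁵ edges) of a real high-confidence PPI
network. Passing tests therefore demonstrate correctness and the
direction of the core-vs-degree effect at benchmark scale, not effect
magnitudes on real interactomes.

## Problem sizes and numerical choices

The test suite and acceptance script run at benchmark scale: fixtures of
120–1000 nodes, RDPN ensembles of 33–100 networks, and swap factors of
2–5 (the package default is 100, sized for real interactomes; degree
preservation and connectivity hold for any attempt count, and a less
mixed null only makes the permutation test more conservative).
Cross-validated comparisons use 33 random networks and 10 repetitions;
the planted-module recovery experiment uses the full default pipeline
(100 networks, p < 0.01, 75th percentile) on 5 independent fixtures.

Degenerate inputs are handled explicitly: empty networks after
confidence filtering raise; disconnected graphs must pass through
largest-connected-component reduction (ties broken by lexicographically
smallest member); genes absent from the network are dropped from weight
and seed inputs with logged counts; `α = 1` returns the input weights
exactly.

## Known limitations

- Edge confidences are used only for threshold filtering; propagation is
  unweighted.
- The RDPN null preserves degrees but not cores; core-based schemes are
  therefore tested against a slightly broader null than degree-based
  ones, which is inherent to the design.
- Per-swap connectivity checking makes randomization the runtime
  bottleneck on large networks; ensembles are cached and can be built in
  parallel (`--workers`).
- Module extension admits only direct neighbors of seeds; genes two
  steps from every seed cannot be recovered regardless of significance.
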