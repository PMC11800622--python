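# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, so results can be interpreted and the
defaults questioned.

## Graph model and state space

A multiplex-heterogeneous graph is a list of components (node types);
each component is a list of undirected, non-negatively weighted layers
over one node type. Layers may have different, even disjoint, node sets.
The walk's state space is the set of *replicas* — one state per (layer,
node) occurrence — so a node present in two layers is two states. Node
identity across layers and components is exact string match of the node
id; identifier mapping is considered preprocessing and out of scope.
Replicas of a shared node id in two layers of a multiplex are coupled by
an inter-layer edge (default weight 1, configurable per component);
bipartite node pairs connect *all* replicas of the two nodes. Duplicate
edges in an input file are collapsed by summing; self-loops are rejected
unless explicitly enabled.

## Transition matrix

Construction is normalize-then-mix. For each source replica, three
target classes exist: intra-layer neighbors, inter-layer replicas, and
inter-component bipartite partners. Each class block is column-normalized
independently (inter-component blocks per partner component), after two
optional row reweightings of the adjacency:

- penalized degree normalization, `A → D^{−k_pen} A` with `D` the degree
  matrix, penalizing transitions *into* hubs (`k_pen = 0` is plain degree
  normalization; applied per layer, overridable per layer);
- biased-walk reweighting, `A → diag(μ) A`, so that after normalization
  `m_ij = μ_i a_ij / Σ_l μ_l a_lj`. A column whose entire biased
  neighborhood is zero falls back to its unbiased transition rates with a
  warning — negative evidence must not create absorbing sinks.

Crosstalk then assigns class masses `(1−δ)(1−λ)` / `(1−δ)λ` / `δ`
(layer-switch probability λ, component-jump probability δ, both in
[0, 1]). The exact mixing algebra of the original formulation is not
public; the multiplicative split used here was chosen because it
partitions every column for any (λ, δ) and keeps each class's mass
affine in its own parameter — the linearity the re-parameterization is
for, verified to 1e-12 on an 11-point grid. When a source lacks a target
class, that class's nominal mass is redistributed proportionally to the
present classes (a lone class receives mass 1); δ is split equally among
partner components that are actually reachable from the column. Replicas
with no targets at all become all-zero *dangling* columns; the diffusion
engine reroutes their incoming mass to the restart term each step, which
keeps the iterate exactly stochastic without densifying the matrix.

## Seed vector and diffusion

Per-layer raw values (non-negative; nodes missing from an assay get 0)
are normalized to sum 1, scaled by layer weights τ (simplex over a
component's layers) then component weights η (simplex over components).
A layer with an all-zero value map contributes nothing and its τ mass is
redistributed proportionally within the component (likewise η across
components); this avoids inventing uniform priors over unmeasured nodes.

RWR iterates `p ← (1−r) M p + r p₀` with L1 convergence tolerance 1e-10
and at most 1000 iterations (non-convergence raises, carrying the
residual trace). The default restart `r = 0.5` follows the standalone
evaluation protocol. The iterative solution agrees with the dense linear
solve `r (I − (1−r)M)^{−1} p₀` to better than 1e-8 on graphs up to
N = 200 (tested over 50 random draws).

Stationary distributions use lazy power iteration (`s ← (Ms + s)/2`,
aperiodic, so bipartite structures converge) with an eigensolver
fallback when the spectral gap is tiny — near-bistochastic matrices need
it — and damped iteration (0.999) as a last resort for reducible chains.
For the unbiased degree-normalized walk the closed form
`s_j = Σ_i a_ij / Σ_ik a_ik` is available and is used as a cross-check.

Distance-decay bias from nodes of interest: `μ_i = exp(−k_scale · d_i)`,
`d_i` the mean unweighted shortest-path distance from replica i to the
nodes of interest, measured on the full heterogeneous replica graph (all
edge classes unit length). Unreachable pairs contribute the largest
observed finite distance plus one.

## Degree-bias adjustment

All three methods treat the stationary distribution as the proxy for
degree influence.

**SDS** divides diffusion scores by stationary probabilities; it is a
post-hoc rank transform (no renormalization; zero-probability nodes are
flagged NaN). **Bistochastic scaling** runs iterative proportional
fitting toward unit row and column sums (tol 1e-6, max 1000 sweeps).
Matrices whose support contains a hub with two degree-1 neighbors cannot
be exactly bistochastic, and pushing IPF on such matrices concentrates
mass on a matching-like pattern that *collapses* stationary entropy —
the opposite of the goal. IPF therefore also stops when the per-sweep
relative improvement of the worst deviation falls below 5e-3, which
empirically lands near the entropy peak; the achieved deviation is
reported in a warning when it exceeds the tolerance.
**Inflation-normalization** raises row i entrywise to
`α_i = 1 + γ (s_i − min s)/(max s − min s)` (γ default 1, one round) and
renormalizes columns: α ≥ 1 everywhere, regular graphs are fixed points,
and incoming mass is displaced away from high-s rows. The affine min–max
exponent is this package's choice; the form is isolated so alternatives
can be swapped.

Scoped adjustment rewrites only the named intra-layer blocks of the
pre-crosstalk normalized block matrix and re-runs the mixing, so global
column stochasticity holds by construction. On 20 scale-free graphs with
random seeds the mean score–degree Pearson correlation orders
control ≥ IN ≥ BS with SDS smallest (negative), and BS/IN strictly
increase stationary entropy — the intended trade-off profile.

## Module search

Each iteration: assemble the transition matrix on the current subnetwork
(bias and degree-bias adjustment recomputed there, since degree structure
changes as the graph shrinks); diffuse; optionally SDS-transform the
scores; collapse each multiplex component onto the union node set with
the primary layer's edges taking precedence (secondary layers fill in
missing pairs, in layer order; per-node score = mean over replicas,
configurable; bipartite edges preserved); shift scores; extract a
connected subgraph; score it; induce the next subnetwork from it.

**Score shifting.** Diffusion scores span orders of magnitude, so
standardization is applied to log-scores; the threshold is the k-th
largest standardized score with `k = ceil(retention_fraction · n)`, so
exactly k nodes carry non-negative weight and the sign pattern is
invariant under positive scaling of the scores. Magnitudes — which the
subgraph extraction trades off — stay commensurate instead of being
dominated by hub outliers.

**Maximum-weight connected subgraph.** NP-hard; the heuristic contracts
connected clusters of non-negative nodes into supernodes, links them by
cheapest paths (path cost = summed |w| of negative nodes crossed), keeps
the maximum-weight subtree of a minimum spanning forest by tree dynamic
programming, and then refines: attach adjacent non-negative nodes, expand
through negative hubs whose cost is outweighed by the non-negative
neighbors they bring, drop negative non-articulation members, plus a few
tentative cheapest-path expansions with best-snapshot tracking (the tree
DP charges a shared connector once per branch; the refinement repairs
that). Against exhaustive enumeration on thousands of random ≤ 12-node
instances the heuristic recovers the full optimum in > 99.9% of cases
and ≥ 90% of the optimal weight in all but ~0.03%.

**Subnetwork score.** experimental term (mean seed value of module
nodes, standardized against the whole input network) × topology term
(fraction of module nodes in its largest connected component ×
`d/(d+1)` for mean module degree `d`). Both factors improve monotonically
as a module collapses onto its best few nodes, so within the search the
topology term also carries a saturating size factor
`1 − exp(−3|V|/n_target)`: essentially no penalty at or above the
requested size (0.95 at the target), steep below about a third of it.
This anchors the optimum near the user's scale without dragging it above
the data's own scale. The score is a strategy interface; the standalone
function without a size target keeps the plain two-term form.

**Schedule and stopping.** The retention fraction decays geometrically
(rate 0.5) toward the target size; once a decay step would overshoot the
target, the loop optionally keeps shrinking (floor 4 nodes) while the
score improves and stops on the first decline, returning the
best-scoring iteration — the module may therefore be more compact than
the target when the data support it (`refine_below_target=False`
restores a hard stop at the target size). If a near-1 retention makes no
progress, one full decay step is forced; if that still cannot shrink the
subnetwork, the loop stops. Iteration-of-removal bookkeeping (which
iteration each node left the subnetwork) is kept for the biased-walk
evaluation.

## Synthetic data

Generators cover everything the tests need without downloads: scale-free
layers by preferential attachment (hub structure that makes degree bias
meaningful), Erdős–Rényi layers, configurable layer overlap (shared node
ids with the first layer), independent bipartite sampling, and a planted
connected module sampled by random walk whose replicas draw seed values
|Normal(effect, 1)| against an |Normal(0, 1)| background. A Chung–Lu
power-law generator (`powerlaw_ppi_graph`, exponent 2.5, mean degree 30)
emulates interactome density — STRING-scale PPI networks average ~30
interactions per protein with a continuous degree spread, which
preferential attachment (minimum degree shared by half the nodes) does
not reproduce. The degree-anticorrelated seed fixture assigns
differential-expression-style −log10(p) values (a null/alt mixture with
a heavy right tail) sorted against degree rank.

What the generators do *not* emulate: community structure and pathway
clustering, edge-weight heterogeneity from evidence scores, assay
missingness patterns correlated with biology, and inter-study degree
biases. Passing tests therefore demonstrate the machinery's contracts
and directional behavior, not performance on real interactomes.

## Benchmark protocols

- **k-fold ranking:** each gene set is split into k folds (deterministic
  given a fold seed); training members become equal-mass seeds; ranks of
  held-out members are computed among all non-seed replica-collapsed
  nodes (mean score over a node's replicas; ties share the mean rank)
  and pooled into an ECDF. Sets smaller than the fold count are skipped.
- **Score–degree correlation:** Pearson correlation of per-replica
  diffusion scores with unweighted intra-layer degree, averaged over
  seed sets; constant scores report NaN.
- **Biased-walk impact:** paired module searches (unbiased vs
  distance-decay bias toward nodes of interest), reporting the NOI's
  mean iteration-of-removal scaled by total iterations and the mean
  full-graph distance from module nodes to the NOI. Identity bias
  (k_scale = 0) reproduces the unbiased run exactly.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| r | 0.5 | restart probability; smoothing extent |
| λ, δ | 0.5, 0.5 | layer-switch / component-jump probabilities |
| τ, η | uniform | layer / component seed weights (simplices) |
| k_pen | 0.5 | hub penalization in penalized normalization |
| γ, rounds | 1, 1 | inflation strength / repetitions (IN) |
| IPF tol / max sweeps / stall | 1e-6 / 1000 / 5e-3 | bistochastic scaling stop rules |
| k_scale | 0.5 | distance decay of the NOI bias |
| n_target | 50 | module size the retention schedule aims for |
| decay | 0.5 | geometric retention decay rate |
| RWR tol / max iter | 1e-10 / 1000 | fixed-point stopping |

Problem sizes used in the test and acceptance runs — graphs of 15–1000
nodes, 200 randomized transition configurations, 50 solver-oracle draws,
100 exhaustive-oracle MWCS instances, 10–20 replicates for the
directional properties — were chosen so the full suite completes in a
few minutes on one CPU while keeping every property's sign and margin
stable across seeds.

## Known limitations

- The crosstalk mixing and the IN exponent reproduce documented
  *behavior* (linearity; entropy increase) rather than a published
  formula; both are isolated behind options.
- The MWCS step is heuristic; adversarial weight patterns with shared
  negative connectors can cost up to ~20% of the optimal weight in rare
  cases (~0.03% of random instances).
- Exact bistochasticity is unattainable on typical interaction networks
  (no total support); BS yields an *approximately* bistochastic matrix
  near the entropy peak, and its IPF warning reports the achieved
  deviation.
- Distances for the NOI bias are unweighted; edge-weighted distances are
  a possible extension.
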