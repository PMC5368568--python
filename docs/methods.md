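# Methods

## Model

A network is an undirected, unweighted simple graph G = (V, E), |V| = n,
|E| = m. Its adjacency matrix **A** is binary and symmetric with a unit
diagonal (`a_ii = 1`): the self-link convention makes every node a member
of its own neighborhood, which stabilizes the factorization on
low-degree nodes.

The generative assumption is that **A** is the observable shadow of an
expectation network Â = XXᵀ, where the nonnegative n×K matrix **X**
holds membership probabilities: x_ik is the probability that node i
belongs to community k, and each row of **X** sums to 1. **X** is fitted
by minimizing the squared Frobenius loss ‖A − XXᵀ‖²_F with the
multiplicative update

    x_ik ← x_ik · (AX)_ik / (XXᵀX)_ik ,

followed by row renormalization after every sweep. The closed form of the
update is the canonical symmetric-NMF multiplicative rule derived from
the gradient of the squared loss; the per-sweep renormalization is part
of the model (rows must stay distributions), not a cosmetic
post-processing step.

Two consequences of the renormalization are worth stating explicitly:

* The renormalized iteration is *not* a descent method for the Frobenius
  loss. On dense blocks (cliques, the small fixtures) the loss decreases
  essentially monotonically and reaches the analytic optimum — on two
  disjoint triangles with K = 2 the block-indicator solution gives loss
  exactly 0, and the fitted loss is below 10⁻⁶. On sparse blocks the
  simplex constraint forces XXᵀ to reconstruct dense unit blocks, so the
  converged loss can sit *above* the loss of the diffuse random start.
  That is inherent to the row-stochastic model; the trajectory is
  monitored and logged, and loss-not-above-init is asserted only on the
  dense fixtures.
* Restart selection by lowest loss remains meaningful because all
  restarts run the same constrained iteration; empirically the landscape
  on community-structured graphs is easy and restarts agree to within
  fractions of a percent.

### Link-entropy score

After fitting, probabilities below 10⁻⁷ are raised to 10⁻⁷ and the added
mass is subtracted from the row's largest entry (for K = 2, from "the
other component"), so logarithms never see zero. With H the Shannon
entropy and JSD = ½KL(p‖m) + ½KL(q‖m), m = ½(p+q), both taken with
base-K logarithms so each lies in [0, 1]:

    LE(i, j) = ½ · [ (H(x_i) + H(x_j))/2 + JSD(x_i, x_j) ]

The two terms cover complementary situations: an edge incident to an
*overlapping* node (high endpoint entropy) and an edge joining two nodes
that are each certain but of *different* communities (high divergence).
Both situations place the edge on a community boundary, where it carries
the burden of global connectivity. LE ∈ [0, 1], symmetric in endpoints.

A floor effect follows from the clamping and should be kept in mind when
reading scores at the bottom of a ranking: once both endpoints of an edge
have fully saturated memberships (entries at 10⁻⁷ and 1 − 10⁻⁷), the
score is pinned at LE ≈ 1.2×10⁻⁶ exactly, and distinctions below that
scale are not resolvable — edges deep inside communities tie there.

### Defaults and parameters

| parameter | default | meaning / rationale |
|---|---|---|
| K | 2 | communities in the factorization; a bipartition targets the cheapest cut into two large components, which is the attack being ranked for |
| log base | K | keeps H and JSD (hence LE) in [0, 1] for any K |
| restarts | 20 | best-of-restarts by loss; tames single-init variance (single-init mode, `n_restarts=1`, is used in the robustness replications) |
| max_iter | 2000 | multiplicative sweeps per restart |
| tol | 10⁻⁹ | relative loss-change plateau declaring convergence (cheaper than membership-stability checks and sufficient at these sizes) |
| clamp floor | 10⁻⁷ | probability floor before entropies |
| init | i.i.d. U(0.01, 1), rows normalized | strictly positive start avoids the zero fixed points of multiplicative updates |
| denominator ε | 10⁻¹² | guards the update against a vanishing denominator |
| θ (degree product) | 1 | only the edge order matters downstream |
| k, ρ (ERW-Kpath) | 20, 50·m | walk length and walk count of the Monte-Carlo estimate |
| bridgeness timeout | 60 s | exact maximal-clique enumeration is exponential; the index is skipped (error raised) rather than approximated, since a heuristic would silently change the index |

## Percolation protocol

Scores are computed once, on the intact network; edges are then removed
one at a time in descending score order. Equal scores are ordered by a
seeded shuffle — degree product and bridgeness produce massive ties, and
a deterministic lexicographic order would bias the curves; the tie seed
is recorded in the trace. After each removal the harness records
f (removed fraction), R_GC (largest-component share of the *original* n;
isolated nodes stay in the denominator) and the normalized
susceptibility S̃ = Σ_s n_s·s²/N over all components except one largest
(co-largest duplicates stay in the sum). The percolation threshold is the
smallest f attaining the S̃ maximum; a trace whose susceptibility never
leaves zero yields threshold 1.0 with a warning. Every removal is
recorded up to 5000 edges; larger graphs are sampled on a 200-point
grid, which preserves the curve shape at the sizes this package targets.

The protocol is deliberately static: scores are not recomputed as the
network unravels, so no synergistic effects of earlier removals enter
the ranking. Adaptive re-scoring attacks and node percolation are out of
scope.

## Synthetic study conditions

Two seeded generators stand in for community-structured benchmark
networks:

* **Planted two-block graphs** — 40 nodes per block, within-block edge
  probability 0.3, between-block 0.02. This places ~470 intra-block edges
  against ~32 planted bridges: blocks are dense enough to be
  unambiguous communities, bridges sparse enough that finding them is
  informative. The generator records the planted bridge set as ground
  truth for enrichment checks.
* **Barbells** — two cliques of 10 joined by one bridge; the canonical
  single-weak-link topology used for the initialization-robustness
  replications (100 single-init runs, threshold histogram in bins of
  width 0.1 centered on multiples of 0.1).

What these emulate: community structure with known boundaries and known
connectivity-critical edges, small enough that the attack comparison
(LE threshold vs. degree-product threshold over 20 generator seeds,
paired one-sided Wilcoxon test at α = 0.05, plus precision of the top
|bridges| LE ranks) runs in seconds. What they do not emulate: heavy-
tailed degree sequences, degree disassortativity, overlapping or nested
communities, and the scale of real interactomes or infrastructure
networks — passing on them shows the pipeline ranks planted boundaries
correctly under clean conditions, not that LE dominates on any real
network.

## Numerical and design choices

* **Node order.** Labels are strings; matrix rows follow a sorted label
  order with numeric labels ordered numerically, so runs are
  reproducible and rows addressable.
* **Edge betweenness convention.** Sums σ_st(E)/σ_st over unordered
  pairs {s, t}; a global halving would not change any ranking.
* **Diffusion importance.** n_x→y counts y's neighbors outside x's
  *closed* neighborhood (x and all of x's neighbors excluded) — the
  reading consistent with the index's epidemic motivation; the edge's own
  far endpoint never counts since it ends inside the closed neighborhood
  by definition.
* **Topological overlap degenerate case.** A zero denominator (two
  degree-1 endpoints) scores 0: "no common friends".
* **Clamp generalization for K > 2.** The compensation rule is stated
  for two components; the deficit is taken from the row's largest entry.
* **Assortativity on regular graphs** is undefined (zero degree
  variance) and returned as NaN with a warning rather than a value.
* **Statistics conventions.** Clustering C is the mean *local*
  clustering coefficient (degree-<2 nodes contribute 0), which is the
  convention that reproduces the standard published karate value 0.5706;
  global transitivity would not.
* **Problem sizes.** The bundled studies run at desk scale: the 9-node
  worked example, 34-node karate, 80-node planted graphs, 20-node
  barbells, oracle sweeps on ≤ 10-node graphs. The factorization is dense
  O(n²K) per sweep, so scaling to 10⁵-node networks would need a sparse
  or hierarchical treatment that is explicitly out of scope.

## Known limitations

* LE needs community structure to say anything: on graphs whose
  factorization finds no meaningful bipartition (regular lattices,
  homogeneous random graphs) the membership rows drift toward uniform
  and scores compress toward 0.5 without a useful ranking signal.
* Multiplicative updates find local optima; best-of-restarts reduces but
  does not eliminate initialization dependence. The
  `threshold_distribution` harness exists to quantify exactly this.
* The clamp floor erases sub-10⁻⁷ membership distinctions by design;
  rankings among fully-saturated within-community edges are arbitrary
  (tied) and broken only by the seeded shuffle during attacks.
* Weighted and directed networks are rejected at input (a symmetrize/
  ignore-weights escape hatch exists for file reading); the factorization
  model is built for binary symmetric adjacency.
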