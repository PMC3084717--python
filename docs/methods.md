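# Methods

## The statistical model

A community is judged against the **configuration model**: the ensemble of
random (multi)graphs in which every vertex keeps its observed degree and edge
stubs are paired uniformly at random. For a cluster `C` under scrutiny the
internal wiring of `C` is held fixed at its observed value, so the cluster's
`kC_out` free stubs can pair only with stubs outside `C`. Conditioned on
this, the number of stubs a candidate vertex `i` (with `k_i` stubs) sends
into `C` is exactly hypergeometric,

    P(k_in = t) = C(k_i, t) C(kG_out, kC_out - t) / C(k_i + kG_out, kC_out),

where `kG_out` counts the stubs of the rest of the graph: the cluster's free
stubs sample the external stub pool without replacement. The expression is
evaluated through log-gamma, so stub counts of any size never overflow, and
it is anchored in the test suite to a brute-force enumeration of the
constrained stub matchings on pools of up to 12 stubs. (The unconditional
matching law — one that lets the cluster's free stubs pair among themselves —
is *not* the null realized by actual configuration-model graphs once the
internal degree is observed; with it, the scores below are measurably
non-uniform.)

Because `k_in` is discrete, its tail probability is smoothed by the
**randomized probability integral transform**: the score of a vertex is
drawn uniformly on `[T(k_in + 1), T(k_in)]`, `T(x) = P(X >= x)`. If `k_in`
comes from the null, `r` is exactly Uniform(0,1). Using interval midpoints
instead would bias the scores and manufacture clusters in random graphs.

Jointly, the internal degrees of all external vertices are multivariate
hypergeometric (they compete for the same `kC_out` free stubs). The scorer
therefore evaluates the external vertices **sequentially in random order**,
each against the stubs not yet consumed by the previously scored vertices.
By the chain rule this makes the whole score vector exactly iid Uniform(0,1)
under the null — the property the order-statistics layer depends on. Scoring
every candidate against the full pool instead leaves a negative dependence
that visibly distorts the null distribution of the cluster score.

## Order statistics and the cluster score

With `n` external vertices, the probability that the q-th smallest score is
below an observed value `r` is the binomial tail
`Omega_q(r) = I_r(q, n - q + 1)` (regularized incomplete beta). The raw
cluster score is the most surprising rank,

    c = min_{q <= rank_cap} Omega_q(r_(q)),

and its null cumulative distribution `Phi`, which depends only on the pool
size, is tabulated by Monte Carlo (default 10^4 draws per pool size; the
first `rank_cap = 128` order statistics are generated directly through the
Renyi representation). `Phi(c)` is the fitness the method works with: a
small value means the boundary holds unexpectedly strong candidates.

Two devices keep the observed statistic and the tabulated null *identical*
objects, which is what makes `Phi(c)` exactly uniform on null graphs:

* pools larger than 64 are bucketed onto a 3 % geometric grid, rounding
  down, and the candidate set is uniformly subsampled to the bucket size
  (a uniform subsample of iid uniforms is again iid);
* the minimum runs over ranks `q <= 128` on both sides.

Null tables are deterministic constants: their seeds derive from the pool
size alone, so every run, in any process, reproduces the same tables.

Interpretation note: `Phi(c)` measures *boundary incompatibility with the
null*. A perfect, well-separated community has a null-compatible boundary —
`Phi(c)` roughly uniform — and its significance shows up operationally (its
members survive pruning; no external candidate is admitted), not as a small
`Phi(c)` of the intact cluster.

## Single-cluster clean-up

One trial alternates two phases until a fixed point (at most `cycles = 3`
alternations):

* **add** — score all external vertices, sort, and admit the longest prefix
  of ranks whose order statistic beats the `P`-quantile of the tabulated
  minimum-statistic null (so the familywise false-admission rate per pass is
  `P`). One pass is capped at roughly doubling the cluster (`2|C| + 8`): a
  chance fluctuation at a deep rank must not avalanche a long prefix of null
  vertices in.
* **prune** — repeatedly remove the member with the highest score relative
  to the rest until the worst member is re-admitted by the add criterion.
  The re-admission check runs at the Bonferroni-corrected level `P / |C|`:
  the worst member is the extreme of `|C|` examined vertices and, unlike
  external candidates, was *selected into* the cluster, so testing it at the
  raw level lets locally optimized subsets of random graphs survive. Members
  whose score exceeds the prefilter cut (0.5) can never be re-admitted and
  are shed in one batch.

Because the bootstrap is stochastic, the trial is repeated (`trials = 10` by
default; the reference protocol used 100) and a cluster is accepted when
more than half the trials return a non-empty result; the final members are
those present in more than half of the non-empty outcomes. The whole
vote is then iterated from its own output until the membership stabilizes —
a significant cluster is a fixed point of its own clean-up, and the
iteration recovers borderline members that enter a climb late. Three speed
short-cuts are built in and documented here because they alter the exact
trial count: an opening streak of three empty trials rejects the seed; a
run of four identical opening outcomes accepts it; and a majority of empty
trials aborts early.

## Network analysis

Seeds are grown by adding `q` vertices one at a time, each the most
significant neighbor of the current set, with `q` drawn from a power law
with exponent `-2` truncated to `[4, min(n - 1, 128)]` (smaller groups
almost never survive cleaning; larger ones are reached by the add phase
climbing from a planted core, or by the supernetwork levels). The grown set
is cleaned; a sweep visits every vertex not yet covered. Several sweeps
(`runs = 4`) vote: a cluster is retained when it (or a similar cluster —
overlap above half the smaller set) appears in more than half of the sweeps,
the biggest version winning. Sweeps that can no longer seed a new majority
group only revisit the territory of groups already found.

Retained clusters are decomposed into **minimal** ones: a single-sweep
search inside the induced subgraph proposes submodules, the unexplained
remainder gets its own chance (it may be a single whole submodule, which the
inner sweep cannot report), and the candidates face *arbitration*: each is
cleaned inside the induced subgraph of their union — neglecting the rest of
the network — and the submodules win only if every one of them is
significant at the Bonferroni level `P / l`. Submodules keep their
subgraph-cleaned membership; re-cleaning them against the whole network
would climb straight back to the union. Similar survivors are merged when
their union shows no internal structure, otherwise the bigger one is kept.
Vertices in no retained cluster are reported **homeless**, never
force-assigned.

An initial cover (from another algorithm, or the previous snapshot of a
dynamic network) can be supplied; its clusters are cleaned first and seed
every sweep, which is both the two-step mode for large graphs and the
snapshot-tracking mode for network dynamics.

## Hierarchy

Each cover level is coarse-grained into a supernetwork: clusters become
supervertices, and an edge whose endpoints belong to `m_i` and `m_j`
clusters contributes `1/(m_i m_j)` (times its weight, if weighted) to every
cluster pair it straddles; aggregated superedge weights are rounded to the
nearest integer (half away from zero, zero-rounded edges dropped) because
the null machinery needs integer stub counts — superedge weights act as edge
multiplicities at the next level. Homeless vertices are *not* carried up as
singleton supervertices by default: experiments on two-level benchmarks show
that leftover fragments of trimmed clusters agglomerate into spurious
supernetwork clusters instead of joining their parent groups
(`carry_homeless=True` restores the carrying behavior). Upper levels run
with at least 10 sweeps and 20 trials — supernetworks are small, so the
extra reliability is nearly free — mirroring the heavier iteration counts
the reference protocol uses above the first level. Recursion stops when a
level yields no grouping, repeats the previous level, or exhausts a depth
cap.

## Directed and weighted graphs

Directed graphs contribute two score channels per candidate (its out-stubs
against the cluster's free in-stubs and vice versa; both channels are
hypergeometric in their own bipartite pools). Edge weights contribute a
third channel: the null law of a weight is exponential with scale equal to
the harmonic mean of the endpoints' average incident weights (the harmonic
mean is the more sensitive to the smaller endpoint; the exponential is the
maximum-entropy law with that mean), giving `r_w = exp(-w/h)` per edge, and
a candidate's edge scores are collapsed with the product-of-uniforms CDF
`F_k(x) = x * sum_{j<k} (-ln x)^j / j!`. The same CDF combines topological
and weight channels (up to four for weighted digraphs) into one uniform
score.

## Synthetic benchmarks

The generator family emulates the standard heterogeneous planted-partition
benchmarks: power-law degrees (exponent 2, mean tuned by the minimum degree,
hard maximum), power-law community sizes tiled to `n`, and a mixing
parameter `mu` = fraction of each vertex's neighbors outside its community.
Vertices are assigned to communities capacity-aware (a community must be
able to host the vertex's internal degree), internal and external stubs are
matched separately with rewiring passes that remove self-loops, duplicates
and (for external stubs) same-community pairs; leftover conflicts reduce the
vertex's degree rather than leak across the boundary, so the requested
mixing is realized to within ~0.01. The two-level variant wires micro- and
macro-communities with fractions `mu2` and `mu1` (equal-size blocks); the
overlapping variant gives a chosen fraction of vertices several memberships
with equally split internal stubs; the noise variant attaches extra
vertices by preferential attachment with power-law initial degrees
(exponent 2.5, minimum 2). These generators reproduce the *statistical
structure* of the published benchmark family, not its exact code; passing
the tests shows recovery under heterogeneous degrees, sizes and controlled
mixing, but says nothing about degree-degree correlations, clustering
coefficients or metadata noise found in real data.

Evaluation uses the overlap-aware normalized mutual information between
covers (per-cluster best-match conditional entropies, with the standard
agreement constraint, averaged and normalized; clusters with zero
membership entropy count as unexplained, and homeless vertices are *not*
turned into singleton clusters), the Jaccard index between vertex sets, and
an L1 distance between unit-normalized weight matrices for comparing
weighted snapshots.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `P` | 0.1 | tolerance: familywise false-admission rate per add pass and acceptance level throughout |
| `trials` | 10 | clean-up repetitions voted over (reference protocol: 100) |
| `runs` | 4 | sweeps combined into the final cover (reference: 10/50) |
| `verdict_threshold` | 0.5 | fraction of non-empty trials required |
| `freq_threshold` | 0.5 | participation-frequency cut for membership |
| `candidate_prefilter` | 0.5 | scores above this are never admissible (speed) |
| `cycles` | 3 | add+prune alternations per trial |
| `q_exponent` | -2 | growth-size power law |
| `similarity_fraction` | 0.5 | overlap/min-size cut for "same module" |
| `null_samples` | 10^4 | Monte-Carlo draws per null table |
| `rank_cap` | 128 | boundary ranks examined by the minimum statistic |

`P` controls resolution: larger values admit smaller clusters. The defaults
for `trials`/`runs` are scaled down from the reference protocol to keep
whole-benchmark analyses at desk scale; both knobs trade time for vote
stability and are the first thing to raise on hard graphs.

## Numerical choices and degenerate inputs

Log-space evaluation throughout; pmf tails are assembled from analytically
normalized terms and clamped to `[0, 1]` against roundoff. Ties in the
minimum statistic break toward the smallest rank; ties in the worst-member
choice break toward the smallest vertex index. A cluster with no external
vertices scores `(1, 1)` (vacuously compatible with the null); a singleton
is never a cluster; an isolated vertex grows nothing. Self-loops are
dropped on input (the null counts stubs between distinct sets), duplicate
edges collapse by weight summation, and undirected edges are stored
canonically.

## Problem sizes used by the shipped checks

The statistical tests run, per invocation: calibration on 10^4 subset draws
of 300-vertex configuration multigraphs (10^5-sample tables); recovery on
ten planted 4-partitions with 256 vertices; false-positive checks on two
500-vertex random graphs; one noise run on a 1000+200-vertex benchmark; ten
two-level benchmarks with 512 vertices; and Zachary's karate club. The
acceptance script recomputes the same quantities at slightly smaller
replication (six planted, one random pair, one noise, four hierarchical
realizations). These sizes are the package's default study conditions; all
scale up through `Config`.

## Known limitations

* The exactly calibrated null is *more conservative* than implementations
  relying on numerical approximations: on Zachary's karate club the two
  factions are returned only at a permissive tolerance (`P = 0.5`) as
  homogeneous cores with ~30 % of vertices homeless, whereas the reference
  reports two clusters of average size 17 at its default. On small, densely
  interlinked graphs the whole graph is often the only unit the null cannot
  reject.
* Boundary scores are exactly iid only under the multigraph configuration
  model; simple-graph ensembles deviate slightly (no multi-edges), which is
  invisible at benchmark scale but would matter for very heavy-tailed
  degree sequences.
* Directed channel pairs are treated as independent, which is exact for
  each channel's marginal but only approximate jointly.
* The weighted null (exponential with harmonic-mean scale) is a modeling
  choice; heavy-tailed weight distributions call for a different law.
* Runtime is dominated by repeated boundary scans; graphs beyond ~10^4
  vertices should use the two-step mode (seed with a fast partitioner via
  `--init-cover`).
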