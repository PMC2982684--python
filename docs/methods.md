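# Methods

## Quality functions

For a partition of an undirected simple graph (n nodes, L edges) into
modules G_1..G_m, with l_in,i internal edges, l_out,i boundary edges,
n_i nodes and d_i = 2·l_in,i + l_out,i total degree per module:

* modularity `Q = Σ_i [l_in,i/L − (d_i/2L)²]` — internal edge fraction
  against a degree-preserving random expectation; Q of the single-module
  partition is exactly 0 and Q < 1 always.
* modularity density `D_λ = Σ_i (4λ·l_in,i − 2(1−λ)·l_out,i)/n_i`, the sum
  of per-module average inner minus outer degree weighted by λ; `D = D_0.5
  = Σ_i (2·l_in,i − l_out,i)/n_i`. Because each term is normalized by n_i
  rather than L, the score of a module does not depend on the size of the
  rest of the network, which is what removes the resolution limit.

Simplifying 4λ·l_in − 2(1−λ)(d − 2·l_in) = 4·l_in − 2(1−λ)·d shows D_λ
equals the trace form Σ_c h_cᵀ M_λ h_c / (h_cᵀ h_c) with
M_λ = 2A − 2(1−λ)B and h_c the 0/1 module indicator. The displayed closed
form of D_λ was chosen as the unique affine-in-λ expression that (a)
reduces to D at λ = 0.5 and (b) matches this trace form; the test suite
asserts the identity to 1e−9 on random graph/partition pairs and the
entrywise reduction M_0.5 = 2A − B. All quality values are computed from
integer tallies and divided once, so results are deterministic across
platforms. Singleton modules are legal (their term is −(1−λ)·2·deg(v)/1);
optimizer constraints, not the quality functions, decide whether to allow
them.

By the Rayleigh–Ritz/Fan bound, D_λ of any k-partition is at most the sum
of the k largest eigenvalues of M_λ. The suite verifies this exhaustively
over all partitions of small graphs, and every SpeMD run asserts it on its
returned partition.

## Simulated annealing (MD / MQ)

The annealer maximizes Q or D_λ with the Metropolis rule on cost −Q or
−D_λ: downhill moves always accepted, uphill moves with probability
exp(−ΔC/T). It starts from the all-singletons partition and keeps every
module's induced subgraph connected throughout — disconnecting proposals
are discarded (the connectivity test runs only for moves the Metropolis
rule would accept, which is equivalent and cheaper).

Moves per temperature stage:

* `min(f1·n², max_single_per_stage)` single-node relabels. The target
  module is the module of a uniformly random neighbour (so incident modules
  are sampled proportionally to their edges to the node), or a fresh
  singleton with probability 1/(deg+1). Δcost is computed incrementally
  from the per-module integer tallies.
* `max(1, f2·n)` collective moves, an even mix of merges (the two modules
  at the ends of a random edge, so merged modules always share an edge and
  stay connected) and splits. A split isolates one module and runs a
  nested annealing on its induced subgraph, maximizing the subgraph's own
  two-way D_λ with both halves kept connected, for min(10·n_i², 2000)
  moves at a tenth of the outer temperature; the winning bipartition is
  then offered to the outer Metropolis rule at the global objective.

Defaults: T0 auto-calibrated so a median uphill probe move from the start
state is accepted with probability ~0.5; geometric cooling 0.95 per stage;
stop at T < T0·1e−4, after 3 stages without an accepted move, or at 500
stages; f1 = 1 (capped at 20,000 single moves/stage), f2 = 0.05. These
constants were chosen to give run times of seconds on 250-node benchmark
networks and a couple of minutes at 1000 nodes while reliably reaching
enumeration-verified optima on small graphs; slower cooling buys little
beyond this point because of the final quench.

After the anneal, a deterministic zero-temperature quench polishes the
incumbent: best-improvement single-node sweeps, best profitable merge, and
profitable splits (via the nested bipartitioner) alternate until a local
optimum under all three move kinds is reached. The quench is what makes
the returned partition a genuine local optimum rather than wherever the
cooling schedule happened to stop; without it the annealer systematically
under-merges on large weakly-coupled networks (it would miss much of the
Q resolution-limit merging) and under-splits on noisy ones.

One seeded `random.Random` generator drives the whole run (nested
annealings draw from the same stream), so runs are bit-reproducible per
seed. The returned score is recomputed from the returned partition from
scratch as a guard against stale incremental tallies.

## SpeMD

1. Compute the K leading eigenpairs of M_λ — dense `eigh` up to 500 nodes,
   ARPACK (`eigsh`, tol 1e−10, deterministic start vector) above; column
   signs fixed by making each eigenvector's largest-magnitude entry
   positive.
2. For each k in 2..K: take eigenvectors u_2..u_k, normalize rows to unit
   length (all-zero rows stay zero), cluster the rows into k clusters with
   k-means (10 restarts; the first uses an orthogonal-centroid
   initialization — each next centroid is the row minimizing the maximum
   absolute cosine to those already chosen — the rest are random; best by
   within-cluster sum of squares). k values exceeding the number of
   distinct rows are skipped. Zero rows are assigned to the nearest
   centroid afterwards, ties to the lowest cluster index.
3. Score every candidate partition with D_λ and return the argmax over k.

Dropping the leading eigenvector u_1 follows the published procedure
literally; `include_u1=True` keeps it (columns u_1..u_k), which is the
conventional spectral-clustering embedding. The default can fail to
separate identical disconnected components whose indicator eigenvectors
are degenerate (equal eigenvalues make the returned basis an arbitrary
rotation, and 1-D row normalization collapses same-sign entries); the
u_1-variant recovers such components exactly, which is why the option
exists. No connectivity constraint is imposed on SpeMD output (the
annealer is the only optimizer with that invariant); modules inducing
disconnected subgraphs are listed in the result rather than repaired.
λ defaults to 0.5; PPI-style scans typically sweep λ from 0.4 to 0.7 in
steps of 0.05 and pick the λ whose modules best match an external
catalogue.

## Benchmark generator

An instance has 2m cliques — m of size n1 = 10 and m of size n2 = 15 by
default, matching the published study conditions — plus exactly
`round(m(n1+n2)·k_out/2)` external edges drawn uniformly without
replacement from inter-clique node pairs, so the mean external degree is
k_out and the total edge count equals the expectation
`m(n1(n1−1)/2 + n2(n2−1)/2) + round(m(n1+n2)k_out/2)` exactly. A
fixed-count uniform-pair scheme is the lowest-variance design consistent
with that expectation and makes edge-count tests sharp; per-pair external
edge counts are still approximately Poisson, so occasional clique pairs
end up joined strongly enough that merging them genuinely increases D (at
k_out = 8 even greedy improvement from the planted truth merges several
pairs — perfect D-maximization does not imply perfect recovery there).
`relax_to_dense_modules` thins each clique's internal edges independently
with probability p_in for dense-but-incomplete planted modules. Instances
at low k_out may be disconnected; all downstream code tolerates that.

What the generator does *not* emulate about real PPI data: degree
heterogeneity within modules (cliques are regular), overlapping complexes,
size distributions beyond the two planted sizes, and false-positive/
false-negative interaction noise structure. Passing recovery tests on
these benchmarks therefore demonstrates correct optimizer behaviour on
well-separated modular structure, not performance on experimental
interactomes.

## Evaluation measures

* **precision(detected, planted)** — planted modules are matched
  one-to-one to detected modules, greedily by descending overlap (ties:
  larger planted module first, then lexicographic labels; a Hungarian
  maximum-total-overlap assignment is available via `method="hungarian"`);
  a node is correct iff its detected module is the one matched to its
  planted module. The measure is invariant to module relabeling.
* **P_ol** — upper tail P(X ≥ k) of the hypergeometric distribution with
  population N (the network size), |C| successes, |M| draws, computed in
  log space (`scipy.stats.hypergeom.logsf`); reported as −log10. Zero
  overlap scores exactly 0. The tail (rather than the point mass) is used
  because it reproduces the published yeast-network worked examples that
  are internally consistent; the suite also checks it against an
  exact-rational oracle.
* **contingency / Sn / PPV / ACC / SEP** — the complexes × modules table
  counts shared proteins over the complex-annotated universe (module
  members outside the catalogue are ignored there, but P_ol's N stays the
  full network size). Sn is the size-weighted mean over complexes of the
  maximal fraction captured by one module; PPV the column-weighted mean
  over modules of the maximal fraction lying in one complex; ACC their
  geometric mean. SEP multiplies row-wise and column-wise relative
  frequencies cellwise; complex-wise/module-wise sums are averaged
  (zero-marginal rows/columns contribute 0) and SEP is the geometric mean
  of the two. A complex split across two otherwise-pure modules keeps
  SEP_co = 1 but halves SEP_cl — splitting is penalized on the module
  side. A protein in several complexes counts in each row (catalogues are
  not partitions).
* **filter_small_modules** — drops modules below a size threshold (the
  published PPI analysis removed modules of size ≤ 3); their nodes become
  unassigned.

## Numerical and design notes

* Graphs are undirected, simple, unweighted; node ids are opaque strings.
  Edge-list input is whitespace/tab-delimited with '#' comments; self-loops
  and duplicate/reversed pairs are dropped with a logged count.
* Giant-component ties break by smallest lexicographic node label.
* Metropolis exponentials are skipped when Δ/T > 700 (underflow guard).
* k-means delegates the Lloyd iterations to scikit-learn; the bespoke
  orthogonal-centroid first restart is passed as an explicit init array.
* The quench's split pass uses the (seeded) run generator, so `sa_optimize`
  remains bit-reproducible end to end.
* Known limitations: the annealer is quadratic-ish per stage and meant for
  networks up to a few thousand nodes (the spectral path scales further);
  SpeMD offers no connectivity guarantee; D_λ with λ near 1 rewards very
  fine partitions and can return many singletons on sparse graphs.
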