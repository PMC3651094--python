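# Methods

This note documents the models and numerical choices behind `voxconn`,
module by module, including the parameters that matter, what the
synthetic generator does and does not emulate, and the design decisions
made where more than one convention exists in the field.

## Network construction

**Normalization.** Each node's time course is centered and scaled to
unit Euclidean norm; the pairwise Pearson matrix is then exactly
`R = UᵀU`. A constant (zero-variance) column is a hard error rather
than being dropped, so node indices never silently desynchronize from
the voxel mask. The blocked evaluation tiles the upper triangle of R
into `b(b+1)/2` dense tiles of at most `block_size` columns
(default 2048, a CPU memory budget: one 2048² float64 tile is 32 MiB);
results are independent of the block size to 1e-9 element-wise, and the
tests assert this for block sizes 1, 3, 7 and ≥ N.

**Group averaging** is the plain arithmetic mean of r values; Fisher-z
averaging (arctanh-mean-tanh) is available behind a flag but off by
default, matching the usual practice of averaging r directly when the
per-subject matrices are similar.

**Sparsity bounds.** `S₁ = ln(N)/(N−1)` uses the natural logarithm:
at N = 58523 this gives 0.019 % (a base-10 logarithm would give
0.008 %, inconsistent with the reference value, which fixes the
convention). The Bonferroni threshold inverts the exact two-tailed
t-test of a Pearson coefficient at per-test level `α / (N(N−1)/2)` with
`df = L − 2`; at N = 58523, L = 215 this yields r_crit = 0.433. No
effective-df correction for temporal autocorrelation after band-pass
filtering is applied — with such a correction the plain `L − 2`
convention would not reproduce the reference threshold. The upper
sparsity bound S₂ (the sparsity actually achieved at r_crit) depends on
the empirical correlation matrix and is always computed from data,
never asserted.

**Binarization** is strict: edge iff `R_ij > r`. Negative thresholds
are honored literally (the rule stays `R_ij > r`), though in practice
thresholds are positive, which implicitly excludes negative
correlations. A Monte-Carlo property test (10⁵ independent Gaussian
pairs, L = 50) confirms the analytic threshold's exceedance rate to
within 3 standard errors of the nominal level.

## Distances

Distances are exact hop counts in int64 with an `INF = 2³¹` sentinel;
min-plus additions saturate at the sentinel, so no overflow is possible
(2·INF < 2⁶³). The `DistanceMatrix` stores the upper triangle of an
r×r grid of dense blocks (diagonal blocks in full), default block edge
`block_n = 64` — a cache-sized dense tile; GPU-style tiling constants
do not transfer to CPUs. A trailing ragged block is used when
`block_n` does not divide N, so results are exact for every N.

**BFS engine.** One frontier-based BFS per source; sources are sorted
by descending degree and dealt round-robin over `workers` buckets.
The worker parameter defines the (deterministic) schedule only — the
output is required, and tested, to be bitwise identical for every
worker count; no particular concurrency mechanism is part of the
contract.

**Blocked Floyd–Warshall engine.** Each round over the r diagonal
"primary" blocks runs Phase 1 (the primary block itself), Phase 2 (the
blocks sharing its row or column) and Phase 3 (all remaining stored
blocks), each update being the generalized (min-plus) matrix product
`C_ij ← min(C_ij, C_ik + C_kj)`. Two refinements: Phase 1 is solved by
applying the blocked scheme recursively (2×2 split down to a 32-wide
base case that runs the plain k-loop), which adds no extra arithmetic;
and because hop distances are symmetric only the upper block triangle
is kept — a Phase-3 update that needs a lower source block takes the
transpose of the mirrored stored block. Equivalence of both engines
with a naive textbook Floyd–Warshall (and with networkx as a third,
independent oracle) is asserted on hundreds of random graphs, including
disconnected ones, for many block sizes.

**Engine selection.** BFS cost grows linearly with edge count while
blocked FW is density-independent; their crossover on large networks
sits near 2 % sparsity, so `select_apsp` returns BFS iff
`S ≤ crossover` (tie to BFS, crossover configurable).

**Disconnected pairs.** `Lp` averages finite distances only; this is a
documented choice (the convention is not standardized), with a strict
mode that raises on disconnected input, and `global_efficiency`
(mean of `1/d`, `1/∞ = 0`) as the disconnection-tolerant companion
metric. `C_i` for nodes of degree < 2 is defined as 0.

## Spectral modularity

The modularity matrix `B = A − kkᵀ/2m` is never materialized: the
operator applies `A·x − k(kᵀx)/2m` with a sparse adjacency product; on
a node subset the generalized form subtracts the diagonal correction
`d_i = Σ_{j∈g} B_ij`, keeping the all-ones vector in the null space
(asserted to 1e-9).

The leading (most positive) eigenpair comes from power iteration with a
two-pass shift: if the dominant-magnitude eigenvalue converges negative,
a second pass on `B + |β₁|·I` — whose spectrum is non-negative and
ordered like B's — isolates the algebraically largest eigenvalue, which
is shifted back. The start vector is seeded uniform noise
orthogonalized against the ones vector; convergence is
`‖Bx − βx‖∞ ≤ tol·max(1, |β|)` with tol = 1e-8 and at most 10⁴
iterations, after which the result is flagged unconverged (an
unconverged module is left unsplit). Power iteration was chosen over
Lanczos to keep the implementation exactly the stated method; it is
slower but has no re-orthogonalization subtleties.

The division queue starts with the whole network, dequeues a module,
and splits it by eigenvector sign when (a) β > tol and (b) the exactly
re-evaluated modularity gain ΔQ (via the closed-form per-module Q) is
strictly positive; entries exactly 0 join the positive sign group
(deterministic tie-break). Condition (b) is an addition to the plain
β > 0 rule: it guards against eigenvectors whose sign split marginally
lowers Q. Kernighan–Lin fine-tuning after each split is deliberately
not implemented; on the structured fixtures (disconnected cliques,
barbells) the plain spectral division already attains the exhaustive
optimum, which the tests verify by enumerating all set partitions.
Q itself includes the diagonal term of the double sum (`i = j`), the
standard convention under which a single-module labeling gives exactly
Q = 0.

## Null ensembles

Maslov–Sneppen rewiring draws two distinct edges uniformly (the second
in random orientation), swaps endpoints, and rejects any proposal
creating a self-loop or duplicate, so degree sequence, edge count and
simplicity are invariant by construction (fuzzed over 1000 random
inputs). The number of swaps is not standardized; the default is 10
successful swaps per edge — enough to decorrelate edge placement on the
test-scale graphs — with a proposal cap of 100× the target, after which
the partially rewired graph is returned flagged (`rewire_saturated`)
with a warning. A triangle (K₃) is the canonical saturating input:
every proposal is rejected, and the tests assert it comes back
unchanged. Connectedness is *not* enforced on nulls; `Lp` of a null
uses the same finite-pairs policy as the real network. Ensemble
summaries use the sample (n−1) standard deviation; with n = 1 the sd is
reported as 0 and flagged degenerate.

## Small-world statistics

`γ = Cp/Cp_rand`, `λ = Lp/Lp_rand`, `σ = γ/λ` are exact ratios; sweeps
are summarized by geometric means (appropriate for ratio-scale
quantities spanning an order of magnitude across thresholds), with
arithmetic means for Q and Z, which are interval-scale and can be
near zero. The degree distribution `p(k)` is the fraction of all nodes
with degree k over the observed support k ≥ 1: isolated nodes count in
the denominator but not the support. The power-law exponent is fitted
by OLS of log₁₀p on log₁₀k with zero bins dropped — the log-log-plot
convention — with a zeta-normalized discrete MLE exposed as an
alternative. Binned OLS is known to bias the exponent low when tail
bins hold single observations; the tests quantify this on simulated
draws (MLE recovers α = 2.5 to ±0.05 where unrestricted OLS lands near
1.7), which is exactly why both estimators are exposed and why fitted
exponents from sparse tails should be read with care. Hubs are nodes
with degree above mean + 1 sample sd; all nodes (including isolated
ones) enter the mean and sd.

## Synthetic data

The generator draws L samples from a zero-mean Gaussian whose
covariance is block-constant: 1 on the diagonal, `within_r` inside
planted modules, `between_r` across (positive semi-definiteness is
checked before Cholesky sampling). Optional AR(1) smoothing — applied
identically to every node — gives the series band-limited temporal
character while preserving cross-node correlations in expectation;
optional white subject noise attenuates all correlations uniformly.
This emulates what the pipeline *assumes* (linear dependence with
modular structure) and deliberately not what real recordings add:
hemodynamic convolution, motion and physiological artifacts,
non-stationarity, spatial autocorrelation of neighboring voxels.
Passing tests therefore demonstrate algorithmic correctness and
end-to-end parameter recovery under the model's own assumptions, not
robustness to fMRI artifacts.

Default planted design: N = 100 nodes in 4 equal modules,
`within_r = 0.9`, `between_r = 0.0`, L = 2000 time points — strong,
clean structure whose thresholded graphs are exactly the four planted
cliques, making "exact recovery" a well-defined check. The benchmark
graph generators (complete, cycle, path, star, ER, ring lattice,
Watts–Strogatz, planted partition, two-cliques, barbell) are pure
functions of parameters and seed.

## Pipeline and reproducibility

`run_pipeline` executes, per threshold: binarize → sparsity → degree →
clustering → APSP (engine auto-selected unless overridden) → Lp →
spectral modules → null ensemble → small-world indices, z-score,
power-law fit, hub mask; then appends a geometric-mean summary row.
Any stage failure aborts with a stage-tagged error. Every random stage
derives its seed as `base_seed XOR crc32(stage name) mod 2³¹`, so each
stage is independently reproducible and whole runs are bit-identical
(tested). Per-stage wall time is logged for curiosity; no timing is
ever asserted.

Problem sizes used by the test and acceptance suites — graphs up to 60
nodes for the oracle-equivalence sweeps (200 random graphs), 10 nodes
for exhaustive modularity enumeration (50 graphs), the 100-node planted
design for end-to-end recovery, and 1000 fuzzed inputs for rewiring
invariants — are the sizes at which the brute-force oracles themselves
stay exact and fast; the implementation has no scale-specific branches,
so the same code paths run at voxel scale.

## Known limitations

* Weighted networks, partial correlation, betweenness and rich-club
  metrics are out of scope; graphs are simple, undirected, unweighted.
* The BFS engine computes full rows, so its distance store is only as
  memory-light as the blocked layout itself; truly out-of-core APSP is
  not attempted.
* Spectral division without Kernighan–Lin refinement can stop short of
  the global optimum on weakly modular graphs; the exactness claims are
  for the structured fixtures the tests enumerate.
* The power-iteration eigensolver can fail to converge when the two
  extreme eigenvalues tie in magnitude with opposite signs; such
  modules are left unsplit and flagged rather than split arbitrarily.
* Mask handling assumes an already-gridded probability map; spatial
  resampling/registration belongs to upstream preprocessing tools.
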