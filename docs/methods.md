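# Methods

## Model and assumptions

`rwdiffmap` treats a simulation data set as *N* samples of *n* configuration
variables, optionally carrying statistical weights *w*_k = *p*(**x**_k)/*q*(**x**_k)
when the sampling density *q* differs from the equilibrium density *p*
(enhanced sampling).  A Gaussian kernel over the samples, normalised by a
kernel density estimate and reweighted by the statistical weights, is
row-normalised into a Markov transition matrix *M*.  Because the kernel is
symmetric, *M* is similar to a symmetric matrix: its spectrum is exactly
real, bounded by one, and the chain is reversible with stationary density
proportional to the kernel row sums.  The chain's "time" is an auxiliary
diffusion parameter, not the simulation time step; no time-lagged estimation
is performed and no kinetic model with physical rates is implied.  The
working assumptions are those of anisotropic diffusion maps: the slow
dynamics is overdamped on the data manifold, the columns are in comparable
units (the Euclidean metric mixes them directly), and the sample set covers
all relevant metastable states.

### Kernel and reweighting

The kernel is K_kl = *w*_k *w*_l g_ε(**x**_k, **x**_l) / √(ϱ_k ϱ_l) with the
reweighted density estimate ϱ_k = Σ_l *w*_l g_ε(**x**_k, **x**_l).  Two
algebraically consistent reweighting conventions exist: normalising by the
plain density estimate (∝ *q*) with reweighting factor √(*w*_k *w*_l), or
normalising by the reweighted estimate (∝ *p*) with factor *w*_k *w*_l.
Pointwise they are the same kernel in the large-*N*, small-ε limit
(w/√p = √w/√q), and both reduce to the standard anisotropic diffusion-map
kernel at unit weights.  This package uses the second form: it is exactly
the target-measure diffusion map with the unbiased density as target, and on
the double-well fixture (below) its equilibrium density is roughly three
times closer to the analytic Boltzmann marginal at N = 2500 than the first
form, because the density normalisation is estimated self-consistently from
the same weights that appear in the numerator.  A global rescaling of all
weights cancels in the row normalisation, so only relative weights matter;
file ingestion normalises weights to mean one for numerical tameness.

### Scale constant

ε is the median of all N(N−1)/2 pairwise Euclidean distances, recomputed
inside every variable subspace considered (distances shrink when columns are
dropped; a full-space ε would distort partial-representation kernels).  The
median is exact by default; for very large N an optional cap with seeded
pair subsampling is available.  A zero median (all samples coincident in the
subspace) is a hard error naming the subspace — no fallback bandwidth is
ever substituted, since any choice would be arbitrary exactly when the data
cannot support one.

### Spectral loss and its normalisation

σ_d = α Σ_{k=0}^{K−1} |λ_k − λ_dk| over the K leading eigenvalues of the
complete and partial transition matrices, both sorted decreasing.  K
defaults to 10 (capped at N): the leading eigenvalues carry the
slow-time-scale content while the trailing bulk reflects fast intra-state
diffusion.  k = 0 is included and contributes exactly zero (both spectra
have λ₀ = 1).  The absolute-difference form makes the loss symmetric in its
two arguments and zero exactly on identical spectra.  α is fixed after the
search so that the best single-variable loss equals one; the normalised
trace therefore ends at σ₁ = 1 and starts at σ_n = 0 exactly (the full set
is compared against its own spectrum, computed once and reused).

### Eigensolver choices

All decompositions solve the symmetric conjugated problem
D^{−1/2} K D^{−1/2} (D = diag of kernel row sums) with a dense symmetric
solver restricted to the top-K eigenpairs, mapping eigenvectors back by
D^{−1/2}.  This guarantees a real spectrum and an exact stationary density
(∝ row sums) without power iteration.  Eigenvector signs are fixed so the
largest-magnitude entry is positive; eigenfunction comparisons use absolute
Pearson correlation, so sign and scale conventions cannot affect results.
Degenerate eigenvalues are ordered stably; the loss depends only on sorted
values, so degeneracy is benign.

### Floating search

The search is sequential backward floating selection: from the complete set,
remove the variable whose removal minimises the loss (ties broken to the
lowest index); then, while re-adding some excluded variable would produce a
strictly better subset of that size than any recorded before (relative
improvement > 1e−12), re-add the best such variable; repeat until one
variable remains.  Comparing re-additions against the best recorded subset
of each size guarantees termination (each re-addition strictly improves a
bounded record); a hard cap of 10 n² kernel evaluations additionally guards
the floating phase, which is disabled if the cap is hit.  Subset evaluations
are memoised within a run, and the search always continues to d = 1 so the
normalisation constant comes from the same run.  The search is greedy and
suboptimal by design; on the well-separated synthetic benchmarks it attains
the exhaustive minimum (verified for n = 6 in the test suite), but no global
guarantee exists.

The *plateau dimension* is the smallest d from which the normalised loss
stays below a tolerance (default 0.05) for **all** larger d.  For monotone
traces this coincides with "first d below tolerance"; requiring contiguity
makes the detector robust to a single noisy dip.  If no d qualifies, the
full dimension is returned with a `RuntimeWarning`.

## Synthetic study conditions

### Hypercube cluster benchmark

`generate_hypercube` emulates clustered, partially redundant feature sets:
m informative coordinates hold m + 1 Gaussian clusters (sd 0.15) on
hypercube vertices (half-spacing 1.0) — the base vertex (all −1) plus the m
single-coordinate flips — and the other n − m columns are linear echoes of
the informative ones (coefficient vectors of norm 0.3, additive noise sd
0.05).  Column order is shuffled; informative positions, labels, centers and
mixing coefficients are returned as machine-readable ground truth.  Three
design choices matter and were validated by construction-phase pilots:

* **Spanning centers, m + 1 clusters.**  Removing informative coordinate i
  merges exactly the pair (base, flip-i) and destroys one slow eigenvalue,
  so every informative variable is genuinely necessary and the intrinsic
  dimension is m by construction.  Placing only 8 clusters (fewer than
  m + 1) would confine the centers to a lower-dimensional subspace and make
  some "informative" coordinates kinetically irrelevant — the recovery task
  would be ill-posed for m ≥ 8.
* **Dominant base cluster (population 0.75).**  With equal populations most
  sample pairs straddle clusters and the median-distance bandwidth lands at
  the inter-cluster scale, erasing metastability entirely (leading
  eigenvalues ≈ 0.2).  A dominant cluster — the realistic situation, where a
  deep metastable state holds most of a trajectory — keeps the median at the
  intra-cluster scale, giving a clear slow/fast spectral gap.
* **Echo columns are weak and nearly proportional.**  Contributions to
  pairwise distances that are *proportional* to the informative ones cancel
  through the per-subspace bandwidth, so dropping an echo column is almost
  free, as redundancy demands; *additive* noise instead inflates the
  bandwidth non-cancellably.  Norm-0.3 coefficients with sd-0.05 noise keep
  the echoes correlated with their generators (verifiable by regression)
  while leaving the loss plateau at d = m.  Full-strength echoes (norm 1)
  would be as informative as the originals and make the labelled ground
  truth meaningless.

What passing the benchmark shows — and what it does not: recovery of m
demonstrates that the spectral loss detects when cluster-resolving
directions are lost, under well-separated, isotropic, unimodal-per-cluster
conditions with a dominant state.  Real molecular features are correlated,
anharmonic and anisotropic; the benchmark says nothing about bandwidth
selection in poorly separated systems, about features in incommensurate
units, or about sampling noise from correlated trajectories.

### Biased double-well fixture

`generate_biased_double_well` draws Metropolis Monte Carlo samples (step sd
0.5, burn-in 2000, thinning 40 — settings chosen so the unbiased chain's
histogram error against the analytic marginal is ≈ 0.02 total variation at
N = 2500) from the tilted double well U = 4(x² − 1)² + 0.55 x + 3 y².  The
tilt gives a ~70/30 well split, so the dominant well keeps the median
bandwidth at the intra-well scale and the reweighting must recover a
non-trivial population ratio.  The biased chain adds a static Gaussian bias
V_b(x) = −s·exp(−x²/2) (default s = 3) that fills the barrier; weights are
w ∝ exp(βV_b), normalised to mean one.  The bias is spatially smooth (unit
width) on purpose: importance weights that vary much faster than the kernel
bandwidth cannot be resolved by any kernel-smoothed estimator, and this
fixture is meant to probe the reweighting algebra, not kernel resolution.
Time-dependent biases (e.g. metadynamics reweighting schemes) are out of
scope — weights are accepted as input, with only the static-bias helper
w ∝ exp(V/kT) provided.

## Numerical conventions

* Dense double-precision kernels throughout; no sparsification, truncation,
  landmarks or nearest-neighbour approximation (N ≈ 2500 is the intended
  working scale).
* Exact duplicate samples are allowed; only an all-coincident subspace
  (zero median distance) is an error.  No jitter is ever added silently.
* Weight ingestion from a static bias subtracts the maximum before
  exponentiation (overflow-safe; the shift cancels exactly).
* Transition-matrix rows sum to 1 within 1e−12; stationarity and detailed
  balance hold within 1e−8 in tests.
* All generators flow through a single integer seed;
  identical parameters and seed give bitwise-identical data.

## Known limitations

* The median-of-all-pairs bandwidth is a blunt instrument: for strongly
  multimodal data with balanced populations it lands between modes and
  washes out metastability.  The `epsilon` override exists for such cases;
  no automatic tuning scheme is provided.
* The equilibrium eigenfunction of a selected subspace converges to, but
  does not exactly reach, the full-representation one when the discarded
  columns carry any real density variation of their own: on the m = 4
  benchmark (six echo columns) the similarity saturates near 0.97,
  while for m = 6 it exceeds 0.99.  This is a property of the
  representation, not an estimator artifact (it persists at N = 2500).
* The greedy floating search offers no optimality guarantee; exhaustive
  search is exposed only implicitly through `evaluate_subset` for small n.
* Spectral losses for different data sets are comparable only after each is
  normalised by its own single-variable loss; α is not transferable.
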