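# Methods

## Model

`shapescale` treats the choice of per-dimension scaling factors for
distance-based clustering as an estimation problem. Given an
n_orig × d matrix X, each dimension k is standardized by its sample standard
deviation σ_k (denominator n_orig − 1, computed over **all** rows, duplicates
included) and stretched by a factor α_k > 0. The estimand is the vector α.

The guiding functional is the shape complexity of the scaled cloud,
SC(α) = g·h with g the root-sum-square and h the sum of reciprocals of the
pairwise distances r_ij. Its gradient decomposes as SC′_k = g′_k h + g h′_k
with

    g′_k = α_k g⁻¹ Σ ρ²_ijk,      h′_k = −α_k Σ r_ij⁻³ ρ²_ijk .

Two exact identities anchor the implementation and its tests:

* **Radial invariance.** Σ_k α_k SC′_k = 0 for every α, i.e. SC is constant
  on rays from the origin. Distances scale uniformly along a ray, so any
  distance-based clusterer gives identical labels for α and tα; the package
  asserts this end-to-end.
* **Pair-sum identity.** Because σ_k² N = Σ over all-row pairs of squared
  differences (N = n_orig(n_orig − 1)), the standardized squared pair
  differences satisfy Σ_{i<j} ρ²_ijk = N on duplicate-free data, which gives
  the closed form g = (N Σ_k α_k²)^½.

Stationarity of SC on the sphere Σα² = d reduces to an orthogonality
condition between the vector of r_ij⁻³ and the plane containing all the
N⁻¹ρ²_ijk vectors; Problem P minimizes the squared residual of that
condition for the dimension pair (1, 2). An `all_pairs` objective variant
(sum of the squared residual over every pair k < ℓ) is available behind a
flag, since the stationarity condition holds for every pair; the (1, 2)
form is the default for fidelity to the method's canonical statement.

### Duplicates

SC diverges when two samples coincide (r_ij = 0), so all pair sums run over
the unique rows only, while σ_k and the constant N keep all n_orig rows, and
clustering/evaluation also use all n_orig rows. Consequence: the pair-sum
identity (and hence the closed form for g) is exact only when the data are
duplicate-free; tests of those identities use duplicate-free fixtures.
Whether σ_k should instead be recomputed after duplicate removal is
genuinely open; the all-rows convention is forced by the N = n_orig(n_orig−1)
bookkeeping and is applied consistently.

## Optimization

* **Problem P**: SLSQP with the single equality constraint Σα² = d and the
  box α_k ≥ 10⁻⁵ (the relaxed positivity bound that also guards r⁻³ against
  division by zero). Initial points are uniform on [0.5, 1.5]^d; iteration
  cap 5000. The gradient is finite-difference by default; an analytic
  gradient (`TrialConfig(gradient="analytic")`) gives identical minima at
  roughly 40× the speed and is used by the packaged sweeps. The SLSQP
  objective tolerance defaults to 1e-16 — the objective is a square whose
  typical magnitude at feasible points is ~1e-9, so a looser absolute
  tolerance would stop immediately. A trial counts as converged only if the
  solver reports success *and* the sphere residual is ≤ 1e-6 with the box
  respected. Non-converged trials are retained but flagged, and downstream
  summaries report the discard fraction (observed ~1–2% on the Iris
  benchmark).
* **max-SC**: L-BFGS-B on −SC with the box only. SC is evaluated at the
  sphere-normalized point (exact by radial invariance), which keeps g and h
  in a benign floating-point range however far the iterates wander. For data
  in which distinct samples coincide on a subset of dimensions, SC is
  *unbounded*: de-weighting the separating dimensions drives some r_ij → 0
  and h → ∞. Such solves run to the iteration cap with enormous factors and
  a converged=False flag; the qualitative structure (which dimensions pin to
  the 10⁻⁵ bound, which blow up) is still informative and matches the known
  behaviour on Iris, where the sepal dimensions pin at the bound.
* **Trials**: one master seed; per-trial substreams via `SeedSequence.spawn`,
  so results are reproducible and independent of execution order.

## Clustering and evaluation

k-means is Lloyd's algorithm with k-means++ initialization, **best of 20
restarts by the k-means objective** (scikit-learn `n_init`), re-seeded up to
10 times in the (never observed) event of an empty cluster, so every
reported partition has exactly C non-empty clusters — the premise of the
fixed-number-of-clusters (fnc) null. Restart stabilization is a deliberate
departure from single-run k-means: it makes reported values reproducible
functions of (data, C, seed) rather than of one RNG stream. The trade-off is
real: on Iris scaled by the extreme max-SC factors, k-means has three local
minima (inertias 275.81 / 276.73 / 277.82 scoring ARI_fnc 0.886 / 0.835 /
0.922 against the species), and restart selection deterministically returns
the lowest-inertia partition, ARI_fnc 0.886 — a *better* k-means solution
that is a *worse* match to the species labels than a lucky single run can
produce. The package reports what the stabilized procedure computes.

Evaluation indices:

* **ARI_fnc** = (RI − E_fnc[RI]) / (1 − E_fnc[RI]) with
  E_fnc[RI] = UV + (1−U)(1−V), U = S(n−1, C)/S(n, C) and V the reference
  co-clustering rate. Stirling numbers are exact Python integers from the
  standard recurrence (O(nC), no overflow); U switches to a signed
  log-sum-exp inclusion–exclusion evaluation beyond n = 5000. Verified
  against exhaustive enumeration of all C-block partitions for n ≤ 8.
* **AMI_max** = (MI − E[MI]) / (max{H(R), H(O)} − E[MI]). No fnc-null
  expectation of MI is known, so E[MI] uses the exact fixed-marginals
  (hypergeometric) permutation model, computed cell-wise with
  log-factorials; verified against exhaustive permutation enumeration for
  n ≤ 6 and against an independent library implementation. Entropies use
  natural logs; the index is base-invariant.

Both indices are ≤ 1 with equality exactly on identical partitions, and can
be slightly negative when the observed agreement falls below its null
expectation.

## Synthetic data

`MixtureSpec`/`make_mixture` draw Gaussian clusters with per-cluster means
and scales, optionally appending pure-noise dimensions and injecting exact
duplicate rows. The default fixture — three unit-scale clusters of 40
samples at (0,0), (4,0), (0,4) plus one noise dimension of scale 100 —
emulates the failure mode the method targets: 1/σ scaling promotes the
noise dimension to unit variance alongside the signal dimensions, while
Problem-P trials can suppress it. The module's core self-test asserts that
the best trial matches or beats 1/σ scaling in ≥ 90% of generator seeds.

What the generator does **not** emulate: non-Gaussian cluster shapes,
correlated dimensions, heavy tails, label noise, and missing data. Passing
the synthetic tests therefore demonstrates correct mechanics and the
intended noise-suppression behaviour, not performance on arbitrary real
data.

Benchmark preparation utilities mirror the standard pipeline: the corrected
Iris table (two printed measurement corrections, verified before applying),
DR3 reduction (centered, unscaled PCA, first three components, deterministic
largest-loading-positive sign convention), the first-10-columns truncation
for the 30-dimension diagnostic table, and a plain per-column mean imputer
(with logged 1e-9 jitter should imputation ever create a duplicate row).
The mean imputer is deliberately simple; results that depend on synthesized
missing values are treated as qualitative context only.

## Problem sizes and numerical choices

Packaged runs use the full 1000-trial protocol on Iris (a trial costs ~4 ms
with the analytic gradient; the sweep including per-trial k-means runs in
well under a minute) and 20 seeds × 30 trials on the synthetic fixture.
Degenerate inputs fail fast with diagnostic errors: constant columns,
fewer than two unique rows, zero pair distances, undefined (denominator-zero)
indices. Tolerances: sphere residual 1e-6 for convergence accounting,
1e-8 relative for the directional-derivative identity, 1e-10 relative for
the pair-sum/closed-form identities.

## Limitations

* Pair storage is dense over the n(n−1)/2 unique-row pairs (O(n²d) memory
  and per-evaluation time): the intended regime is thousands of samples, not
  millions.
* Problem P encodes only first-order stationarity; second-order conditions
  are not checked, and the multi-start protocol offers no global guarantee.
* The selected α ultimately requires domain scrutiny: on data where most
  trials cluster poorly, the trial consensus can point away from the best
  candidate, so per-trial index distributions (and distance histograms via
  `distance_histogram`) are first-class outputs rather than internals.
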