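# shapescale

Per-dimension scaling factors for distance-based clustering, chosen by the
*shape complexity* of the data rather than by per-dimension statistics alone.

## The problem

Before running k-means (or any clustering method built on Euclidean
distances), each dimension of an *n* × *d* data matrix *X* is usually divided
by its sample standard deviation σ<sub>k</sub>. That default can hurt: it
promotes high-variance pure-noise dimensions to the same footing as
informative ones and flattens dimensions that carry the cluster structure.
`shapescale` searches for an extra positive factor α<sub>k</sub> per
dimension — the data are scaled by α<sub>k</sub>/σ<sub>k</sub> — using the
shape complexity of the scaled point cloud:

```
SC = g · h,    g = ( Σ_{i<j} r_ij² )^½,    h = Σ_{i<j} r_ij⁻¹,
r_ij² = Σ_k α_k² ρ_ijk²,    ρ_ijk = (X_ik − X_jk) / σ_k .
```

Growing any distance increases g (fastest for the largest r<sub>ij</sub>)
and decreases h (fastest for the smallest r<sub>ij</sub>), so SC embodies a
tension whose equilibrium, g′<sub>k</sub>/g = −h′<sub>k</sub>/h for every k,
balances how scaling acts on the large (inter-cluster) and small
(intra-cluster) ends of the distance distribution — the "midrange" distances
most easily confused between the two roles. SC is radially invariant
(SC(tα) = SC(α) for t > 0), so candidate factors are sought on the sphere
Σ<sub>k</sub> α<sub>k</sub>² = d via the constrained program (**Problem P**)

```
minimize  ( Σ_{i<j} r_ij⁻³ N⁻¹ (ρ_ij1² − ρ_ij2²) )²
subject to  Σ_k α_k² = d,   α_k ≥ 10⁻⁵,          N = n_orig (n_orig − 1),
```

solved from many random initial points in [0.5, 1.5]^d. Each converged
trial yields a candidate α; candidates are scored by clustering the scaled
data with restart-stabilized k-means and comparing against a reference
partition with two chance-corrected indices:

* **ARI_fnc** — the Rand index corrected under the fixed-number-of-clusters
  null (the obtained partition is a uniformly random partition into exactly
  C non-empty clusters; the co-clustering probability is the Stirling-number
  ratio S(n−1, C)/S(n, C));
* **AMI_max** — mutual information corrected by the exact hypergeometric
  expected MI and normalized by max{H(R), H(O)}.

A `maximize SC subject to α_k ≥ 10⁻⁵` alternative (`mode="max_sc"`) is also
provided.

## Worked example

```python
from shapescale import ShapeComplexityScaling, TrialConfig, corrected_iris

data, species = corrected_iris()          # 150 x 4, two printed corrections
model = ShapeComplexityScaling(data, reference=species, dataset="iris")
res = model.fit(n_trials=100, seed=7, config=TrialConfig(gradient="analytic"))
print(res.summary())
```

```
Shape-complexity scaling results
========================================
samples (n_orig):      150
unique samples (n):    149
dimensions (d):        4
mode:                  problem_p
trials:                100
converged:             98  (discard fraction 2.00%)
selected alpha:        0.4959  0.6637  1.147  1.413
alpha/sigma factors:   0.5988  1.523  0.6498  1.854
ARI_fnc over trials:   [0.548, 0.886]
AMI_max over trials:   [0.589, 0.862]
```

Reading the output: of 100 Problem-P trials, 98 converged; each converged α
was used to scale the data by α<sub>k</sub>/σ<sub>k</sub>, cluster with
k-means (C = 3, best of 20 restarts) and score against the species labels.
The trials span ARI_fnc 0.548–0.886 — the best trial beats both no scaling
(ARI_fnc 0.728) and plain 1/σ<sub>k</sub> scaling (0.621) on this data, and
its factors shrink the sepal dimensions while amplifying the petal ones.
`res.params` holds the best trial's α, `res.scale()` / `res.cluster()` apply
it, and `res.trials` is the tidy per-trial table.

A command-line interface mirrors the library (`shapescale sc`,
`shapescale trials`, `shapescale evaluate`, `shapescale benchmark`).

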