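# Methods

## Model

Species dynamics `dX/dt = diag(X) f(X)` are analyzed only through their
linearization at a feasible equilibrium `X* > 0`:

    dx/dt = diag(X*) J x = M x,   x(t) = X(t) − X*.

No functional form of `f` is assumed anywhere in the package; every result
concerns the community matrix `M` and its spectrum. Stability is
`−Re(λ₁(M))`, with strict inequality `Re(λ₁) < 0` for the stable verdict —
an exact zero counts as unstable, matching the asymptotic-stability
definition. Eigenvalues are computed with a dense nonsymmetric solver
(`numpy.linalg.eigvals`); at the community sizes this package targets
(S up to a few thousand) a dense solve is exact and fast, so no sparse or
iterative path is provided.

## Set structure

Each of `S` species joins `K` of `G` sets, chosen uniformly **without
replacement** and independently across species. Uniform-without-replacement
is the simplest exchangeable reading of "randomly chosen sets"; choosing
with replacement would give the same expected order for K ≪ G. Under this
scheme the expected number of sets shared by two species is exactly
`H = K²/G` (per-set sharing probability `(K/G)²`, summed over `G` sets),
and the expected size of any set is `S·K/G`. Empty and singleton sets are
legal and simply contribute no interactions.

## Community-matrix construction

For each set `g` and each unordered member pair, an interaction is placed
with probability `C`, **independently across sets**: a pair sharing `h`
sets interacts `Binomial(h, C)` times and the strengths add,
`M_ij = Σ_g M_ij^g`. This multiplicity is the point of the model — it makes
the expected interaction count per pair `T = C·H`, the set-structured
analogue of connectivity. The diagonal is overwritten with `−d` after the
sum (never accumulated per set); abundance scaling `M ← diag(X*) M` is
applied last, so with unit abundances `M_ii = −d` exactly.

Strength pairs `(M_ij^g, M_ji^g)` per interaction type (`X ~ N(0, σ²)`):

| type | forward | backward |
|---|---|---|
| random | `X` | `X'` (independent) |
| exploitative | `±|X|` | `∓|X'|` |
| mutualistic | `+|X|` | `+|X'|` |
| competitive | `−|X|` | `−|X'|` |

For the exploitative type, which side is positive is a fair coin per pair
per set — the only symmetric choice, and the one that reproduces the
cross-moment `E(M_ij M_ji) = −T·(2/π)σ²`. The `mixed` type draws one of the
four types uniformly per placed pair. `d` defaults to 1; only the ratio
`d/σ` enters any criterion, so `d` is a unit choice, not a free parameter.

## Degree-heterogeneous and local-symmetric flavors

`scale_free_within_set` replaces each set's Erdős–Rényi graph with a
Barabási–Albert preferential-attachment graph at connectivity `C`;
`local_symmetric` fixes each set's **average degree** at `k` instead (its
matched unstructured system gets a single global BA graph at average degree
`k`, so the set-structured system's overall average degree ≈ `K·k` exceeds
it). A BA graph on `m` nodes with attachment count `a` has exactly
`a(m−a)` edges, i.e. average degree `2a(m−a)/m`; the naive choice
`a = round(k/2)` therefore undershoots the target by the factor `(1−a/m)`
plus integer-rounding error — up to ~30% for the small sets that arise at
large `G`. The generator instead inverts the quadratic,
`a = (m − √(m²−2km))/2`, and rounds stochastically, making the realized
average degree unbiased for the target (up to the floor of one attachment
per node; sets too small to reach `k` are clamped to `a = m−1`, and sets
with fewer than two members are skipped with a logged notice). Hub
positions are decoupled from species indices by a random relabelling.

## Stability criteria

Per interaction type the criterion is `lhs < d/σ` with

    random        √(S·C·H)
    mutualistic   (S−1)·C·H·√(2/π)
    exploitative  √(S·C·H)·(1 − 2/π)
    competitive   F(C·H) + C·H·√(2/π),
    F(x) = √(S·x·(1 − 2x/π)) · (1 + 2(1−x)/(π − 2x)),  0 ≤ x < π/2.

The unstructured column is the same code path with `H := 1`, so the
reduction identity at `H = 1` is structural, not duplicated arithmetic.
The competitive form is a bulk-edge approximation; it degrades as
`C·H → 0`, so results with `C·H < 0.1` carry a warning field (the 0.1 floor
is this package's choice of where "≪ 1" starts to bite). `F` raises a
domain error at `x ≥ π/2`.

### Moment background (what the criteria rest on)

Under the construction above, exactly:

    E(M_ij)        = ±T·E|X|          (mutualistic/competitive; 0 otherwise)
    Var(M_ij)      = T·σ²             (random, exploitative)
    E(M_ij M_ji)   = −T·(E|X|)²       (exploitative)

with `E|X| = σ√(2/π)`. For the folded (one-signed) types the *second*
moments carry an additional shared-set correlation term: the second
factorial moment of the shared-set count is
`E[h(h−1)] = K²(K−1)²/(G(G−1))`, contributing `E[h(h−1)]·(C·E|X|)²` to
`E(M_ij²)` and to `E(M_ij M_ji)`. The leading-order forms used in the
closed-form criteria drop this `O(T²)` term; at `K=6, G=50, C=0.5` the gap
is ~20% of the variance. The test suite asserts the exact finite-`(K,G)`
moments to Monte-Carlo precision and the leading-order forms where they are
exact. The criteria themselves are unaffected at the accuracy the sweeps
resolve, because the mean (which drives the mutualistic/competitive
outlier eigenvalue) is exact and the bulk terms enter under a square root.

## Experiments

**ΔStability sweeps.** One sweep point builds `n` independent
(set-structured, unstructured) pairs sharing scalar parameters, and records
mean and sd of the stability difference. Pairs share parameters, not draws;
a common-random-numbers option (same seeds for both builders) exists for
variance reduction but is off by default so the default estimator is the
plain two-ensemble contrast. The critical ratio is the linear interpolation
of the zero crossing of mean ΔStability against `K²/G`; no smoothing is
applied — noise near the crossing is handled by replicate count — and when
several crossings exist the one nearest 1 is reported (all are logged).

**Perturbation dynamics.** `x(0)` has entries uniform in
`±(scale·X_i*)`; the linear system is propagated exactly with the matrix
exponential of `M·Δt` on a fixed grid, avoiding ODE-tolerance choices.
"Converged" means the final `‖x‖` fell below `10⁻²` of the initial one;
trajectories that overflow are truncated at the overflow point and flagged
rather than raised. Defaults (`perturbation_scale=0.1`, `horizon=50`,
`n_steps=200`) are this package's choices — nothing in the model fixes
them — and paired systems given the same seed receive bit-identical
perturbations.

**Stable proportions.** The fraction of draws with `Re(λ₁) < 0` per system
kind, over matched ensembles.

## Problem sizes and reproducibility

The headline sweeps use `S=200, K=6, σ=0.05, d=1` with `G` from 10 to 100
and 50 replicates per point — enough for the crossing estimate's
Monte-Carlo error to be well inside ±0.1. The acceptance script uses a
step-5 grid of `G` (19 points); the test suite exercises a step-2 grid for
the homogeneous flavor. All randomness flows through
`numpy.random.Generator`; builders spawn one child stream per set and
sweeps one per replicate, so results are independent of evaluation order.
The CLI derives per-stage seeds from one master seed by stable hashing of
stage names and records them in a JSON manifest; re-running a manifest
reproduces every stochastic output bit-identically.

## What the generator does and does not emulate

The synthetic ensembles realize the model's own assumptions: exchangeable
random memberships, independent interaction placement, i.i.d. strength
magnitudes, constant self-regulation. Real communities violate most of
these — memberships correlate with traits, strengths correlate with
degree, self-regulation varies across species — so passing tests validate
the theory *within its model class*, not its fit to any empirical system.
Equilibrium abundances can be made heterogeneous (uniform on `[0.75, 1.25]`
by default, log-normal and floor-truncated half-normal also available), but
no empirical-network import or parameter estimation from data is provided.

## Known limitations

- The competitive criterion is a bulk-edge approximation with a limited
  validity regime (`C·H` neither ≫ 1 nor ≪ 1); the warning field marks the
  low end.
- Preferential-attachment targets below average degree 2 are clamped to
  tree attachment (`a = 1`), the sparsest BA graph.
- Dense eigensolves bound practical community sizes to a few thousand
  species.
- The dynamics are linear by construction; trajectories far from
  equilibrium are illustrative, not ecological predictions.
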