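# setstab

Stability analysis of ecological (and other networked) communities whose
species are organized into **overlapping sets** — a hypergraph structure in
which higher-order interactions arise because two species can meet in more
than one shared set.

## The model

Near a feasible equilibrium `X* > 0`, community dynamics linearize to

    dx/dt = diag(X*) J x = M x,

and the community matrix `M` decides stability through the largest real part
of its spectrum: the system is asymptotically stable iff `Re(λ₁) < 0`, and
`−Re(λ₁)` serves as a stability score.

In a **set-structured** community of `S` species, each species belongs to
`K` of `G` sets chosen uniformly at random. Within every set, each member
pair interacts with probability `C`, receiving a bivariate strength draw
`(M_ij^g, M_ji^g)` built from `N(0, σ²)` — unconstrained (*random*), `+/−`
(*exploitative*), `+/+` (*mutualistic*), or `−/−` (*competitive*) — and the
community matrix sums over sets, `M_ij = Σ_g M_ij^g`, with diagonal `−d`.
The matched **unstructured** system places one interaction per pair with
the same `C`.

Two species share `H = K²/G` sets on average (the *order*), so the expected
number of interaction events per pair is `T = C·H`. Closed-form criteria of
the form `lhs(S, C, H) < d/σ` hold per interaction type (e.g. `√(SCH) < d/σ`
for random interactions; the unstructured criteria are the same formulas at
`H = 1`). They imply a simple stabilization rule: relative to its
unstructured counterpart, a set-structured community is **more stable iff
K²/G < 1** — for competitive interactions the critical ratio sits strictly
below 1. `setstab` generates these ensembles (including degree-heterogeneous
variants with a preferential-attachment graph per set, local-symmetric
variants with fixed per-set average degree `k`, and non-unit equilibrium
abundances), evaluates the criteria, and runs the Monte-Carlo sweeps,
perturbation dynamics, and stable-proportion experiments that locate the
critical ratio.

## Worked example

```python
import numpy as np
from setstab import (
    EnsembleConfig, sample_membership, build_set_structured,
    build_unstructured, leading_real_part, criterion, sweep_over_G,
)

cfg = EnsembleConfig(n_species=200, connectivity=0.5, strength_sd=0.05,
                     n_sets=100, sets_per_species=6)          # H = 0.36
membership = sample_membership(200, 100, 6, seed=0)
m_set = build_set_structured(cfg, membership, seed=1)
m_free = build_unstructured(cfg, seed=2)
print(f"set-structured stability  {leading_real_part(m_set).stability:.3f}")
print(f"unstructured  stability  {leading_real_part(m_free).stability:.3f}")
print(f"criterion lhs {criterion('random', 200, 0.5, 0.36, 1.0, 0.05).lhs:.2f}"
      f" vs d/sigma {1.0/0.05:.0f}")

sweep = sweep_over_G(cfg, range(10, 101, 10), n_replicates=20, seed=3)
print(f"critical K^2/G  {sweep.critical_ratio:.3f}")
```

prints

```
set-structured stability  0.719
unstructured  stability  0.480
criterion lhs 6.00 vs d/sigma 20
critical K^2/G  0.970
```

At `H = 0.36` the set-structured community is markedly more stable than its
unstructured match (both predicted stable: `√(SCH) = 6 < 20`), and the sweep
over `G` locates the stabilization threshold at `K²/G ≈ 1`.

The same machinery is exposed on the command line:

```sh
setstab criteria --type random --species 100 --connectivity 0.5 \
        --sets 50 --sets-per-species 6 --sigma 0.05
setstab sweep --species 200 --sets-per-species 6 --connectivity 0.5 \
        --sigma 0.05 --g-min 10 --g-max 100 --g-step 10 \
        --replicates 20 --seed 3 --out sweep.csv
```

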