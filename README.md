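# htmarginal

Low-rank computation of **time-marginal distributions** of continuous-time
Markov chains with separable transition rates — stochastic automata networks
(SANs) and, in particular, **Mutual Hazard Networks** (MHNs) for tumor
progression.

## The problem

An MHN models a tumor genotype as d binary events that occur irreversibly,
with rates coupled through a nonnegative parameter matrix Θ ∈ R^{d×d}:
the rate of event i in state x is Θ_ii · ∏_{j: x_j=1} Θ_ij.  Because the age
of a tumor at observation is unknown, the observable distribution over the
2^d genotypes is the transient distribution integrated over an Exp(1)
observation time — the *time-marginal distribution* — which solves

    (Id − Q) p = p(0),      p(0) = e_0,

with Q the column generator.  The state space grows as 2^d, so this system
cannot even be *stored* densely beyond d ≈ 25.

`htmarginal` exploits the separable rate structure: Q is a sum of d Kronecker
products (CP format), and p is computed in the **hierarchical Tucker (HT)**
tensor format by a normalized truncated uniformization iteration

    p^(k) ∝ Σ_{m≤k} (γ/(1+γ))^m P^m p(0),      P = Id + Q/γ,

renormalized by its total mass every step so the result sums to one exactly,
with SVD-based rank truncation (error bound
‖x − trunc(x)‖² ≤ Σ_t Σ_{m>r_t} σ_{t,m}²) keeping storage and work linear in
d.  The iteration converges linearly with rate γ/(1+γ).

The package provides:

* `models` — MHN/SAN types, CP generators, uniformization bound γ;
* `tree`, `httensor` — dimension trees and the full HT engine
  (conversion, arithmetic, orthogonalization, singular values, truncation);
* `solver` — dense reference solvers, exact uniformization partial sums,
  and the low-rank iteration;
* `synthetic` — block-structured synthetic Θ (strict / neighbor /
  neighbor-plus-random designs);
* `diagnostics` — effective rank, storage accounting, KL divergence,
  spectrum / rank / convergence studies;
* `io`, `cli` — CSV/TSV/JSON parameter I/O, HDF5 tensors, and a thin
  `marginal` command-line tool.

## Worked example

```python
import numpy as np
from htmarginal import (
    BlockDesign, sample_theta, mhn_to_san, build_generator_cp, gamma_bound,
    balanced_tree, ht_unit, SolverConfig, solve_marginal_lowrank,
    ht_to_dense, dense_marginal, generator_dense, InitialState, effective_rank,
)

design = BlockDesign(d=8, n_blocks=2, kind="B1", seed=7)
theta = sample_theta(design)                  # 8x8 block parameter matrix
spec = mhn_to_san(theta)
q = build_generator_cp(spec)                  # CP rank 8 generator
gamma = gamma_bound(spec)
tree = balanced_tree(8)
p0 = ht_unit(tree, spec.sizes, (0,) * 8)

res = solve_marginal_lowrank(q, p0, SolverConfig(gamma=gamma, tol=1e-4))
print(f"gamma={gamma:.3f} iterations={res.iterations} "
      f"residual={res.final_residual:.2e} mass={res.final_mass:.12f} "
      f"r_eff={effective_rank(res.p)}")

p_ref = dense_marginal(generator_dense(spec), InitialState.all_zero(8).dense(spec.sizes))
err = np.linalg.norm(ht_to_dense(res.p).ravel() - p_ref) / np.linalg.norm(p_ref)
print(f"relative distance to dense solve: {err:.2e}")
```

prints

```
gamma=9.093 iterations=91 residual=9.39e-05 mass=1.000000000000 r_eff=4
relative distance to dense solve: 4.13e-04
```

γ is the uniformization rate (here ≈ 9.1, so the iteration contracts with
rate γ/(1+γ) ≈ 0.90); the solver stops once the relative residual of
(Id − Q)p = p(0) drops below 1e−4; the mass is exactly 1 by construction;
the effective rank 4 says the 256-state distribution is stored at the cost
of a constant-rank-4 HT tensor; and the low-rank answer agrees with the
dense solve to ~4e−4.

More narrative scripts live in `examples/` (one per capability: building
generators, HT arithmetic and truncation, exact partial sums and bounds,
synthetic designs, spectra and tree ordering, rank and convergence studies).

The same solve from a shell:

```sh
marginal gen-theta --type B1 --d 8 --blocks 2 --seed 7 --out theta.csv
marginal solve --theta theta.csv --tol 1e-4 --out run/
```

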