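# Methods

## Problem

A continuous-time Markov chain over a product state space
S = S_1 × … × S_d describes d interacting processes ("automata"); in tumor
progression each automaton is a binary genomic event that switches
irreversibly from absent to present.  Because the observation time of a tumor
is unknown, the quantity of interest is not a transient distribution p(t) but
the *time-marginal* distribution, the transient distribution integrated
against an Exp(1) observation time.  It is the unique solution of the linear
system

    (Id − Q) p = p(0),

where Q is the column generator (Q[y,x] ≥ 0 the rate of x → y, columns
summing to zero) and p(0) = e_z a unit tensor.  The state space has
∏ n_i (= 2^d for binary events) states, so dense solves stop being feasible
around d ≈ 25; everything here is about computing p without ever enumerating
S.

## Separable rates and the CP generator

We assume one local transition at a time and separable rates: a transition
t_i = (x_i → y_i) in automaton i has rate ∏_j Θ(t_i, x_j), each factor
depending only on the local state of one automaton.  The generator is then a
sum of Kronecker products with one term per local transition (CP format,
representation rank Σ_i |T_i|).  For a Mutual Hazard Network (MHN, binary
automata, single transition 0 → 1 per event, inactive events neutral) the
parameterization collapses to a d×d matrix Θ: diagonal entries are baseline
rates, off-diagonal Θ[i,j] the multiplicative effect of an active event j on
event i, and the CP rank equals d.

Synchronized transitions that change several automata at once are out of
scope, as is the estimation of Θ from data.

## Uniformization and the normalized iteration

With γ ≥ max_x |Q[x,x]|, P = Id + Q/γ is column-stochastic and

    p = 1/(1+γ) Σ_{m≥0} (γ/(1+γ))^m P^m p(0),

a convergent Neumann series.  The partial sums p̃^(k) approximate p from
below entrywise; their total masses have the closed form
((1+γ)^{k+1} − γ^{k+1})/(1+γ)^k, which the exact normalization α_k inverts so
every normalized iterate sums to one.  The normalized iterates converge
linearly with rate γ/(1+γ) and constant c = ‖p(0)/(1+γ) − p‖ + γ‖p‖.  A
companion upper approximation adds the missing mass (γ/(1+γ))^{k+1} as a
constant tensor, sandwiching p entrywise; it converges more slowly in the
residual and is provided for diagnostics only.

γ is computed from the parameters in O(d² n² T) without enumerating S; for an
MHN, γ = Σ_i ∏_j max(1, Θ[i,j]).  This can substantially overestimate the
true diagonal maximum, which slows convergence (the rate γ/(1+γ) approaches
one as γ grows); tighter low-rank bounds are an open problem.

In the truncated low-rank solver the exact α_k scaling is replaced by
dividing each iterate by its computed total mass ⟨1, p^(k)⟩, so the result
sums to one (to 1e−12) regardless of truncation.  The iteration stops when
the relative residual ‖(Id − Q)p − p(0)‖/‖p(0)‖ falls below `tol` (default
1e−4) or after `max_iter` (default 10 000) iterations; stagnating residuals
trigger a warning recommending a smaller truncation tolerance.

## Hierarchical Tucker engine

Iterates are stored in the hierarchical Tucker (HT) format over a binary
dimension tree: leaf frames (n_i × r_i) and per-inner-node transfer tensors
(r_left × r_right × r_node, root rank 1).  Trees are balanced, splitting
⌈m/2⌉ / ⌊m/2⌋ in leaf order; the leaf order is the design parameter that
matters, since the rank at node t is the matrix rank of the matricization
p^(t).  Grouping strongly interacting automata in the same subtree keeps
those ranks low; interleaving blocks across the root demonstrably slows the
root-level singular-value decay.

Implemented operations: CP→HT conversion (node ranks bounded by the CP
rank), evaluation (full or single entry), addition (ranks add), scaling,
inner product, operator application (per-term leaf-frame multiplication),
leaves-to-root orthogonalization (QR), reduced Gramians, per-node singular
values, and truncation.

Truncation orthogonalizes, eigendecomposes each non-root Gramian, and keeps
the smallest rank whose discarded tail fits a per-node share of the budget
(ε‖x‖)² split uniformly over the 2d−2 non-root nodes, so the total error
satisfies the computable bound ‖x − trunc(x)‖² ≤ Σ_t Σ_{m>r_t} σ_{t,m}² ≤
(ε‖x‖)².  Ties in singular values keep the lower index; ranks never drop
below 1; an optional per-node cap takes precedence over the error budget.
Matricization ordering (complement modes ascending, first index fastest) is
fixed; only consistency matters.

Operator application defaults to *incremental* mode: terms are applied one
at a time and the running sum re-truncated after each addition, keeping
intermediate ranks near (working rank + term rank) instead of the product
r_op · r_x of the exact (batch) application.  Batch mode is retained as the
oracle path.

### Truncation budget inside the solver

Where truncation sits in the iteration is a genuine design choice.  Two
placements were compared against exactly computed solutions (sparse solves
up to d = 20):

* truncating the accumulated partial sum with a *fixed* relative budget ε
  every iteration discards ~ε‖p‖ mass hundreds of times and erases the small
  singular values ε is meant to preserve — the final effective rank falls
  measurably below that of the exact solution truncated once at ε;
* bounding the accumulation-truncation error by ε·‖increment‖ (the term just
  added) keeps the aggregate truncation noise at the level of a single
  ε-truncation of the limit and reproduces the exact solution's rank
  structure at the same iteration count.

The solver therefore truncates the partial sum with budget
ε_trunc · min(1, ‖u^(k)‖/‖s^(k)‖).  This is consistent with the general
requirement that a truncated fixed-point iteration converges when the
truncation error is small relative to the iteration's own progress.  Term
and intra-application truncations use the plain relative ε_trunc (splitting
that budget across the per-term truncations had no measurable effect).

On output the accumulated sum is truncated once more at the full ε_trunc and
renormalized: the returned tensor is an ε_trunc-accurate representation of
the limit rather than one padded with sub-budget noise directions, matching
the output semantics of the fixed-budget scheme (whose last step is exactly
such a truncation) while retaining the in-iteration information protection.

No non-negativity projection is applied: truncation can leave entries of
order −1e−9, which is deliberate (error control, not positivity, is
enforced; the KL diagnostic's cutoff handles them).

## Dense reference solvers

Two oracles validate everything at small d: the direct solve of
(Id − Q)p = p(0), and, for progressive chains, the splitting
Id − Q = D + L with D diagonal and L strictly lower triangular under the
order by number of active events.  L adds one event per application, so
L^(d+1) = 0 and the splitting series has exactly d + 1 terms (a chain can
accumulate all d events starting from none); with d + 1 terms it agrees with
the direct solve to 1e−10.

## Synthetic parameters

The generator emulates pathway structure: blocks of automata with direct
mutual effects.  Within-block entries (diagonal included) have natural-log
values drawn Normal(0, 0.25); all other entries are exactly 1 (neutral).
Three designs: B1 strict blocks; B2 additionally 4 uniformly drawn directed
effects per pair of index-adjacent blocks, log-Normal(0, 0.125); B3
additionally 8 such effects between arbitrary distinct blocks.  Sampled
cross-block pairs are directed, drawn without replacement (an already
non-neutral pair is re-drawn); symmetric placement is a documented
alternative not used here.  Sampling is integer-seeded and reproducible.

What this emulates — modular, weakly coupled event networks with
log-normally dispersed effect sizes — and what it does not: real tumor data
has effect magnitudes estimated with error, non-modular hub structure, and
many exactly-neutral within-block pairs.  Tests passing on these designs
show the solver handles the rank structure such modularity induces, not that
real networks have low rank (the pipeline accepts any user-supplied Θ).

## Diagnostics

* **Effective rank**: the smallest integer r such that a constant-rank-r
  representation on the same tree (leaves n_i·r, non-root inner nodes r³,
  root r²) costs at least as much as the actual one — a single number
  summarizing a rank tuple.
* **Storage counts**: HT storage vs the dense ∏ n_i (2^d for an MHN).
* **KL divergence** Σ p_ref log(p_ref/p_approx) (natural log), with
  reference entries ≤ ε_cutoff (default 1e−8) dropped via 0·log 0 = 0; a
  surviving nonpositive approximate entry raises an error telling the user
  to increase the cutoff.  No renormalization is applied.
* **Spectrum study**: dense solves per sample, per-node singular values
  averaged arithmetically.  "Numerically zero" defaults to the standard
  numerical-rank threshold σ_1 · max(m, n) · eps; a fixed relative threshold
  like 1e−12 miscounts, because the spectra decay through genuinely tiny but
  nonzero values (~1e−15 relative) before hitting the machine-noise floor.
* **Rank and convergence studies**: mean effective ranks across designs /
  tolerances, and residual-vs-iteration curves with least-squares log10
  slopes.

## Numerical choices and degenerate inputs

* γ = 0 (all transitions disabled) is rejected; zero baselines for
  individual transitions are allowed.
* Norms are computed via orthogonalization (root norm), which is backward
  stable; inner-product-based norms lose half the digits to cancellation for
  near-zero tensors such as residuals.
* Masses ⟨1, p⟩ ≤ 0 after truncation raise a numerical-breakdown error
  advising a smaller ε_trunc.
* d = 1 is supported throughout (the tree degenerates to a single node of
  rank 1).
* Residual evaluation costs one operator application; the evaluation stride
  is configurable and the studies use strides of 5–25.

## Problem sizes used in tests and experiments

Dense-oracle validation uses d ≤ 10 (≤ 1024 states); exact-solution rank
studies used sparse solves up to d = 20 during development.  The shipped
studies run the low-rank solver up to d = 32 with 10 samples (effective-rank
means) and 5 samples per configuration for plateau comparisons, with
tol = 1e−2 for rank studies (ranks are insensitive to tol below ~1e−1) and
tol = 1e−4 elsewhere; spectra average 100 dense samples at d = 8.  These
sizes keep each study in the minutes range on one CPU while matching the
regimes where the studied effects (block structure, tree ordering, rank
plateaus) are expressed.

## Known limitations

* The computed approximation can have small negative entries (see above).
* γ from the parameter bound can be loose for strongly dispersed Θ,
  inflating iteration counts linearly in d.
* The dimension tree is user-chosen; no automatic tree adaptation is
  provided, and a bad leaf order (splitting blocks across the root) can
  raise ranks substantially.
* KL evaluation requires materializing the dense tensor and is limited to
  small d.
* The general SAN path supports only single-automaton (unsynchronized)
  transitions.
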