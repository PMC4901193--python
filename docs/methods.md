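# Methods

This note records the modelling assumptions, numerical choices, and known
limitations behind `tvcoupling`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The object of inference is the instantaneous coupling matrix `C(t)` of

    dx_i/dt = f(x_i) + Σ_j c_ij(t) Γ x_j,

under four standing assumptions: (i) the node dynamics `f` and the inner
coupling matrix `Γ` are known; (ii) off-diagonal couplings are nonnegative
and each row of `C(t)` sums to zero (diagonal entries are *defined* as
negative off-diagonal row sums and are never free parameters); (iii) each
row of `C(t) ⊗ Γ` is sparse; (iv) the observer can sample `K` independent
trajectories at the identification time `t` and at a nearby time `t*`.
Each time point is solved independently — no smoothness of `t ↦ C(t)` is
assumed or exploited, which is what makes *continuously varying* weights
identifiable from two-snapshot data.

## Observation model

The derivative is replaced by a difference quotient. Two schemes exist:

* **forward** (default): `t* = t + dt`, truncation error `(dt/2)·Ẍ`;
* **central**: quotient over `(t − dt, t + dt)`, truncation `(dt²/6)·X⃛`.

For noiseless data the offset is `dt = 1e-6` (the same value used to
generate the reference data) and forward differences suffice: the induced
target error is far below what the recovery tolerances resolve.

For noisy data the offset is a bias–variance tradeoff: uniform state noise
of standard deviation σ enters the central quotient with magnitude
`√2·σ/(2dt)` while truncation grows as `(dt²/6)·M₃`, where `M₃` is the
third-derivative scale of the states. Balancing the two gives

    dt* = (3·√2·σ / M₃)^(1/3).

`M₃ = 3e4` is the package constant for Lorenz-type fixtures; it is the RMS
third derivative measured by finite-differencing a clean fine-step
trajectory of the 6-node fixture over the identification window (the
acceptance-relevant regime). `suggest_snapshot_offset` applies the rule;
the noisy fixtures use it with central differences. Both members of every
snapshot pair are independently corrupted — the identifier never sees
clean states, and `F` is evaluated at the noisy `X(t)`.

The per-target noise scale passed to the discrepancy principle is
`2σ/(2dt)`: one factor √2 for the difference of two draws, one for the
truncation bias that the balanced offset leaves at the same scale as the
noise. The (smaller) perturbation of `F(X)` is not modelled; the
discrepancy factor τ = 1.1 absorbs part of it.

## Simulator

Classical fixed-step RK4 (the integrator whose order-4 convergence the
suite verifies). The full `K`-trajectory ensemble advances as one batched
array; all node dynamics broadcast over leading axes. The integrator step
(`h = 1e-3` for Lorenz fixtures, `1e-2` for consensus) is separate from
the snapshot offset: recording times are hit exactly by shortening the
last step of each segment, and the `t ± dt` snapshot states are produced
by single fine RK4 steps from `X(t)`, so an experiment with `dt = 1e-6`
does not require a `1e-6` global step. Trajectories that leave `|x| ≤ 1e6`
are flagged as diverged (their records become NaN) and are excluded from
snapshot extraction; the batch continues.

Initial conditions are i.i.d. uniform per component: `[-5, 5]` for Lorenz
nodes (keeps the transient on-scale with the attractor without
divergence), `[-1, 1]` for consensus agents. Ensembles are pure functions
of `(system, K, t_end, h, init_box, seed)`.

## Sparse recovery

Both problems are solved in scaled-dual ADMM form with an auxiliary
variable carrying the ℓ¹ term. All `nN` rows at a time point share one
design matrix, so the factorization (Cholesky of `A Aᵀ`, or of
`AᵀA + ρI`) is computed once and all right-hand sides are updated as one
matrix — the key performance decision for time sweeps.

**Basis pursuit.** x-update projects onto `{Ax = y}` (the returned iterate
is therefore always feasible); z-update is soft thresholding at `1/ρ`;
ρ = 1 with over-relaxation 1.5 (an optional residual-balancing ρ
adaptation exists but is off by default, favouring reproducibility).
Stopping combines three routes:

1. the usual primal/dual residual rule with tolerances 1e-6 absolute /
   1e-4 relative. Tighter defaults are counterproductive here: on
   difference-quotient data no exactly sparse solution fits, so the
   distance between the feasible iterate and its sparse shadow stalls at
   the data's deviation-from-sparsity (≈ the `O(dt)` model error in
   normalized coordinates) and tolerances below that floor never trigger
   while the solution has long stopped improving. Callers can pass any
   tighter `ADMMOptions`; the solver cross-check tests do.
2. an **exact-optimality certificate**, checked on a geometric iteration
   schedule: the scaled dual tracks an ℓ¹ subgradient; projecting it into
   `range(Aᵀ)` proposes an active set, the least-squares "polish" on that
   set gives a candidate, and the min-norm dual ν solving
   `A_Sᵀ ν = sign(x_S)` certifies it when `‖Aᵀν‖_∞ ≤ 1`. A certified
   column is a provable ℓ¹ minimizer; exactly-sparse consistent systems
   terminate this way within tens of iterations.
3. `max_iter = 5000`: unconverged rows are flagged (never silently
   dropped) and the best feasible iterate is returned.

**Regularized problem.** `min ½‖Ax − y_δ‖² + α‖x‖₁` — the quadratic
data-fit plus ℓ¹ form, the canonical Tikhonov-type relaxation of the
equality-constrained problem (alternative weightings reduce to rescaling
α). α comes from the Morozov discrepancy principle: the largest α on a
geometric grid whose solution keeps `‖Ax − y‖ ≤ τ·δ·√m` (τ = 1.1) —
regularize as hard as the noise allows, no harder. The x-update is
α-independent, so per-row α values share one factorization. The final
estimate is **selected by ℓ¹, valued by least squares**: the shrunk
solution declares the support (its bias keeps spurious entries small) and
an unpenalised refit on that support removes the shrinkage bias from the
retained coefficients.

`l1_oracle` (linear programming via HiGHS on the split-variable
formulation) is an independent reference used only in tests.

## Reconstruction and diagnostics

Rows are rescaled through the stored column norms, stacked into `M̂_t`,
and collapsed blockwise: `ĉ_ij = ⟨B_ij, Γ⟩ / ⟨Γ, Γ⟩`, exact for true
Kronecker products and linearly stable under perturbation. Diagonals are
then re-derived from the row-sum convention (so every returned estimate
has machine-zero row sums), and edges are declared by `|ĉ_ij| > τ`
(default τ = 0.05; τ = 0 preserves raw estimates).

When `Γ` is diagonal, row `(i, r)` of `C ⊗ Γ` is supported on the `N`
component-`r` columns only; the pipeline can solve these reduced
`N`-column systems instead (`decouple=True`). The default remains the
full `nN`-column formulation; the noisy 6-node fixture enables the
reduced form because with `K = 11` the support-selection variance of the
full 18-column problem dominates the error budget, while the reduced
problem is selection-free in its known structure.

Each estimate carries a `reliable` flag:
`(cond(A_norm) < 1e6) ∧ (all rows converged) ∧ (relative residual < 1e-4,
noiseless solvers only)`. The condition number and a synchronization
index (maximum pairwise distance between node states, maximized over the
observed trajectories) are computed *before* solving, so ill-posedness
near synchronization is detectable a priori; an unsolvable time point
(rank collapse) still yields an estimate object whose diagnostics explain
the failure, and sweeps continue past it.

## Fixtures: what they emulate, and what passing them shows

* **fifty-node** — ring of 50 Lorenz oscillators, degree 4, rewired with
  probability 0.5 (seeded W–S draw; the two designated time-varying edges
  are pinned through rewiring so the recipe is well-posed for every
  seed); `c13 = c31 = |sin t|`, `c24 = c42 = ln(1+t)`, other edges 1;
  `K = 100` noiseless pairs at `dt = 1e-6`; identification at
  t ∈ {0.5, 1, 1.5, 2}.
* **six-node** — directed, 8 edges in two 3-node clusters, weights chosen
  below the full-state coupling synchronization threshold; `K = 11`
  (m = 12 rows, 18 unknowns). Identification times sit in the early
  transient (t ≤ 0.2): with this few observations the ℓ¹ geometry needs
  heterogeneous states, and once trajectories collapse onto the
  attractor, the all-positive, mutually correlated z-columns defeat
  sparse recovery (the LP oracle confirms the true row then stops being
  the ℓ¹ minimizer). This is a genuine identifiability boundary of the
  method, not a solver artifact.
* **six-node noisy** — same network, central differences, bias-variance
  offset, regularized solver, reduced per-component systems; evaluated at
  t = 0.2, the earliest time where every true weight clears the support
  threshold by a multiple of the expected error.
* **consensus** — `f ≡ 0`, one-dimensional agents on W–S(N, 8, 0.4); the
  full-scale version of this experiment (50000 agents, 10000
  trajectories) is a cluster job, so the package ships desk defaults
  N = 200, K = 400 (then m > N and the noiseless problem is solved by
  least squares); scaling up is a matter of the config's `N` and `K`.
* **sync** — a 60-agent consensus variant with edge weights 0.4 and
  `K = 45 < N`; consensus contracts to the state average at rate λ₂, so
  the sweep provably reaches synchronization. Early times are recovered
  reliably; by t ≥ 18 the synchronization index is below 1e-6 and the
  design-matrix condition number exceeds 1e6.

The generator produces exactly the data the method assumes: ensembles of
the stated model with i.i.d. uniform initial conditions and (optionally)
i.i.d. uniform observation noise. It does not emulate process noise,
unknown or mismatched node dynamics, unknown `Γ`, irregular sampling, or
missing nodes — so passing tests demonstrates correctness of the
method under its own assumptions, not robustness to model error.

## Problem sizes and determinism

The test suite and the acceptance script run the fixtures at their native
sizes (the 50-node, K = 100 experiment included; only the 50000-agent
consensus run is represented by its scaled configuration). A full
acceptance run is about half a minute on one CPU. Every random draw —
graphs, initial conditions, noise, solver test instances — flows from
explicit integer seeds; identical inputs give bit-identical ensembles and
estimates.

## Known limitations

* ℓ¹ exact recovery has an intrinsic phase boundary. At very small sizes
  it is noticeably below 1: for 8×20 Gaussian systems with 2-sparse
  planted vectors, the LP oracle certifies that roughly a fifth of random
  instances have a strictly smaller-ℓ¹ feasible point than the planted
  one, so no correct basis-pursuit solver recovers the plant there. The
  solver is validated by objective agreement with the independent oracle
  and by exact recovery at more generous measurement ratios (m = 8k).
* The `reliable` flag is conservative (a stalled solver row can flag an
  accurate estimate) and not complete: an ℓ¹ identifiability failure with
  a well-conditioned design matrix — as in the 6-node fixture past its
  transient window — is not detectable from the diagnostics alone.
* Weak edges near the support threshold are undecidable under strong
  noise; the noisy fixtures evaluate at times where true weights clear τ
  by a margin.
* Joint estimation of `Γ`, unknown `f`, stochastic dynamics, and
  smoothing of `Ĉ(t)` across time are out of scope.
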