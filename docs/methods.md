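# Methods

## Model structure

A Kv channel is modeled as four independent alpha subunits; the channel
conducts only in the unique state where every subunit is open and none is
inactive. Because subunits of a type are interchangeable, the Markov state
records counts, not identities. Three families are covered, each with at
most two subunit types (one inactivating + one non-inactivating):

* **Plain homomer** (no inactivating subunits): states `P0..P4` count open
  subunits; the classic five-state activation chain whose open probability
  is exactly the Hodgkin–Huxley form `O = q^4`.
* **N-type family** (n = 1..4 inactivating subunits): states `(i, j)` with
  `i ≤ n` open inactivating and `j ≤ 4−n` open plain subunits, plus a
  single pore-blocked state `I`. Inactivation is occlusion of the open
  pore by any one of the n tethered N-terminal balls, so `I` is reachable
  only from the conducting state, at rate `n·aI`; unblocking is `bI`
  regardless of n (one ball is bound at a time). Size: `(n+1)(5−n)+1`.
* **C-type family** (m = 1..4): a C-type subunit has closed → open →
  inactive transitions of its own (`a1/b1` and `aI/bI`); states `(i, j, k)`
  with `i ≤ m` subunits having reached the open state, `j ≤ i` of those
  inactive, `k ≤ 4−m` open plain subunits. Only the `i−j` open non-inactive
  subunits can close (`(i−j)·b1`) or inactivate (`(i−j)·aI`); each of the
  `j` inactive ones recovers at `bI`. Size: `(m+1)(m+2)/2 · (5−m)`.

The generator `R(V)` uses the column convention `R[to, from]`, diagonal =
negative column sum, so `dP/dt = R·P` conserves total probability; this is
asserted to 1e-12 at build time in the tests and to 1e-9 along every
simulated trajectory.

State ordering is lexicographic in the count indices (with `I` appended
last for the N-type family). This fixes, e.g., the all-open-all-inactive
corner of the 2:2 C-type model as the 18th state, which the tests use to
check a full row of `R` against its hand-expanded form.

## Units and rate laws

Voltage in mV, time in ms, rates in ms⁻¹ (standard electrophysiology
convention). Voltage-dependent transitions follow single-exponential laws
`rate(V) = m·exp(n·V)` with prefactor `m` (ms⁻¹) and slope `n` (mV⁻¹);
voltage-insensitive transitions (both inactivation mechanisms) are
constants. Sigmoid/Boltzmann laws and temperature scaling are out of
scope.

## Voltage-clamp protocols

All protocols equilibrate at the holding potential (−90 mV) and use steps
of −90..50 mV in 10 mV increments (15 sweeps) unless reconfigured.

* **Activation**: step and hold (default 1000 ms; the duration is a
  package choice — long enough for the transient peak of inactivating
  channels). Outputs: peak open probability, and τ from the rising phase.
* **Inactivation**: 5000 ms conditioning pulse P1 at the step voltage,
  then 1000 ms test pulse P2 at +50 mV. Output: availability vs P1
  voltage. The literal per-sweep quotient (P2 peak / P1 peak) diverges for
  hyperpolarized P1 where the P1 peak is ≈ 0, so the default normalizer is
  the standard steady-state-inactivation convention — each P2 peak divided
  by the largest P2 peak across sweeps, which starts the curve near 1 and
  keeps it in [0, 1]; the literal quotient is available via
  `normalization="per_sweep"`.
* **Recovery**: 5000 ms P1 at +50 mV, a gap of Δt at −90 mV, then a
  1000 ms P2 at +50 mV (P2 duration mirrors the inactivation protocol's
  1 s test pulse). Output: per-sweep P2/P1 peak ratio vs Δt, on a default
  grid of 20 log-spaced points from 10 ms to 10 s.

**Integration.** Within a constant-voltage segment the master equation is
linear with constant coefficients, so the default backend propagates with
`expm(R·dt)` — exact up to floating point; with ≤ 20 states this is also
fast. An adaptive stiff integrator (BDF, rtol 1e-8 / atol 1e-10) is
available for cross-checking and agrees with the exponential to 1e-8 in
the tests. Entries in [−1e-12, 0) are clamped to zero (floating-point
dust); larger violations raise an error naming the segment.

**Peak extraction.** O(t) is sampled every 1 ms (configurable), then the
propagator is re-evaluated on a 10× finer grid around the coarse
maximum — post-step peaks are sharp, and this removes most of the grid
bias without fine global sampling.

**τ extraction.** τ is the time constant of a least-squares
single-exponential fit `O(t) ≈ A(1 − e^{−t/τ})` over [step onset, time of
peak], with the amplitude A profiled out analytically (the model is
linear in A) and τ optimized on a log scale. By convention τ is reported
for homomeric channels only (heteromer rising phases mix two subunit
timescales); a flag enables it everywhere. Note that for a monotone
Hodgkin–Huxley-type rise `(1−e^{−rt})^4` this window-based fit yields
τ ≈ 2/r, not 1/r: the sigmoidal onset is slower than any single
exponential, and the fit splits the difference. Traces with no detectable
rise report τ as absent.

## Quasi-steady-state reduction (N-type family)

When `a1, b1, a2, b2 ≫ aI, bI` (the shipped N-type fixture satisfies
≥ 100× over −60..50 mV), the activation chain equilibrates instantly on
the inactivation timescale. Writing `X` for the total probability of the
non-inactivated states, the conditional distribution within the chain is
the binomial equilibrium, so the open fraction is `X/κ` with

    κ(V) = ((a1+b1)/a1)^N · ((a2+b2)/a2)^(4−N),

and, using `X + I = 1`,

    dX/dt = −aI·N·X/κ(V) + bI·(1−X),  O = X/κ(V).

κ is evaluated adiabatically at the instantaneous voltage, consistent
with the fast-equilibrium assumption. The reduction is one ODE (X and
I = 1−X before applying conservation). Its error is the finite speed of
activation: the QSS channel opens instantly after a step, so its peak
open probability bounds the full model's from above at depolarized
voltages, while availability and recovery curves — which probe the slow
inactivation variable — agree with the full model to a few 1e-4 on the
shipped fixture. No QSS-quality claim is made outside the rate-separation
regime. The single pore-blocked state shared by all n balls is also why
no exact manifold reduction exists for this family: the N-type scheme is
not a product of independent subunit chains.

## Invariant-manifold reduction (C-type family)

Subunit independence gives an exact reduction. With `q` the open
probability of one plain subunit, and `(n, h)` the open and inactive
probabilities of one C-type subunit,

    dq/dt = a2(1−q) − b2·q
    dn/dt = −(b1+aI)·n + a1(1−n−h) + bI·h
    dh/dt = aI·n − bI·h,

the product distribution

    P(i,j,k) = m!/((m−i)!(i−j)!j!) · (1−n−h)^(m−i) n^(i−j) h^j
               × C(4−m, k) q^k (1−q)^(4−m−k)

is an invariant manifold of the full master equation: trajectories
started on it never leave it, verified two ways — the algebraic residual
`‖R·lift − J_lift·(dq,dn,dh)‖∞` is ≤ 1e-10 (observed ~1e-15) at random
interior gating states across compositions and voltages, with the
Jacobian of the lift computed analytically (product rule on the closed
form, not finite differences, so the bound is tight); and full-model
trajectories initialized on the lift track the lifted reduced
trajectories to better than 1e-8 through all three protocols. The
dynamical dimension is 3 for heteromers, 2 for the C-type homomer (q is
absent), 1 in the plain limit. The reduced (n, h) system is an affine
2×2 ODE solved in closed form by its spectral decomposition, with an
augmented-matrix-exponential fallback for the degenerate cases (e.g.
`aI = bI = 0`).

This reduction is what makes the global fit tractable: C-type protocol
curves in the fitting objective are computed from (q, n, h) rather than
the 12–20 state master equation, with identical results.

## Parameter fitting

The six C-type parameters `(m1, n1, m2, n2, aI, bI)` — or any designated
subset, with the rest fixed — are fitted to target curves by minimizing a
weighted SSE over the four summary curves: activation peak-O(V), τ(V)
(homomeric fits only), availability(V), recovery(Δt), at the target's
abscissae. Undefined points (absent τ) count as zero on either side, so
degenerate kinetics cannot escape the comparison; points undefined on
both sides contribute nothing. Candidates whose simulation fails score
+∞ and are rejected.

Search: a 512-point Sobol pre-scan plus two independently seeded
differential-evolution islands (`best1bin`, Sobol init, population
12×dim, up to 80 generations each) over bounds of [1e-5, 1e2] ms⁻¹ for
prefactors/constants — searched in log10 space — and [−0.2, 0.2] mV⁻¹
for slopes (spanning physiological Kv kinetics). Every evaluation feeds
a spatial archive holding the best candidate per cell of the normalized
search box (8 bins per dimension); ranking cells rather than raw
candidates preserves start-point diversity even after the evolution has
concentrated in one basin. The best two dozen archive cells then seed
short trust-region least-squares (Gauss–Newton) triage runs — the
objective is a sum of squares, and exploiting that structure follows its
curved parameter ridges far better than direct search — and the
incumbent best is re-polished until a restart gains less than 0.1%.
The finite-difference step for the residual Jacobian (1e-4 in internal
units) is chosen large enough to average over any remaining
discretization noise of the curve extraction; relatedly, peaks are
interpolated parabolically on the refined grid precisely so that the
extracted peak value and time — and hence the τ-fit window — vary
smoothly with parameters, keeping the objective free of grid-induced
micro-minima. The whole pipeline is deterministic given the seed; a
`max_evaluations` budget below the population size degrades to seeded
random sampling so the budget is honored exactly.

On a noiseless six-parameter synthetic target the search recovers
SSE ≈ 1e-18 and all four curves to ~1e-9 sup-norm in about five minutes
on one CPU, consistently across seeds. Identifiability caveat: several
parameter sets can produce near-identical curves — the search space
contains a competing fast-inactivation basin whose availability curves
are qualitatively wrong but locally optimal — which is why the global
stage keeps diverse polish starts, and why curve recovery, not parameter
identity, is the contract.

## Synthetic data

`make_synthetic_target` produces forward protocol curves from known
parameters plus independent zero-mean Gaussian noise per curve point
(probability/ratio curves clipped to [0, 1]; τ unclipped), seeded. This
emulates the *shape* of digitized voltage-clamp summary data. It does not
emulate: correlated noise within a sweep, rundown or drift across sweeps,
capacitive/leak artifacts, series-resistance error, or cell-to-cell
variability. Passing recovery tests therefore demonstrates that the
pipeline inverts its own forward model under idealized noise — the
appropriate check for a method whose experimental inputs are summary
curves — not that parameters are identifiable from noisy recordings of a
real cell.

The three packaged fixture parameter sets are synthetic stand-ins (the
experimentally fitted Kv1.1/Kv1.4 rate constants are not public),
designed once to sit in the documented regimes: single-subunit activation
midpoints near −30 mV (channel midpoints near −5 mV); the N-type set at
≥ 100× activation/inactivation separation over −60..50 mV with
multi-second ball kinetics; the C-type set with ~1 s per-subunit
inactivation at +50 mV and a modest (~7%) per-subunit steady-state
inactivated fraction, the regime where independent per-subunit gates make
the dose response nearly linear. Qualitative dose-response claims in the
tests (N-type sub-linearity vs C-type near-linearity, 25% decrement
spread) are claims about these fixtures, not about all parameter sets.

## Problem sizes and tolerances

Defaults used by the test suite and the acceptance script, chosen as
reasonable scientific settings for ≤ 20-state models: 15-voltage sweeps,
20-point recovery grids, 1 ms output sampling with 10× peak refinement;
invariance residuals at 100 random interior states × 5 voltages per
composition (50 in the script); trajectory comparisons sampled every
20 ms across all three protocols; the recovery fit uses the default
protocol grids and a ~1e4-evaluation search budget. Key tolerances:
column sums 1e-12; probability conservation 1e-9; stationary null-space
residual 1e-10; manifold invariance 1e-10; full-vs-lifted trajectories
1e-8; expm-vs-adaptive 1e-8.

## Known limitations

* At most two subunit types per channel and no subunit cooperativity;
  auxiliary beta subunits and co-expression stoichiometry distributions
  are out of scope.
* Open probability is the observable; no conductance/driving-force
  current computation, no stochastic single-channel simulation.
* The N-type family has no exact reduction here; QSS quality degrades as
  rate separation shrinks, and only the availability/recovery agreement
  (not peak open probability) is close even at 100× separation.
* τ extraction is a package convention (see above); comparisons with
  externally reported τ values should account for the windowing choice.
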