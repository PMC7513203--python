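# Methods

## Model

One chemical species X in a well-mixed volume V undergoing the
trimolecular scheme `3X ⇌ 2X`, `X ⇌ ∅`, with the constant reservoir
concentrations absorbed into the birth constants.  The count process is a
birth–death Markov chain with propensities

    W+(X) = (k2/V)·X(X−1) + k4·V,
    W−(X) = (k1/V²)·X(X−1)(X−2) + k3·X,

while the concentration x = X/V obeys the mass-action cubic
`dx/dt = −k1x³ + k2x² − k3x + k4`.  The stochastic model uses
falling-factorial combinatorics and the deterministic one plain powers;
the package keeps the two literally distinct everywhere, because the
O(1)-count offset between probability peaks and deterministic attractors,
and the mismatch between the bimodal and bistable parameter ranges, stem
precisely from this difference.  The reference constants are
(k1, k2, k3) = (0.42, 70, 3150) with k4 swept over [1e4, 7e4]; at V=1
the deterministic system is bistable for k4 roughly in [1.8e4, 4.4e4]
while the stationary pmf is bimodal roughly on [2.8e4, 4.8e4].

## Moment hierarchy

`d{X_m}/dt = E[m·(X)_{m−1}·W+(X)] − E[m·(X−1)_{m−1}·W−(X)]`, with
`(X)_m` the falling factorial, follows directly from the forward/backward
difference rules of falling factorials under X → X±1.  The right-hand side
is re-expanded exactly in the falling-factorial basis with sympy (top-down
peeling of leading coefficients), giving `dμ/dt = Aμ + A′μ′ + μ0` with
exact rational coefficients in k1/V², k2/V, k3, k4V.  The third-order death
propensity makes μ′ span exactly orders Ψ+1 and Ψ+2.  Correctness rests on
two independent anchors: symbolic equality of rows 1–2 and μ0 with the
literature system at Ψ=4, and agreement of the full numeric system with a
brute-force generator expectation on arbitrary pmfs to 1e-9 relative.
(Rows 3–4 of the printed reference system are typographically unreliable
and are therefore re-derived, not transcribed.)

## Zero-information closure

Among pmfs on 0..xmax matching the first Ψ factorial moments, the
max-entropy one is `p(X) = exp(−Σ_{i≤Ψ} λ_i (X)_i)`; the closure condition
is that the Ψ stationary moment equations hold for this family.  Solver
details:

- **Truncation.**  xmax defaults to 3·V·x̄ (x̄ the largest deterministic
  root), grown by ×1.5 until the boundary mass is below 1e-14.
- **Scaling.**  Newton runs on scaled multipliers t_i = λ_i s^i with
  s = V·x̄, on basis functions (X)_i/s^i, with coefficient-row-scaled
  residuals; raw factorial moments would otherwise span ~40 orders of
  magnitude.
- **Jacobian.**  ∂μ_j/∂λ_i = −Cov(b_j, b_i) under the current pmf —
  analytic, no finite differences.
- **Globalization.**  Damped Newton with an Armijo line search on the
  least-squares merit ½‖R‖², also accepting any step that lowers the
  residual max-norm; up to 30 halvings; convergence at scaled residual
  < 1e-10 (max-norm) with a small-step escape hatch.
- **Fallback chain.**  If the direct solve stalls: (1) a continuation
  ladder in the closure order 2, 4, …, Ψ, each warm-started; (2)
  continuation in k4 from an automatically chosen monostable-right anchor
  (~1.25-fold steps above the upper fold), marching back to the target in
  ~1–2% steps on a lattice wide enough for the anchor.
- **Initialization.**  "poisson"/"auto": a Gaussian-like exponent (only
  λ1, λ2 nonzero) centred on the dominant attractor — chosen with the
  exact birth–death oracle when available, else the largest stable root —
  with variance equal to the centre; "delta": the same with variance ¼ at
  the largest root; warm starts pass a previous solution's multipliers.
  Converged solutions are independent of the initialization (tested:
  delta starts at either attractor agree to TV < 1e-8 at tol 1e-12).
- **Parity.**  Even Ψ is required in practice: an odd leading order makes
  the family non-normalizable on the half-line for negative leading
  multiplier; odd Ψ warns.  Default Ψ=10 — the empirical order needed to
  capture bimodal Schlögl distributions.

**Accuracy of the Ψ=10 closure (measured, V=1).**  Against the exact
stationary pmf, total variation distance is ~6e-3 at k4=2e4, ~5e-3 at
3.5e4–3.7e4, 2.4e-3 at the critical 4.21e4, 1.3e-3 at 4.5e4 and 7e-5 at
6e4; NESS entropies agree to better than 1e-2 nats across the sweep and
the error shrinks with growing Ψ.  These figures are properties of the
closure itself, not of the solver: a 50-digit re-solve of the Ψ=10 system
reproduces the double-precision pmf to six digits, and the KL-optimal
10-moment fit of the exact pmf (information projection) already has
TV 1.8e-3 at the critical point — no Ψ=10 solution can do much better.
Closure solutions can also carry small spurious tail wiggles (extra
sub-1e-3 local maxima) in strongly left-dominant regimes.

**Known limitations.**  In double precision the solve degrades where the
constrained moments are carried by states holding almost no mass: at V=1
this happens below k4 ≈ 1.8e4 (mean count < ~5, order-10 moments live
entirely on X ≥ 10), and at fixed k4 for volumes V ≳ 2 when the
non-dominant basin carries most of the mass (scaled left-basin moments
~1e-8 at V=5, k4=3.5e4).  The solver raises a diagnostic ConvergenceError
or, at large V, can land on a spurious single-basin branch.  Sweeps
therefore default to the exact engine — exact and fast for this
one-species class — with the ZI engine cross-validated at V=1; sweep
drivers record per-point failures and continue.

## Exact stationary distribution

Detailed balance of one-dimensional birth–death chains gives
`log p(X) − log p(0) = Σ_{y≤X} [log W+(y−1) − log W−(y)]`, accumulated in
extended-precision partial sums and normalized by log-sum-exp.  The
log-space route is essential: the linear-space product overflows near
V ≈ 60 at these parameters (a deliberately naive implementation is kept
privately to demonstrate this), while the log-space evaluation is
routinely used at V = 200 and beyond.  Validation: Poisson closed form on
the linear network (TV < 1e-12), per-state detailed-balance flux residuals
< 1e-12 of the maximal flux, and machine-precision agreement (TV ~ 1e-14)
with the null vector of the truncated generator matrix computed by a
sparse eigensolver.

## Stochastic simulation

Direct-method Gillespie with inlined propensities; exponential waiting
times and uniform reaction picks drawn in blocks from numpy's
counter-based Philox generator, so trajectories are byte-reproducible
given (params, x0, t_end, seed).  Occupancy histograms are time-weighted
(dwell-time per state), the only unbiased convention; per-bin standard
errors come from batch means.  Two statistical facts matter when testing
against the exact pmf and are easy to get wrong: neighbouring states
fluctuate coherently, so per-state errors must not be combined in
quadrature over coarse bins (aggregate the bin occupancy per
run/batch first); and rare valley-ward excursions cluster, so within-run
batch means can understate errors severalfold — independent trajectories,
ideally with initial states drawn from the stationary law (which removes
the O(hitting-time/T) transient of a fixed start), give honest error bars.
The default burn-in heuristic is 10× the slowest linear relaxation scale.

## Modes and mean first passage times

Local maxima by strict neighbour comparison; plateaus resolve to their
leftmost index (documented tie-break).  A peak only counts as a mode if
its basin (between flanking minima) holds at least `threshold` mass,
default 1e-12 — the concrete stand-in for "numerically absent" secondary
peaks; analyses that need the underlying two-peak geometry at any mass
(e.g. passage times at large V) pass a smaller threshold.  Between peaks
a < c the mean passage times are the classical stationary double sums

    T_ac = Σ_{x=a..c−1} [W+(x)p(x)]⁻¹ Σ_{y≤x} p(y),
    T_ca = Σ_{x=a+1..c} [W−(x)p(x)]⁻¹ Σ_{y≥x} p(y),

with the infinite tail truncated at xmax (harmless at tail mass < 1e-14;
passage times are invariant to further truncation to 1e-12 relative).
All sums run in log space off the stored log-pmf; an optional
extended-precision (mpmath, 40 digits) mode covers volumes where even
log-stabilized valley terms lose significance.  The sums are verified
against an independent propensity-only oracle — the absorbing-state
tridiagonal system solved by stable per-step elimination — to 1e-6
relative over V = 1..20; note that a generic banded LU factorization of
the same system silently loses all precision once passage times exceed
~1e9.  At k4=4e4 the log-ratio log(T_ca/T_ac) grows linearly in V
(R² > 0.999): the hallmark of exponentially hardening metastability.

## NESS sweeps

`entropy_sweep` records entropy, mode structure, basin masses and peak
heights per k4 (warm-started continuation when the ZI engine is used);
`critical_k4` takes the grid argmax and refines it by a bounded
golden-section step inside one grid cell; `bimodal_range` reports the
extreme grid points with two modes; `collapse_profile` traces the
secondary-basin mass along a volume grid.  Measured reference behaviour at
(k1,k2,k3) = (0.42,70,3150): the V=1 entropy maximum sits at k4 ≈ 4.20e4
(within one 100-step of 4.21e4) and coincides with equal *peak heights*
(≈ 4.200e4) — not with equal basin masses, which occur near 3.98e4; the
bimodal k4-window on a shared 121-point grid shrinks 20000 → 2000 → 1000
for V = 1 → 51 → 101; at k4=3.5e4 the left attractor dominates at every
volume and the secondary basin drops below 1e-12 mass at V ≈ 62, while at
k4=4.0e4 dominance switches to the right attractor at large V.  Basin
splits assign the valley state to neither side (its mass is negligible at
the reported precision).  Probability peaks sit a stable −3..−7 counts
from V·(stable root) at any volume — so peak concentrations approach the
deterministic attractors as O(1/V), but count-space agreement tighter
than ~8 counts should not be expected at small V.

## Configuration and I/O

Plain `key=value` config files (k1..k4, V, psi, xmax, tol, seed, engine,
output) with strict unknown-key rejection; CSV at 17 significant digits
(lossless round trip); JSON summaries; every CLI run logs a header with
the full parameter set and library versions.

## What the tests show — and what they do not

All inputs are synthetic: the package's own generators (fixture pmfs with
closed-form moments, seeded SSA ensembles) under the reference kinetic
constants.  Passing tests demonstrate internal consistency of four
independent routes to the same stationary laws (product formula, moment
closure, simulation, generator null vector) and reproduction of the
qualitative volume phenomenology; they say nothing about how well the
Schlögl scheme models any particular physical or biological system, and
the closure-accuracy figures above are specific to this parameter regime.
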