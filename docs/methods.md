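# Methods

## Model class and assumptions

The package treats reaction networks that split into a *linear subsystem*
and a *Markov environment* with strictly one-way influence: environment
states modulate subsystem rates, the subsystem never feeds back.  The
subsystem propensity vector is affine in the counts,
`f(x | z) = Γ(z) x + γ(z)`; under mass action this admits zeroth- and
first-order reactions, and more generally any affine rate law (e.g. a
linearized repression term `a − b·x_other`).  The dependence on the
environment label `z` may be arbitrary.  Construction rejects reactions
with total substrate order ≥ 2 and negative constant propensities
(`γ(z) < 0`).

The environment is a finite, irreducible CTMC.  Generators are stored
column-source (`Λ[z', z]` = rate z→z', columns sum to zero, `Λπ = 0`);
a conversion accepts row-oriented input since most references use rows.
Ergodicity assumptions: each per-state first-order matrix `A(z)` must
have eigenvalues with nonnegative real part (zero allowed — a switched-off
degradation channel), and the environment-averaged `Ā` must be strictly
Hurwitz.  For rate structures containing negative first-order
coefficients (linearized repression) the per-state condition can fail by
construction in low-degradation states; such models are admitted with the
violation recorded, and the share-based validity report (below) is the
decisive applicability gate.  Models without negative coefficients that
violate the per-state bound are rejected outright.

## The solver

End-of-sojourn conditional means `x(z)` obey
`A(z) x(z) = Σ_z' Λ(z, z') (π(z')/π(z)) x(z') + b(z)`; in weighted
variables `y(z) = π(z) x(z)` this is the sparse block system
`(blockdiag(A) − Λ⊗I_d) y = stack(b π)`, whose sparsity is the
environment transition graph expanded by d×d blocks.  The stationary mean
is `Σ_z y(z)`; shares are `α_i(z) = y_i(z)/mean_i` and sum to one by
construction.

Numerics: sparse LU (SuperLU) factorization; the residual must satisfy
`‖Ay − rhs‖ ≤ 1e−9 ‖rhs‖` or the solve errors with the advice to tighten
the truncation; a one-norm condition estimate above 1e12 emits a warning
(near the toggle's asymptote the system degrades numerically before it
becomes invalid).  States with `π(z) < 1e−300` are dropped from `x(z)`
reporting.  Two cross-check paths exist and are exercised in tests: the
d = 1 reduction `eᵀ(A − Λ)⁻¹Bπ`, and the unweighted x-form recursion
`(blockdiag(A) − Λᵀ⊗I_d) x = stack(b)`, which is valid only under
detailed balance and therefore gated by an exact `π`-flow symmetry check.

## Q.SS reference, deviation, validity

The quasi-steady-state reference replaces `Γ(z), γ(z)` by their
`π`-averages; its mean `Ā⁻¹b̄` is the baseline and the relative deviation
`(mean − qss)/qss` the headline diagnostic.  Zeroth-order-only modulation
leaves the deviation at zero exactly — a structural identity used as a
test oracle.

The validity report flags (a) any share below −1e−12 and (b) environment
states whose per-state fixed point `A(z)⁻¹b(z)` has a negative component;
it passes iff no share is negative and the flagged states carry at most
1e−4 of any species' share mass.  In practice (toggle past its
asymptote) the negative-share clause trips first; both clauses are
checked because either one signals that the linearization has left its
descriptive region.

## Truncation of countable environments

Immigration–death (Poisson) environments and their switch-gated variants
are truncated reflectingly at `z_max`: the birth transition out of the
last state is dropped, keeping a proper generator, and `π` is re-solved
on the truncated space.  `z_max` defaults to the smallest level whose
Poisson upper tail is below `tail_mass` (default 1e−12; 1e−8 for the
two-component circuit environments, where the product space would
otherwise grow needlessly).  For the switch-gated modulator the
always-on Poisson law stochastically dominates the gated chain, so its
quantile is a conservative level.  Refining the tail mass changes
downstream means monotonically less per halving (tested).

## Case-study constructors

All constructors parametrize by the relative correlation time
`ratio = τ_Z/τ_X` (environment autocorrelation decay over subsystem
relaxation) and by target means, converting internally to rates:

- **Telegraph-gated death** — `z ∈ {0, 1}`, death `c6·z·x`
  (subsystem time scale `1/c6`), switch rates from `(p_off, ratio)`,
  birth set to `qss_mean · c6 · (1 − p_off)`.  Exact mean:
  `qss·(1 + p_off·ratio)`.  An optional `level` scales the On-state death
  rate, with the time scale then `1/(c6·level)`.
- **Poisson-modulated death** — environment birth `c3`, death `c4·z`
  (mean `c3/c4`), `ratio = c6/c4`; optional leak gives death propensity
  `(c6 z + λ0) x` and caps the slow-environment mean at `birth/λ0`.
- **Switch-gated modulator synthesis** — the modulator's birth is
  `c3·z3` with `z3` a telegraph switch; the joint `(z2, z3)` chain is
  Markov, and the modulator's stationary mean is exactly
  `c3·E[Z3]/c4` (its mean dynamics are linear), which the constructor
  uses for calibration.
- **Controller** — sensing species U produced at `c1·z`, decaying at
  `c2·u`; X born at `c5·u`, degraded at `c6·z·x`.  The Q.SS setpoint
  `c5c1/(c2c6)` is environment-mean-independent.  Proportional sensing
  is used because the excursion dynamics (`u(0) = c1/c2`, plateau excess
  `qss·c6/c2`) and the critical-speed law `c2*/c6 = 1/Δ*` follow from
  it; an indicator-sensing variant is available behind a flag without
  fidelity claims.
- **Toggle / oscillator** — two species on the product environment
  (Z1: expression modulator, Z2: degradation modulator).  Free rates are
  matched from the linear Q.SS balance so the reference means hit the
  requested targets; for positive targets the matched rates are provably
  positive.  The toggle's linearized repression produces negative
  first-order coefficients, activating the validity gate; its relative
  asymmetry `R = r/r0` grows with the ratio toward a vertical asymptote
  beyond which the gate fails.  The oscillator (induction instead of one
  repression) has rotational per-state dynamics (zero real-part
  eigenvalues when degradation is off) and decreasing `R`.

Zeroth-order birth modulators are collapsed to their mean by default —
exact at the mean level — with a flag to re-introduce them as an explicit
environment component for simulator cross-checks (the mean is unchanged;
only the joint law differs).  For the circuits Z1 multiplies first-order
terms and is always explicit.  Note that with the standard circuit
parameters only Z2 accelerates as the ratio shrinks while Z1 keeps its
own fixed time scale, so the circuits' deviation retains a small
Z1-induced floor instead of vanishing linearly.

## Stochastic simulators — what they emulate and what they don't

The SSA (direct method) samples the exact joint jump chain and accepts
arbitrary propensity functions, including the Hill-repression variants
that are outside the exact-solver class; negative affine propensities are
clamped at zero with a tally, and a clamp fraction above 0.1% marks a run
as outside the validity region.  The hybrid estimator simulates only
environment jumps and propagates the conditional mean through each
sojourn by the exact affine update — scalar closed form for d = 1, an
augmented matrix exponential `exp([[−A, 0, b], [I, 0, 0], [0, 0, 0]]Δt)`
otherwise, which needs no special-casing at singular `A(z)` and yields
the interval integral alongside the endpoint.  It filters out the
subsystem's shot noise, so where intrinsic noise dominates its standard
error is well below the SSA's at equal horizon.

Estimates are time averages with batch-means standard errors (50 batches,
default burn-in 20% of the horizon — no estimator details are inherited
from elsewhere, these are this package's choices).  Empirical shares sort
the species' time integral by the sojourn label and normalize, so they
sum to one exactly; their errors use the delta method on batch means of
the numerator/denominator pair.  The division–dilution lineage simulator
draws deterministic or Erlang division times, Poisson birth placement
within cycles, and binomial halving at divisions.

Passing simulator cross-checks shows agreement between two exact
descriptions of the *same* idealized model; it says nothing about
un-modelled features of real data (bursting, cell-size effects,
measurement noise, semi-Markov or continuous environments — all out of
scope).

## Problem sizes and tolerances used in the test suite

Exact identities are asserted at solver precision (1e−9 to 1e−12
relative, matching the LU residual bound).  Monte-Carlo comparisons use
three estimated standard errors with fixed seeds; horizons range from
200 to 20 000 time units, scaled to the environment's jump rate so each
run accumulates thousands of sojourns and standard errors near 1% —
sizes chosen as a sensible accuracy/effort trade-off for a default test
run.  The product-environment circuits solve at ~1200 unknowns in well
under a second; the solver itself scales to the ~1e5-unknown range with
the sparse factorization.

## Known limitations

Means only — no variances, transients, or subsystem distributions.
Finite Markov environments only (semi-Markov and continuous-state
environments are outside the model class; countable ones must truncate).
One-way modulation only; bimolecular coupling inside the subsystem is
structurally excluded.  The linearized-repression circuits are
descriptive only inside their validity region, and near its boundary the
block system becomes ill-conditioned before the gate fails — the
condition-number warning is the early signal.  The slow-environment
proportionality constant is estimated numerically (log-log secant slope
/ `mean/ratio` at the largest ratio); no closed form is provided.
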