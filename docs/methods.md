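# Methods

## Model and assumptions

The package implements a deterministic mean-field model of a collective-risk
social dilemma with two environmental feedback loops. An infinite well-mixed
population plays a threshold public goods game in randomly sampled groups of
size `N`: cooperators pay `c`, and the group keeps its endowments `b` when at
least `M` members cooperate (the threshold counts as met at exact equality,
`χ(0) = 1`; the comparison is on integers, no float tolerance). A failed
group loses everything with probability `r`.

The cooperator fraction `x` follows the replicator equation. Averaging the
payoffs over the binomial distribution of co-players yields the gradient of
selection in closed form,

    f_C − f_D = b r C(N−1, M−1) x^(M−1) (1−x)^(N−M) − c,

the expected pivotal benefit of being the decisive M-th contributor minus
the cost. Both the summation and closed-form routes are implemented; their
equality (to 1e−10 over random draws of all parameters with N ≤ 12) is a
standing test, since the closed form is what every downstream computation
uses. Binomial coefficients come from exact integer arithmetic
(`math.comb`), which is exact for every group size, so no floating-point
fallback is needed.

Risk and cost respond linearly to the population state, with logistic /
quadratic prefactors pinning them to their bounds:

    ṙ = r(1−r)[μ₁(1−x) − μ₂x],
    ċ = (α−c)(c−β)[θ₁(1−x) − θ₂x + θ₃r − θ₄(1−r)].

Defection raises both risk and cost; cooperation lowers both; risk raises
cost. All six coefficients are strictly positive and have units of inverse
time; `b`, `c`, `α`, `β` are payoff units; `x`, `r` are dimensionless. The
timescale factors `ε₁`, `ε₂` divide the strategy and risk equations and
default to 1; the cost equation carries no timescale factor of its own, so
relative cost-update speed is controlled through the θ magnitudes.

The feedback pair is injectable in `vector_field(…, feedbacks=(U1, U2))`, so
variants (e.g. a cost-to-risk coupling) can be plugged in without touching
the replicator layer. The analytic Jacobian is implemented only for the
default pair.

## Equilibrium atlas

All fixed points are enumerated in closed form:

* **Corners** — the eight vertices of the box. Only `(0, 1, α)` is stable;
  this holds for *every* admissible parameter set, so the tragedy of the
  commons is never bifurcated away.
* **Edges** — on `r = 1` with `c` pinned at `α` or `β`, the roots of
  `benefit(x) = c₀` where `benefit(x) = b C(N−1,M−1) x^(M−1) (1−x)^(N−M)`.
  `benefit` is unimodal with its maximum at `x̂ = (M−1)/(N−1)`, value
  `b ((N−M)/(N−1))^(N−M) ((M−1)/(N−1))^(M−1) C(N−1,M−1)`; when the peak
  exceeds `c₀` there are two roots, bracketed by `[0, x̂]` and `[x̂, 1]` and
  found with Brent's method (certain brackets; no general polynomial
  solving). The lower root is always a saddle; only the upper root can be
  stable. A peak exactly equal to `c₀` (double root) is reported as
  non-existent with a `degenerate` flag rather than as a single semi-stable
  point. For `M = 1` or `M = N` the benefit term is monotone and the single
  bracketed root is returned on its side of `x̂`.
* **Surfaces** — `(x*, Br, β)` and `(x*, Tr, α)` at the risk-balance
  frequency `x* = μ₁/(μ₁+μ₂)` with `Br = β/benefit(x*)`,
  `Tr = α/benefit(x*)` (existing when the pinned risk lies in (0,1)); and
  `(Rx, 1, Rc)` at the cost-balance frequency `Rx = (θ₁+θ₃)/(θ₁+θ₂)` with
  `Rc = benefit(Rx)` (existing when `θ₃ < θ₂` and `β < Rc < α`; always
  unstable).
* **Interior** — `(x*, r*, c*)` with
  `r* = (θ₂μ₁ − θ₁μ₂ + θ₄(μ₁+μ₂)) / ((θ₃+θ₄)(μ₁+μ₂))` and
  `c* = benefit(x*) r*`; always unstable when it exists.

Stability is classified twice and cross-validated:

1. **Closed-form conditions.** The upper `c = α` edge root is stable iff
   `x₂ < min(μ₁/(μ₁+μ₂), (θ₁+θ₃)/(θ₁+θ₂))`; the upper `c = β` root iff it
   lies strictly between the cost ratio (below) and the risk ratio (above);
   the cost-face surface points are stable iff `T1 < 0 ∧ T5 < 0`
   respectively `B1 < 0 ∧ B5 < 0`, with

       T1 = α(M − Nx* − x*) + α(2x* − 1),
       T5 = (β−α)[θ₁(1−x*) − θ₂x* + θ₃Tr − θ₄(1−Tr)],

   and `B1`, `B5` the same with `β` and `Br`. `T1`/`B1` are kept in this
   expanded grouping (they algebraically equal `α(M−1−(N−1)x*)` and
   `β(M−1−(N−1)x*)`; the test suite asserts the identity).
2. **Eigenvalues** of the analytic Jacobian, using the full 3-D
   linearisation at boundary points (directions leaving the box included).
   Verdicts use a marginal band of half-width 1e−9 around the imaginary
   axis; non-hyperbolic parameter sets occur only on measure-zero slices and
   random draws that hit one are discarded and replaced.

Agreement of the two classifiers over hundreds of random draws (several
thousand individual equilibria) is the headline validation and is exercised
both in the test suite and in `scripts/acceptance.py`.

## Numerical integration

The vector field is polynomial with coefficients of order one — not stiff.
Trajectories do, however, pass exponentially close to the invariant faces
(components reaching ~1e−12 before growing back), and there both
stiffness-switching (LSODA) and implicit (BDF) solvers were observed to
collapse their step size or fail outright on random-parameter sweeps, while
explicit embedded Runge–Kutta pairs handle every case. The default
integrator is therefore RK45 with `rtol = 1e−9`, `atol = 1e−11`, horizon
`t_end = 2000` (the slowest feedback coefficients used in the study
presets are of order 0.1 per time unit, giving relaxation times far inside
this horizon); any `solve_ivp` method remains selectable. Box invariance is
analytic, so states are clipped back to the box after integration and the
largest excursion is recorded; it is required to stay below 1e−6 (observed:
~1e−8 at `rtol = 1e−8`).

A trajectory is assigned to an attractor when its final state lies within
`dist_tol = 1e−3` of a stable equilibrium **and** the vector-field norm
there is below 1e−6; anything else is `unresolved`. Assignment refuses to
run if two stable equilibria are closer than `2·dist_tol`.

## Basin estimation and sweeps

Basin "volume" is operational: the fraction of a regular interior grid of
starts (default 21×21×11, margins 0.02 on `x`, `r` and 0.02·(α−β) on `c` to
stay off the degenerate faces) whose trajectories resolve to each stable
equilibrium. All grid starts are advanced together through a vectorised
copy of the right-hand side (RK45, `rtol = 1e−7`) in windows of 400 time
units; after each window the settled starts are labelled and the rest
continue, up to 6 windows. The batch shares step-size control across
trajectories; this only affects accuracy along the way, not the identity of
the attractor reached, and the default tolerances resolve every grid point
in the regimes studied. Fractions are bit-for-bit reproducible from the
grid alone; optional seeded jitter (off by default) perturbs starts within
their cells.

The threshold sweep varies `M` at fixed background parameters, keeping only
thresholds where the upper edge root at the requested cost level exists and
is stable under *both* classifiers; skipped thresholds are reported with
reasons. Each kept row records the stable cooperator fraction `x₂`, its
basin fraction (default 11×11×7 grid for desk-scale runtime), and the
collective success probability `P(X ≥ M)`, `X ~ Binomial(N, x₂)`, computed
by the explicit complementary sum (exact for dyadic-rational frequencies).

## Study presets

The packaged presets share the baseline game `N = 8`, `M = 5`, `b = 2`,
`β = 0.1`, `α = 0.3`, `μ₂ = 0.3`, `θ₁ = 0.5`, `θ₄ = 0.6` and select regimes
through `μ₁`, `θ₂`, `θ₃`: one monostable set (tragedy corner only), two
bistable sets with an edge attractor (at maximal and at minimal cost), one
tristable set with both edges, one bistable and two tristable sets
involving the cost-face surface attractors, plus two sweep backgrounds.
These are analytic parameter choices, not data: passing tests demonstrate
internal consistency of the dynamics, atlas, and basin machinery, not
agreement with any empirical population.

## Limitations

* Deterministic infinite-population dynamics only; no finite-population or
  structured-population (Moran/Fermi) updating.
* The only built-in feedback pair is the linear one above; in particular
  there is no cost-to-risk coupling, under which the model class is known
  to admit oscillations. Accordingly no limit-cycle detection is attempted:
  all attractors handled are fixed points.
* Basin fractions are grid shares, sensitive at the stated resolutions to
  O(1/√n_grid) discretisation; refinement tests bound this.
* The closed-form stability table and the eigenvalue classifier are mutually
  validating; at genuinely non-hyperbolic parameter sets both abstain
  (`marginal`), and no center-manifold analysis is performed.
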