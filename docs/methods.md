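# Methods

## Model

A semi-infinite unidirectional chain of phase oscillators
`theta_s in T = R/Z`, `s = 1, 2, ...`, forced at the root by
`theta_0(t) = f(t)`:

    dtheta_s/dt = 1 + eps   if theta_{s-1} mod 1 in [0, a0] and theta_s mod 1 in [0, a1]
                  1         otherwise.

The natural frequency is rescaled to 1; `eps > 0` is the coupling
intensity; `[0, a0]` is the stimulus window of the upstream unit and
`[0, a1]` the response window of the driven unit (a square type-I
phase-response curve).  Both windows share the left boundary 0 — a
deliberate simplification that keeps the parameter count at three.  The
forcing is Lipschitz, increasing, has slope >= 1 wherever defined, and is
periodic in the lift sense `f(t + tau) = f(t) + 1`, `f(0) = 0`.

Because information flows strictly downstream, truncating the chain at S
sites is exact, and the whole system is solved inductively: site s is a
one-dimensional forced system whose input is the computed trajectory of
site s-1.

## Exact event-driven integration

Between events every trajectory is affine with slope 1 or `1+eps`, so the
next event — the earliest of: the site reaches its response boundary
`n + a1`, the site completes a revolution at `n + 1`, the upstream signal
crosses a level `k` (window entry) or `k + a0` (window exit) — is the root
of an affine equation, computed in closed form.  There is no time stepping
and no root finding; with rational inputs (`fractions.Fraction`) the
integration is exact, which the test suite uses to freeze reference values.

Conventions for degenerate configurations:

- Windows are closed, but boundary contact is instantaneous: an event
  landing exactly on a boundary contributes a zero-length fast piece, so
  the measure-zero choice of side cannot change the trajectory.  Zero
  length pieces are pruned from the output.
- Simultaneous self/upstream events are processed in one slope
  recomputation; the order is immaterial by construction.
- In floating-point mode events closer than `merge_tol = 1e-12` are
  merged; in rational mode the tolerance is 0.  Validation checks use
  `1e-9` absolute by default; all tolerances are arguments.
- Forcings with slope-1 plateaus sitting exactly on the level `a0` or an
  integer make the on/off condition ambiguous over an interval; the
  validator *flags* such signals (`grazing_warnings`) rather than silently
  resolving them.

The independent cross-check is a deliberately naive explicit small-step
integrator (`euler_oracle`).  Its sup error over a few periods is O(dt)
away from tangencies; note that the *per-fixture* sup error is dominated by
a few terms of the form `t_event mod dt` and therefore fluctuates around
the O(dt) trend — the first-order scaling is asserted on the average over
fixtures, not on each one.

## The wave family and its intervals

A traveling wave is a solution `theta_s(t) = f(t + alpha*s)`; the forcing
doubles as the wave shape and `alpha/tau` is the wave number.  For the
stable family the shape is the three-piece profile

    Theta_{alpha,sigma}(t) = t                         t <= alpha
                             alpha + (1+eps)(t-alpha)  alpha <= t <= sigma+alpha
                             eps*sigma + t             t >= sigma+alpha

restricted to `[0, tau]`, `tau = 1 - eps*sigma`, where
`sigma = min{t0, t1}` with `t0 = min{a0, (a0+alpha*eps)/(1+eps)}` (first
exit of the forcing from the stimulus window) and
`t1 = (a1-alpha)/(1+eps)` (first exit of the driven phase from the
response window).

**Existence interval.**  The construction is self-consistent iff
`0 <= alpha < a1` and `f(tau-alpha) >= a0`.  Reducing the second condition
to closed form requires care: the classical reduction uses the identity
`Theta_{alpha,s}(t0) = a0` *for every* s, which holds only when
`t0 <= t1 + alpha` (or `t0 = a0 <= alpha`).  When `t0 > t1 + alpha` (wide
stimulus window, narrow response window) the evaluation point
`tau - alpha` lands on the terminal slope-1 branch where
`f(tau-alpha) = eps*sigma + tau - alpha = 1 - alpha`, and the condition
becomes `alpha <= 1 - a0`.  The implementation therefore uses

    0 <= alpha < min{ a1,
                      max{(1+eps)(1-a0) - eps*a1, (1-a0+eps(1-a1))/(1+eps)},
                      1 - a0 }.

Without the `1-a0` term, parameter sets such as
`(eps, a0, a1) = (0.536, 0.905, 0.180)` admit an `alpha` whose constructed
shape violates its own on/off condition (`f(tau-alpha) = 0.83 < a0 =
0.91`).  The corrected bound was validated against a direct bisection on
the evaluated condition over thousands of random parameter draws (agreement
to 1e-12); the admissible set remains an initial segment of `alpha` and the
stability interval below remains non-empty for every draw.

**Stability interval.**  The wave is asymptotically stable iff the driven
phase leaves its response window strictly before the forcing leaves the
stimulus window, `t1 < t0`, equivalently
`alpha > alpha0 = max{a1-(1+eps)a0, (a1-a0)/(1+eps)}`.  The tie
`t0 = t1` is a neutral boundary and classified as such with a warning.
Endpoint conventions: existence is half-open `[0, hi)` (strict `alpha <
a1`), stability open at `alpha0`; `alpha = 0` (wave number 0) is excluded
from construction by default and available behind `allow_zero=True`.

**Uniform-forcing interval.**  The ramp `g = t/tau` generates the wave when
`g(sigma) < a0 < g(tau-alpha)`, which reduces to

    (a1-a0-eps*a0(1-a1))/(1+eps*a0) < alpha < (1-a0)(1+eps(1-a1))/(1+eps*a0),

intersected with the stability interval.  In extensive sampling this
intersection was never empty, so the "may be empty" branch of the API is
defensive.

**tau <-> alpha.**  `tau(alpha) = 1 - eps*min{t0, t1}` is continuous and
piecewise affine with kinks at `alpha0` and `a0`; it is inverted piece by
piece and *all* preimages are reported, since injectivity over the whole
existence interval is not guaranteed.

## Stroboscopic analysis

The period map `F(theta) = theta_1(theta, tau) - 1` is a degree-1 lift of
an orientation-preserving circle homeomorphism and is exactly piecewise
affine with slopes `(1+eps)^k`, k integer.  The decomposition is computed
structurally: two initial phases lie on the same affine branch iff their
one-period trajectories share the same *event signature* (the fast/slow
piece pattern plus the ordered event kinds); branches are fitted from the
samples of each signature class, and breakpoints are the intersections of
adjacent fitted branches — no bisection residual.  The sweep starts at 256
samples and doubles until every branch holds at least three samples
(capped, default piece limit 64).  A branch narrower than the sweep that
touches `theta = 1` is recovered analytically from the lift's continuity
anchor `B(1) = F(0) + 1` plus one sample near 1.  Fitted slopes are
snapped to the nearest integer power of `1+eps` when within tolerance.

For a stable wave shape the decomposition has exactly four branches (two
rotations, one contraction `1/(1+eps)`, one expansion `1+eps`), hence one
stable fixed point at the wave phase `f(alpha)` and one unstable fixed
point; fixed points are solved per branch and classified by local slope,
with slope-1 branches whose offset is an integer reported as neutral
*segments*.  Rotation numbers are estimated as `(F^n(theta)-theta)/n` from
the decomposed map; a map with a fixed point has rotation number zero and
the estimator converges at O(1/n).

**Downstream sites.**  Site s at stroboscopic times is the non-autonomous
composition of the per-period maps induced by the (converging) trajectory
of site s-1; it is computed by direct chain simulation rather than by
storing map objects, trading memory for exactness.  The exceptional initial
phase of site s — the unique one whose orbit avoids the wave — is located
by bisection on the integer translate of the orbit limit, which jumps by 1
across it (default precision 1e-10; the number of periods per probe is
chosen so the local expansion `1+eps` resolves that precision).

With the upstream site exactly on the wave, the site-2 map is the
stroboscopic map of the alpha-shifted forcing, and its unstable point is
`u(alpha)`, the time-alpha value of the *unstable periodic solution* u of
the single-site system (`u(0)` = the unstable fixed point).  Note that u is
not a time-translate of the wave shape — `f(. + t_unst)` violates the
on/off condition — so `u(alpha)` must be computed by evolving the flow (for
the reference parameter set it is exactly 3/10, obtained in rational
arithmetic and confirmed by the bisection).

## Generation experiments

A generation run forces the chain with the wave shape, the uniform ramp, or
a perturbed shape, starts from seeded i.i.d. uniform phases, and records
per-site stroboscopic circle distances
`d_s(n) = dist(theta_s(n*tau), f(n*tau + alpha*s))`.  A site counts as
converged when the sup of `d_s` over a trailing window (default 20
periods) is below tolerance (default 1e-6).  Perturbed forcings are convex
blends of the wave shape with the uniform ramp (a seeded weight in
(0, 0.3]); convex combination preserves every forcing constraint and the
admissibility margins are verified before use.  The measure-zero
exceptional initials are exercised only in targeted exact-rational runs.

**Transient lengths.**  The local contraction per period is `1/(1+eps)`,
but that does not bound the transient: an orbit must first traverse the
rigid-rotation branches of the period map, which takes on the order of
(branch length)/(rotation offset) periods, and the offset is not bounded
below over parameter space.  Empirically, about 90% of random
uniform-interval fixtures with `eps in [0.05, 0.3]` bring all of the first
5 sites below 1e-6 within 500 periods; the remainder need thousands of
periods but do converge (verified out to 8000 periods).  Default horizons
in the package (300-500 periods, problem sizes of 5-20 sites) were chosen
to cover the typical case at interactive run times; the attractivity
statement itself carries no horizon.

## What the synthetic fixtures do and do not show

Random fixtures draw `eps` uniform in `[0.05, 1]` (experiments use
`[0.05, 0.3]` where the uniform-forcing interval is the subject) and
`a0, a1` uniform in `[0.05, 0.95]`, with `alpha` uniform inside the
requested admissibility interval; initial phases are i.i.d. uniform on
`[0, 1)`.  This matches the model's own assumptions exactly — the system
is piecewise affine by definition, so there is no model error, only
floating-point rounding (all headline identities hold to 1e-12 in float
mode and exactly in rational mode).  What the fixtures do *not* probe:
smooth phase-response curves, noisy or non-periodic forcing, bidirectional
or ring topologies, and windows with distinct left boundaries.  Passing
tests therefore certify the idealized square-window model, not any smooth
neural model it caricatures.

## Known limitations and regime-restricted identities

- The textbook lower bound "every slope-1 piece has length >= 1-a1" holds
  only for slow pieces flanked by fast pieces *and* when fast phases end by
  the oscillator leaving its own response window; a fast phase cut short by
  a wide upstream window (`(1-a0)/(1+eps) < 1-a1`) can be followed by a
  shorter slow piece.  `check_trajectory_invariants` reports such pieces;
  callers decide whether the regime guarantees the bound.
- Wave construction is implemented only for the stable-family shape class
  (initial fast piece, slow at the revolution); the other three classes of
  the four-way shape classification are labeled but not constructed, as no
  closed form is available for them here.
- The piece cap (64) and sweep resolution of `strobe_decompose` guard
  against pathological non-wave forcings; both are configurable.
- `euler_oracle` is a validation device, never the integration path.
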