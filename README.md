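# oscwave

Traveling-wave generation in periodically forced unidirectional chains of
two-speed phase oscillators: an exact event-driven simulator plus the
closed-form wave family, its admissibility intervals, and the
stroboscopic-map stability machinery.

## The problem

Feed-forward chains of type-I phase oscillators are a minimal model of wave
propagation in layered neural tissue (synfire chains, central pattern
generators): each pool of synchronized neurons is one phase variable
`theta_s` on the circle `T = R/Z`, driven only by its upstream neighbor.
This package studies the idealized piecewise-affine variant in which the
phase-response curve and the incoming stimulus are both square windows:

    dtheta_s/dt = 1 + eps    if  theta_{s-1} mod 1 <= a0  and  theta_s mod 1 <= a1
                  1          otherwise,           s = 1, 2, ...

with `theta_0(t) = f(t)` an increasing tau-periodic forcing
(`f(t+tau) = f(t)+1`, slope >= 1, `f(0)=0`), coupling `eps > 0`, and window
widths `a0, a1` in `(0,1)`.  Because every trajectory is piecewise affine
with slopes in `{1, 1+eps}`, the flow can be integrated *exactly*, event by
event — which is what this package does.

The striking phenomenon is *generation*: force the root with almost any
admissible signal — including the structureless uniform ramp
`g(t) = t/tau` — and the chain self-organizes into a traveling wave
`theta_s(t) -> f(t + alpha*s)` whose shape `f` is determined by the model
parameters, not by the input.  The library constructs that shape in closed
form, proves-by-computation its stability properties via the stroboscopic
map, and measures the generation transient site by site.

### Core objects

- **Wave shape.** For a phase shift `alpha` per site, the stable-family
  shape is the three-piece profile `Theta_{alpha,sigma}`: slope 1 on
  `[0, alpha]`, slope `1+eps` on `[alpha, sigma+alpha]`, slope 1 up to the
  period `tau = 1 - eps*sigma`.  The fast duration is
  `sigma = min{t0, t1}` with `t0 = min{a0, (a0+alpha*eps)/(1+eps)}` and
  `t1 = (a1-alpha)/(1+eps)`.
- **Admissibility intervals.**  `alpha_intervals` returns nested intervals
  of `alpha` (and their images under `alpha -> tau(alpha)`): existence of
  the wave, asymptotic stability (`alpha > alpha0 =
  max{a1-(1+eps)a0, (a1-a0)/(1+eps)}`), and robustness to uniform forcing.
- **Stroboscopic map.**  `F(theta) = theta_1(theta, tau) - 1` is an exactly
  piecewise-affine circle homeomorphism; for a stable wave it has four
  branches (two rotations, one contraction, one expansion), a stable fixed
  point at the wave phase `f(alpha)` and a single unstable fixed point.
  `strobe_decompose` recovers the branches exactly from trajectory event
  signatures.

## Worked example

The reference parameter set `eps=1/2, a0=3/10, a1=3/5` with `alpha=2/5`
(all closed forms rational: `t0=3/10`, `sigma=t1=2/15`, `tau=14/15`):

```
$ oscwave intervals --epsilon 0.5 --a0 0.3 --a1 0.6
 existence: [0.0, 0.6]
    stable: [0.19999999999999998, 0.6]
   uniform: [0.20869565217391306, 0.6]
```

Any `alpha` in the stable interval yields an attracting wave; in the
uniform sub-interval even the plain ramp generates it.  Driving 5 sites
from random initial phases with the uniform ramp for 300 periods:

```
$ oscwave generate --epsilon 0.5 --a0 0.3 --a1 0.6 --mode uniform \
      --alpha 0.4 --sites 5 --periods 300 --seed 11
{ ...
  "converged": [true, true, true, true, true],
  "first_below": [20, 26, 32, 36, 41],
  "limit_phases": [0.4, 0.8666666666666667, 0.26666666666666683,
                   0.7333333333333334, 0.1333333333333333]
}
```

Every site locks to the *wave* phases `f(alpha*s) mod 1 =
(2/5, 13/15, 4/15, 11/15, 2/15)` — not to the ramp — and the first period
index at which each site reaches the wave (`first_below`) increases
downstream: convergence starts at site 1 and propagates down the chain.

The stroboscopic map behind this, with its two fixed points:

```
$ oscwave strobe --epsilon 0.5 --a0 0.3 --a1 0.6 --alpha 0.4 --fixed-points
{ "fixed_points": [
    {"theta": 0.39999999999999886, "slope": 0.6666666666666666, "class": "stable"},
    {"theta": 0.8333333333333343, "slope": 1.5, "class": "unstable"} ] }
```

Orbits contract to the wave phase 0.4 at rate `1/(1+eps) = 2/3` per period;
the single exceptional initial condition 5/6 is the measure-zero set on
which generation fails.

## Layout

- `oscwave.core` — circle/lift arithmetic, piecewise-affine paths, forcing
  signals (uniform, user profiles via CSV, time shifts, blends).
- `oscwave.traveling_wave` — closed-form wave construction, admissibility
  intervals, the `tau <-> alpha` correspondence, shape-case classification.
- `oscwave.simulator` — exact event-driven integration of single sites and
  truncated chains (truncation is exact: coupling is unidirectional), a
  brute-force small-step oracle, semi-group checks, and the
  order-reversal witness showing the dynamics is not monotone.
- `oscwave.stroboscopic` — period map decomposition, fixed points and
  stability, rotation numbers, composed downstream maps, bisection for the
  exceptional initial conditions.
- `oscwave.experiments` — forcing admissibility, generation experiments
  with per-site convergence reports, fixture sampling, snapshot export.
- `oscwave.cli` — `oscwave tw | intervals | simulate | strobe | generate`.

See `docs/methods.md` for the model, numerical conventions, and known
limitations (including two textbook identities that hold only in restricted
parameter regimes).
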