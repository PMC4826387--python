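"""Closed-form traveling waves and their admissibility intervals.

A traveling wave (TW) of the forced chain is a solution in which the forcing
shape repeats identically at every site with a fixed time shift alpha:
``theta_s(t) = f(t + alpha s)``.  For the stable family of waves the shape is
the explicit three-piece profile

    Theta_{alpha,sigma}(t) = t                          for t <= alpha
                             alpha + (1+eps)(t-alpha)   for alpha <= t <= sigma+alpha
                             eps*sigma + t              for t >= sigma+alpha

restricted to one period ``[0, tau]`` with ``tau = 1 - eps*sigma``.  The fast
duration sigma is the smaller of two first-exit times: ``t0``, when the
forcing leaves the stimulus window ``[0, a0]``, and ``t1``, when the driven
oscillator leaves the response window ``[0, a1]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import (
    DEFAULT_TOL,
    ForcingSignal,
    ModelParams,
    PiecewisePath,
    frac_part,
    is_exact,
)

__all__ = [
    "TravelingWave",
    "AlphaIntervals",
    "NoCaseAWaveError",
    "AlphaNotAdmissibleError",
    "tw_times",
    "build_tw",
    "alpha_intervals",
    "classify_tw_case",
    "tau_of_alpha",
    "alpha_for_tau",
]


class NoCaseAWaveError(ValueError):
    """Raised when no wave with an initial fast phase exists (alpha > a1)."""


class AlphaNotAdmissibleError(ValueError):
    """Raised when the requested phase shift is outside the existence range."""


@dataclass(frozen=True)
class TravelingWave:
    """A constructed stable-family traveling wave.

    Fields: model parameters, phase shift per site ``alpha``, fast-piece
    duration ``sigma``, period ``tau``, the two first-exit times ``t0``
    (forcing leaves the stimulus window) and ``t1`` (oscillator leaves the
    response window), the shape as a periodic forcing signal, and the case
    label of the four-way shape classification (always ``"a"`` here).
    """

    params: ModelParams
    alpha: float
    sigma: float
    tau: float
    t0: float
    t1: float
    shape: ForcingSignal
    case_label: str = "a"

    def validate(self, tol: float = 1e-12) -> None:
        eps = self.params.epsilon
        if abs(self.tau - (1 - eps * self.sigma)) > tol:
            raise ValueError("tau != 1 - eps*sigma")
        if abs(self.sigma - min(self.t0, self.t1)) > tol:
            raise ValueError("sigma != min(t0, t1)")
        if not (-tol <= self.sigma <= self.tau + tol):
            raise ValueError("sigma outside [0, tau]")
        f = self.shape
        if abs(f(0)) > tol or abs(f(self.tau) - 1) > tol:
            raise ValueError("shape endpoints differ from (0,0), (tau,1)")
        if self.case_label == "a":
            if not f(self.alpha) < self.params.a1 + tol:
                raise ValueError("case (a) needs f(alpha) < a1")
            if not f(self.tau - self.alpha) >= self.params.a0 - tol:
                raise ValueError("case (a) needs f(tau - alpha) >= a0")


@dataclass(frozen=True)
class AlphaIntervals:
    """Nested admissibility intervals of the phase shift alpha.

    existence
        ``[lo, hi)``: a case-(a) wave exists.
    stable
        ``(lo, hi)``: the wave is asymptotically stable (t1 < t0, i.e.
        alpha > alpha0).
    uniform
        ``(lo, hi)`` or None: stable waves additionally generated by the
        uniform ramp ``g(t) = t/tau``.
    tau_*
        images of the corresponding alpha intervals under alpha -> tau(alpha),
        given as (min, max) pairs.
    """

    existence: tuple
    stable: tuple
    uniform: tuple | None
    tau_existence: tuple
    tau_stable: tuple
    tau_uniform: tuple | None

    def contains(self, alpha, which: str = "existence") -> bool:
        iv = getattr(self, which)
        if iv is None:
            return False
        lo, hi = iv
        if which == "existence":
            return lo <= alpha < hi
        return lo < alpha < hi


def tw_times(params: ModelParams, alpha):
    """First-exit times and derived (sigma, tau) for a case-(a) wave.

    Returns ``(t0, t1, sigma, tau)`` where ``t0 = min{a0, (a0+alpha*eps)/(1+eps)}``
    is when the shape leaves the stimulus window, ``t1 = (a1-alpha)/(1+eps)``
    is when the driven oscillator leaves the response window,
    ``sigma = min{t0, t1}`` and ``tau = 1 - eps*sigma``.  Exact for rational
    inputs.
    """
    if alpha < 0:
        raise ValueError("phase shift alpha must be >= 0")
    eps, a0, a1 = params.epsilon, params.a0, params.a1
    t1 = (a1 - alpha) / (1 + eps)
    if t1 < 0:
        raise NoCaseAWaveError(
            f"no case-(a) fast onset: alpha={alpha} exceeds the response "
            f"window width a1={a1}"
        )
    t0 = min(a0, (a0 + alpha * eps) / (1 + eps))
    sigma = min(t0, t1)
    tau = 1 - eps * sigma
    return t0, t1, sigma, tau


def alpha_intervals(params: ModelParams) -> AlphaIntervals:
    """Existence, stability and uniform-forcing intervals of alpha.

    existence: ``0 <= alpha < min{a1, alpha1, 1-a0}`` with
    ``alpha1 = max{(1+eps)(1-a0) - eps a1, (1-a0+eps(1-a1))/(1+eps)}``
    (upper endpoint treated as open; the boundary is measure zero).  The
    ``1-a0`` term enforces ``f(tau-alpha) >= a0`` in the regime where the
    evaluation lands on the terminal slope-1 branch of the shape; see the
    methods note for the derivation.
    stable: additionally ``alpha > alpha0 = max{a1-(1+eps)a0, (a1-a0)/(1+eps)}``.
    uniform: additionally
    ``(a1-a0-eps a0(1-a1))/(1+eps a0) < alpha < (1-a0)(1+eps(1-a1))/(1+eps a0)``.
    The stable interval is non-empty for every valid parameter set; the
    uniform one can be empty for large eps.
    """
    eps, a0, a1 = params.epsilon, params.a0, params.a1
    zero = eps * 0
    alpha1 = max((1 + eps) * (1 - a0) - eps * a1, (1 - a0 + eps * (1 - a1)) / (1 + eps))
    # the shape's value one shift before the period end is 1 - alpha whenever
    # the evaluation lands on the terminal slope-1 branch, so the stimulus
    # window condition f(tau - alpha) >= a0 additionally requires
    # alpha <= 1 - a0; without it the constructed shape fails its own
    # defining on/off condition for wide stimulus windows
    hi = min(a1, alpha1, 1 - a0)
    existence = (zero, hi)
    alpha0 = max(a1 - (1 + eps) * a0, (a1 - a0) / (1 + eps), zero)
    stable = (alpha0, hi)
    u_lo = (a1 - a0 - eps * a0 * (1 - a1)) / (1 + eps * a0)
    u_hi = (1 - a0) * (1 + eps * (1 - a1)) / (1 + eps * a0)
    lo_u, hi_u = max(alpha0, u_lo), min(hi, u_hi)
    uniform = (lo_u, hi_u) if lo_u < hi_u else None

    def tau_image(lo, hi):
        # tau(alpha) is piecewise affine; extremes occur at endpoints or kinks
        cands = [lo, hi] + [
            k for k in _tau_kinks(params) if lo < k < hi
        ]
        taus = [tw_times(params, a)[3] for a in cands]
        return (min(taus), max(taus))

    return AlphaIntervals(
        existence=existence,
        stable=stable,
        uniform=uniform,
        tau_existence=tau_image(*existence),
        tau_stable=tau_image(*stable),
        tau_uniform=tau_image(*uniform) if uniform else None,
    )


def _tau_kinks(params: ModelParams):
    """Interior kink locations of alpha -> tau(alpha)."""
    eps, a0, a1 = params.epsilon, params.a0, params.a1
    alpha0 = max(a1 - (1 + eps) * a0, (a1 - a0) / (1 + eps))
    return sorted({a0, max(alpha0, 0 * eps)})


def tau_of_alpha(params: ModelParams, alpha):
    """The wave period as a function of the phase shift."""
    return tw_times(params, alpha)[3]


def alpha_for_tau(params: ModelParams, tau, tol: float = DEFAULT_TOL) -> list:
    """All phase shifts in the existence interval whose wave period is tau.

    The map alpha -> tau(alpha) is continuous and piecewise affine but not
    necessarily injective; every preimage is returned (sorted ascending).
    """
    lo, hi = alpha_intervals(params).existence
    knots = sorted({lo, hi, *(k for k in _tau_kinks(params) if lo < k < hi)})
    sols = []
    for a, b in zip(knots[:-1], knots[1:]):
        ta, tb = tau_of_alpha(params, a), tau_of_alpha(params, b)
        if abs(tb - ta) <= tol:
            if abs(tau - ta) <= tol:
                sols.append(a)
            continue
        s = (tau - ta) / (tb - ta)
        if -tol <= s <= 1 + tol:
            sols.append(a + s * (b - a))
    out = []
    for s in sorted(sols):
        if not out or s - out[-1] > tol:
            out.append(s)
    return out


def build_tw(
    params: ModelParams, alpha, *, allow_zero: bool = False, tol: float = 1e-12
) -> TravelingWave:
    """Construct the case-(a) traveling wave with phase shift alpha.

    The shape is the three-piece profile restricted to one period, with
    breakpoints ``(0, 0), (alpha, alpha), (sigma+alpha, alpha+(1+eps)sigma),
    (tau, 1)``.  Raises :class:`AlphaNotAdmissibleError` naming the violated
    existence condition.  ``allow_zero`` permits the degenerate alpha = 0
    shape (wave number 0), excluded by default.
    """
    eps = params.epsilon
    if alpha < 0:
        raise AlphaNotAdmissibleError("alpha must be non-negative")
    if alpha == 0 and not allow_zero:
        raise AlphaNotAdmissibleError(
            "alpha = 0 (wave number 0) is a degenerate shape; pass "
            "allow_zero=True to construct it anyway"
        )
    ivs = alpha_intervals(params)
    lo, hi = ivs.existence
    if alpha >= params.a1:
        raise AlphaNotAdmissibleError(
            f"existence requires alpha < a1: alpha={alpha} >= a1={params.a1} "
            "(the wave phase at fast onset must lie inside the response window)"
        )
    if alpha >= hi:
        raise AlphaNotAdmissibleError(
            f"existence requires alpha < {hi}: the forcing must already be "
            "past the stimulus window when the driven phase completes a "
            "revolution (f(tau - alpha) >= a0 fails)"
        )
    t0, t1, sigma, tau = tw_times(params, alpha)
    mid_t = sigma + alpha
    mid_v = alpha + (1 + eps) * sigma
    bp = [alpha * 0, alpha, mid_t, tau]
    vals = [alpha * 0, alpha, mid_v, 1 - alpha * 0]
    # degenerate merges (alpha=0 or sigma=0 or sigma+alpha=tau)
    bp2, vals2 = [bp[0]], [vals[0]]
    for t, v in zip(bp[1:], vals[1:]):
        if t > bp2[-1]:
            bp2.append(t)
            vals2.append(v)
    shape = ForcingSignal(period=tau, profile=PiecewisePath(bp2, vals2))
    shape.validate(tol=max(tol, 0 if shape.exact else 1e-12))
    tw = TravelingWave(
        params=params, alpha=alpha, sigma=sigma, tau=tau, t0=t0, t1=t1,
        shape=shape, case_label="a",
    )
    tw.validate(tol=0 if (shape.exact and is_exact(alpha)) else 1e-12)
    return tw


def classify_tw_case(f: ForcingSignal, alpha, params: ModelParams) -> str:
    """Label a shape by the four-way classification: which of the windows
    are active when the driven phase starts (f(alpha) vs a1) and when it
    completes a revolution (f(tau - alpha) vs a0).

    Returns one of ``"a"`` (f(alpha) < a1 and f(tau-alpha) >= a0), ``"b"``
    (both reversed), ``"c"`` (both >=) or ``"c'"`` (both <).
    """
    tau = f.period
    if not 0 < alpha < tau:
        raise ValueError(f"alpha must lie in (0, tau={tau}); got {alpha}")
    fa = frac_part(f(alpha)) if f(alpha) >= 1 else f(alpha)
    fb = f(tau - alpha)
    below_a1 = fa < params.a1
    above_a0 = fb >= params.a0
    if below_a1 and above_a0:
        return "a"
    if not below_a1 and not above_a0:
        return "b"
    if not below_a1 and above_a0:
        return "c"
    return "c'"
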