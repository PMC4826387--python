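"""Circle/lift arithmetic, piecewise-affine paths, and periodic forcing signals.

Oscillator states live on the circle ``T = R/Z`` but are stored as *lifts*:
unbounded reals whose fractional part is the circle phase.  Crossing an
integer corresponds to completing one revolution (one firing cycle).  Every
trajectory and forcing signal handled by this package is a continuous,
increasing, piecewise-affine function of time represented by breakpoints and
the lift values attained there.

All arithmetic is type-agnostic: if breakpoints, values and parameters are
:class:`fractions.Fraction` (or int) instances, computations stay exact; with
floats, comparisons use a configurable absolute tolerance (default 1e-9 for
validation, 1e-12 for event merging downstream).
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from fractions import Fraction
from numbers import Rational
from pathlib import Path
from typing import Sequence

__all__ = [
    "DEFAULT_TOL",
    "ModelParams",
    "PiecewisePath",
    "ForcingSignal",
    "ChainState",
    "circle_distance",
    "frac_part",
    "make_uniform_forcing",
    "make_forcing_from_profile",
    "time_shift",
    "blend_forcings",
    "write_profile_csv",
    "read_profile_csv",
]

#: default absolute tolerance for continuity / validation checks
DEFAULT_TOL = 1e-9


def is_exact(*values) -> bool:
    """True when every argument is a rational number (int or Fraction)."""
    return all(isinstance(v, Rational) for v in values)


def frac_part(x):
    """Fractional part ``x - floor(x)`` (exact for rationals)."""
    return x - math.floor(x)


def circle_distance(x, y):
    """Distance on the circle between two lift values.

    Returns ``min_k |x - y - k|`` over integers k, a value in ``[0, 1/2]``.
    This is the metric used for every "mod 1" convergence statement.
    """
    d = frac_part(x - y)
    return min(d, 1 - d)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-speed oscillator chain.

    epsilon
        Coupling intensity (dimensionless, > 0); the fast phase speed is
        ``1 + epsilon``.  The natural frequency is normalized to 1.
    a0
        Width of the upstream stimulus window ``[0, a0]`` (mod 1), in (0, 1).
    a1
        Width of the phase-response window ``[0, a1]`` (mod 1), in (0, 1).
    """

    epsilon: float
    a0: float
    a1: float

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if not 0 < self.a0 < 1:
            raise ValueError(f"a0 must lie in (0, 1), got {self.a0}")
        if not 0 < self.a1 < 1:
            raise ValueError(f"a1 must lie in (0, 1), got {self.a1}")

    @property
    def exact(self) -> bool:
        return is_exact(self.epsilon, self.a0, self.a1)

    def as_rational(self, max_denominator: int = 10**6) -> "ModelParams":
        """Nearest rational parameter set (for exact-arithmetic fixtures)."""
        conv = lambda x: Fraction(x).limit_denominator(max_denominator)
        return ModelParams(conv(self.epsilon), conv(self.a0), conv(self.a1))


@dataclass
class PiecewisePath:
    """A continuous, strictly increasing, piecewise-affine lift trajectory.

    Stored as breakpoint times ``t_0 < t_1 < ... < t_n`` and the lift values
    attained there; slopes are derived, which makes the continuity invariant
    structural.  Trajectories of the chain dynamics additionally have slopes
    restricted to ``{1, 1 + epsilon}``.
    """

    breakpoints: list
    values: list
    #: optional event log attached by the simulator: (time, kind) tuples
    events: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if len(self.breakpoints) != len(self.values):
            raise ValueError("breakpoints and values must have equal length")
        if len(self.breakpoints) < 2:
            raise ValueError("a path needs at least two breakpoints")

    # -- basic geometry ---------------------------------------------------

    @property
    def start(self):
        return self.breakpoints[0]

    @property
    def end(self):
        return self.breakpoints[-1]

    @property
    def slopes(self) -> list:
        bp, v = self.breakpoints, self.values
        return [
            (v[i + 1] - v[i]) / (bp[i + 1] - bp[i]) for i in range(len(bp) - 1)
        ]

    @property
    def exact(self) -> bool:
        return is_exact(*self.breakpoints, *self.values)

    def __call__(self, t, tol: float = DEFAULT_TOL):
        """Evaluate the lift at time ``t`` (must lie within the domain)."""
        bp, v = self.breakpoints, self.values
        if t < bp[0] - tol or t > bp[-1] + tol:
            raise ValueError(
                f"time {t} outside path domain [{bp[0]}, {bp[-1]}]"
            )
        t = min(max(t, bp[0]), bp[-1])
        i = bisect_right(bp, t) - 1
        if i >= len(bp) - 1:
            return v[-1]
        m = (v[i + 1] - v[i]) / (bp[i + 1] - bp[i])
        return v[i] + m * (t - bp[i])

    def validate(self, tol: float = DEFAULT_TOL) -> None:
        """Check strict monotonicity in time and value; raise on failure."""
        bp, v = self.breakpoints, self.values
        for i in range(len(bp) - 1):
            if bp[i + 1] <= bp[i]:
                raise ValueError(
                    f"breakpoints not strictly increasing at index {i}"
                )
            if v[i + 1] - v[i] <= 0:
                raise ValueError(f"path not strictly increasing on piece {i}")

    def check_trajectory_invariants(
        self, params: ModelParams, tol: float = DEFAULT_TOL
    ) -> list:
        """Check chain-trajectory structure; return a list of violations.

        Verifies that slopes lie in ``{1, 1+epsilon}`` and alternate, and
        reports any interior slope-1 piece shorter than ``1 - a1``.  The
        length bound is guaranteed whenever fast phases end by the
        oscillator itself leaving its response window; a fast phase cut
        short by the upstream signal can be followed by a shorter slow
        piece, so callers should treat those reports as informational
        unless ``(1 - a0)/(1 + epsilon) >= 1 - a1``.
        """
        problems = []
        fast = 1 + params.epsilon
        slopes = self.slopes
        for i, m in enumerate(slopes):
            if not (abs(m - 1) <= tol or abs(m - fast) <= tol):
                problems.append(f"piece {i} has slope {m} not in {{1, 1+eps}}")
        for i in range(len(slopes) - 1):
            if abs(slopes[i] - slopes[i + 1]) <= tol:
                problems.append(f"pieces {i},{i+1} do not alternate slope")
        for i, m in enumerate(slopes):
            if i == 0 or i == len(slopes) - 1:
                continue  # boundary pieces are truncated by the horizon
            if abs(m - 1) <= tol:
                length = self.breakpoints[i + 1] - self.breakpoints[i]
                if length < 1 - params.a1 - tol:
                    problems.append(
                        f"slow piece {i} has length {length} < 1 - a1"
                    )
        return problems


@dataclass(frozen=True)
class ForcingSignal:
    """A tau-periodic lift ``f`` with ``f(t + tau) = f(t) + 1``.

    The profile stores one fundamental period on ``[0, tau]`` with values
    running from 0 to 1.  A nonzero ``shift`` represents the time-translated
    signal ``R^T f = f(. + T)`` without re-anchoring the profile, so the
    periodic-lift identity survives translation exactly.
    """

    period: float
    profile: PiecewisePath
    shift: float = 0

    @property
    def exact(self) -> bool:
        return (
            is_exact(self.period, self.shift)
            and self.profile.exact
        )

    def __call__(self, t):
        """Evaluate the lift at any time ``t + shift >= 0``."""
        tt = t + self.shift
        k = math.floor(tt / self.period)
        r = tt - k * self.period
        # guard against float residue pushing r to the period boundary
        if r >= self.period:
            k += 1
            r = tt - k * self.period
        if r < 0:
            r = 0
        return self.profile(r) + k

    def value_mod1(self, t):
        return frac_part(self(t))

    def unroll(self, T) -> PiecewisePath:
        """Materialize the lift as a PiecewisePath on ``[0, T]``."""
        if T <= 0:
            raise ValueError("horizon T must be positive")
        bp_out = [0 * self.period]
        vals_out = [self(0)]
        pbp, pv = self.profile.breakpoints, self.profile.values
        k = math.floor(self.shift / self.period)
        while True:
            base = k * self.period - self.shift
            done = False
            for i in range(len(pbp)):
                t = base + pbp[i]
                if t <= bp_out[0]:
                    continue
                if t >= T:
                    bp_out.append(T)
                    vals_out.append(self(T))
                    done = True
                    break
                bp_out.append(t)
                vals_out.append(pv[i] + k)
            if done:
                break
            k += 1
        # drop duplicate breakpoints (profile seam coincides with period end);
        # float rounding can misalign the seam by one ulp, so merge within a
        # relative tolerance in inexact mode
        exact = self.exact
        bp, vals = [bp_out[0]], [vals_out[0]]
        for t, v in zip(bp_out[1:], vals_out[1:]):
            gap = 0 if exact else 1e-12 * max(1.0, abs(float(t)))
            if t - bp[-1] > gap and v > vals[-1]:
                bp.append(t)
                vals.append(v)
        if bp[-1] < T:  # endpoint merged away by the seam tolerance
            bp[-1] = T
            vals[-1] = self(T)
        return PiecewisePath(bp, vals)

    def breakpoint_times(self, t_lo, t_hi) -> list:
        """Profile breakpoint times (translated) falling inside [t_lo, t_hi]."""
        out = []
        k = math.floor((t_lo + self.shift) / self.period) - 1
        while True:
            base = k * self.period - self.shift
            if base > t_hi:
                break
            for t in self.profile.breakpoints[:-1]:
                tt = base + t
                if t_lo <= tt <= t_hi:
                    out.append(tt)
            k += 1
        return out

    def validate(self, tol: float = DEFAULT_TOL) -> None:
        """Check the forcing-signal contract; raise naming the violation."""
        p = self.profile
        p.validate(tol)
        if abs(p.start) > tol:
            raise ValueError("profile must start at time 0")
        if abs(p.end - self.period) > tol:
            raise ValueError(
                f"profile must cover one period: ends at {p.end}, "
                f"period is {self.period}"
            )
        if abs(p.values[0]) > tol:
            raise ValueError(f"f(0) must be 0, got {p.values[0]}")
        if abs(p.values[-1] - 1) > tol:
            raise ValueError(f"f(tau) must be 1, got {p.values[-1]}")
        for i, m in enumerate(p.slopes):
            if m < 1 - tol:
                raise ValueError(
                    f"slope must be >= 1 everywhere; piece {i} has slope {m}"
                )

    def grazing_warnings(self, params: ModelParams, tol: float = DEFAULT_TOL):
        """Flag slope-1 plateaus of the profile ending exactly on a window
        boundary level (a0 or an integer); such signals make the on/off
        condition ambiguous at an instant and are reported, not resolved."""
        warnings = []
        p = self.profile
        for i, m in enumerate(p.slopes):
            if abs(m - 1) > tol:
                continue
            for j in (i, i + 1):
                v = frac_part(p.values[j])
                if abs(v - params.a0) <= tol or min(v, 1 - v) <= tol:
                    warnings.append(
                        "slope-1 piece "
                        f"[{p.breakpoints[i]}, {p.breakpoints[i+1]}] touches "
                        f"window boundary level near value {p.values[j]}"
                    )
        return warnings


@dataclass
class ChainState:
    """Initial phases ``theta_1 ... theta_S`` (site 0 is the forcing)."""

    phases: list

    def __post_init__(self):
        if len(self.phases) < 1:
            raise ValueError("need at least one site")

    def __len__(self):
        return len(self.phases)


# ---------------------------------------------------------------------------
# constructors


def make_uniform_forcing(tau) -> ForcingSignal:
    """The uniform ramp ``g(t) = t / tau`` as a forcing signal.

    Requires ``0 < tau <= 1`` so the slope ``1/tau`` is at least 1.
    """
    if not tau > 0:
        raise ValueError(f"period must be positive, got {tau}")
    if tau > 1:
        raise ValueError(
            f"uniform forcing needs tau <= 1 (slope 1/tau >= 1); got {tau}"
        )
    one = tau / tau  # preserves Fraction-ness
    profile = PiecewisePath([0 * tau, tau], [0 * tau, one])
    return ForcingSignal(period=tau, profile=profile)


def make_forcing_from_profile(
    breakpoints: Sequence, values: Sequence, period=None, tol: float = DEFAULT_TOL
) -> ForcingSignal:
    """Build and validate a forcing signal from one period of its profile."""
    bp = list(breakpoints)
    vals = list(values)
    if period is None:
        period = bp[-1]
    f = ForcingSignal(period=period, profile=PiecewisePath(bp, vals))
    f.validate(tol)
    return f


def time_shift(f: ForcingSignal, T) -> ForcingSignal:
    """The translated signal ``R^T f`` with ``(R^T f)(t) = f(t + T)``."""
    if T < 0:
        raise ValueError("time shift must be non-negative")
    return replace(f, shift=f.shift + T)


def blend_forcings(f: ForcingSignal, g: ForcingSignal, lam) -> ForcingSignal:
    """Convex combination ``(1-lam) f + lam g`` of two same-period signals.

    The slope >= 1, monotonicity and endpoint constraints are all preserved
    under convex combination, so the result is again a valid forcing; this is
    how C1-small perturbations of a wave shape are generated.
    """
    if abs(f.period - g.period) > DEFAULT_TOL:
        raise ValueError("can only blend forcings with equal periods")
    if not 0 <= lam <= 1:
        raise ValueError("blend weight must lie in [0, 1]")
    if f.shift != 0 or g.shift != 0:
        raise ValueError("blend operates on unshifted signals")
    bp = sorted(set(f.profile.breakpoints) | set(g.profile.breakpoints))
    vals = [(1 - lam) * f.profile(t) + lam * g.profile(t) for t in bp]
    return make_forcing_from_profile(bp, vals, period=f.period)


# ---------------------------------------------------------------------------
# I/O: profiles as CSV (t,value) with a JSON sidecar {"period": tau}


def write_profile_csv(f: ForcingSignal, path) -> None:
    path = Path(path)
    lines = ["t,value"]
    for t, v in zip(f.profile.breakpoints, f.profile.values):
        lines.append(f"{float(t)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"period": float(f.period)}))


def read_profile_csv(path) -> ForcingSignal:
    path = Path(path)
    rows = path.read_text().strip().splitlines()
    if rows[0].strip() != "t,value":
        raise ValueError("profile CSV must have header 't,value'")
    bp, vals = [], []
    for row in rows[1:]:
        t, v = row.split(",")
        bp.append(float(t))
        vals.append(float(v))
    sidecar = path.with_suffix(path.suffix + ".json")
    period = json.loads(sidecar.read_text())["period"] if sidecar.exists() else bp[-1]
    return make_forcing_from_profile(bp, vals, period=period)
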