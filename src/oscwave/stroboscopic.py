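"""The period-tau stroboscopic (Poincare) map of the forced single site.

For a tau-periodic forcing f, the map ``F(theta) = theta_1(theta, tau) - 1``
advances the first site by one forcing period and translates back.  It is a
degree-1 lift of an orientation-preserving circle homeomorphism, and for the
two-speed dynamics it is *exactly* piecewise affine with slopes that are
integer powers of ``1 + eps``: slope 1 pieces are rigid rotations,
``(1+eps)^{-1}`` pieces contract, ``(1+eps)^{+1}`` pieces expand.  For a
stable-family wave shape the decomposition has exactly four pieces -- two
rotations interleaved with one contraction and one expansion -- giving one
stable fixed point (the wave phase ``f(alpha)``) and one unstable fixed
point; every other orbit converges to the wave phase.

Breakpoints of the decomposition are found structurally, not numerically:
two initial phases belong to the same affine branch iff their trajectories
share the same event signature (slope pattern plus ordered event kinds), and
the breakpoint between two branches is the intersection of the two fitted
affine maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .core import ForcingSignal, ModelParams, circle_distance, frac_part
from .simulator import ChainState, evolve_site, simulate_chain
from .traveling_wave import TravelingWave

__all__ = [
    "AffinePiece",
    "FixedPoint",
    "StroboscopicMapModel",
    "MapComplexityError",
    "strobe_eval",
    "strobe_decompose",
    "find_fixed_points",
    "classify_stability",
    "rotation_number",
    "iterate_map",
    "composed_site_map",
    "find_unstable_initial",
]


class MapComplexityError(RuntimeError):
    """Raised when the decomposition exceeds the configured piece cap."""


@dataclass(frozen=True)
class AffinePiece:
    """One affine branch ``theta -> slope*theta + intercept`` on [left, right)."""

    left: float
    right: float
    slope: float
    intercept: float

    def __call__(self, theta):
        return self.slope * theta + self.intercept


@dataclass(frozen=True)
class FixedPoint:
    theta: float          # location mod 1 (left endpoint for neutral segments)
    slope: float          # local multiplier
    kind: str             # "stable" | "unstable" | "neutral"
    segment: tuple | None = None   # (left, right) for neutral continua


@dataclass
class StroboscopicMapModel:
    """Ordered affine pieces of the degree-1 lift F on [0, 1)."""

    forcing: ForcingSignal
    params: ModelParams
    pieces: list
    fixed_points: list = field(default_factory=list)

    def __call__(self, theta):
        """Evaluate the lift at any real theta via degree-1 equivariance."""
        n = math.floor(theta)
        fr = theta - n
        for p in self.pieces:
            if p.left <= fr < p.right:
                return p(fr) + n
        return self.pieces[-1](fr) + n

    def iterate(self, theta0, n: int) -> list:
        orbit = [theta0]
        th = theta0
        for _ in range(n):
            th = self(th)
            orbit.append(th)
        return orbit

    def degree_check(self) -> float:
        """|sum slope*length - 1|; zero for an exact degree-1 lift."""
        total = sum(p.slope * (p.right - p.left) for p in self.pieces)
        return abs(total - 1)


def strobe_eval(forcing: ForcingSignal, params: ModelParams, theta):
    """One application of the stroboscopic map: evolve over one period and
    subtract 1.  ``theta`` is a lift value; F commutes with integer shifts."""
    path = evolve_site(forcing, theta, params, forcing.period)
    return path(forcing.period) - 1


def _signature(forcing_path, params: ModelParams, theta, tau):
    """Event signature of the one-period trajectory from theta: the piece
    slope pattern and the ordered event kinds.  Initial phases on the same
    affine branch of F share the same signature."""
    path = evolve_site(forcing_path, theta, params, tau)
    fastslow = tuple(
        "F" if s > 1 + params.epsilon / 2 else "S" for s in path.slopes
    )
    kinds = tuple(kind for _, kind in path.events)
    return (fastslow, kinds), path(tau) - 1


def strobe_decompose(
    forcing: ForcingSignal,
    params: ModelParams,
    *,
    n_grid: int = 256,
    max_pieces: int = 64,
    tol: float = 1e-9,
) -> StroboscopicMapModel:
    """Exact piecewise-affine decomposition of F on [0, 1).

    Sweeps a grid of initial phases, groups them by trajectory event
    signature, fits the affine branch of each group from two sample points,
    and solves adjacent branches' intersections for the exact breakpoints.
    Grid resolution doubles until every branch holds at least three samples;
    a verification pass asserts every sample lies on its fitted branch.
    """
    tau = forcing.period
    U = forcing.unroll(tau)

    grid_n = n_grid
    while True:
        xs = [i / grid_n for i in range(grid_n)]
        sigs, Fs = [], []
        for x in xs:
            sig, Fx = _signature(U, params, x, tau)
            sigs.append(sig)
            Fs.append(Fx)
        # maximal runs of equal signature
        runs = []
        start = 0
        for i in range(1, len(xs)):
            if sigs[i] != sigs[i - 1]:
                runs.append((start, i - 1))
                start = i
        runs.append((start, len(xs) - 1))
        if len(runs) > max_pieces:
            raise MapComplexityError(
                f"stroboscopic map has more than {max_pieces} branches"
            )
        if all(b - a >= 2 for a, b in runs) or grid_n >= 64 * n_grid:
            break
        grid_n *= 2

    # fit each branch from its extreme samples, verify interior samples
    branches = []
    for a, b in runs:
        if b == a:  # isolated sample: slope from neighbors unavailable
            raise MapComplexityError(
                "a branch of the stroboscopic map is narrower than the "
                "finest sweep resolution"
            )
        slope = (Fs[b] - Fs[a]) / (xs[b] - xs[a])
        slope = _snap_slope(slope, params.epsilon, tol)
        pts = list(range(a, b + 1))
        intercept = sum(Fs[i] - slope * xs[i] for i in pts) / len(pts)
        for i in pts:
            if abs(slope * xs[i] + intercept - Fs[i]) > tol:
                raise MapComplexityError(
                    "trajectory event signatures do not separate the affine "
                    "branches at the current resolution"
                )
        branches.append((xs[a], xs[b], slope, intercept))

    # merge branches whose affine maps coincide (signature oversensitivity)
    merged = [branches[0]]
    for l, r, s, c in branches[1:]:
        L, R, S, C = merged[-1]
        if abs(S - s) <= tol and abs(C - c) <= tol:
            merged[-1] = (L, r, S, C)
        else:
            merged.append((l, r, s, c))

    # exact breakpoints: intersection of adjacent affine branches
    pieces = []
    left = 0.0
    for i, (l, r, s, c) in enumerate(merged):
        if i + 1 < len(merged):
            l2, r2, s2, c2 = merged[i + 1]
            if abs(s - s2) <= tol:
                raise MapComplexityError(
                    "adjacent branches with equal slope but distinct "
                    "intercepts: an intermediate branch was missed"
                )
            x = (c2 - c) / (s - s2)
            if not (r - 2 / grid_n <= x <= l2 + 2 / grid_n):
                raise MapComplexityError(
                    "branch intersection escapes its bracketing samples"
                )
            right = x
        else:
            right = 1.0
        pieces.append(AffinePiece(left, right, s, c))
        left = right

    # degree-1 seam: the last branch must meet the first one at the integer.
    # A mismatch means the branch containing theta=0 wraps across the seam;
    # its continuation below 1 is the first branch shifted by the degree.
    seam = pieces[-1](1.0) - (pieces[0](0.0) + 1.0)
    if abs(seam) > max(tol, 1e-8):
        # continuity of the lift pins the hidden branch's value at the seam:
        # B(1) = F(0) + 1; one sample near 1 then determines its slope
        last = pieces[-1]
        anchor = pieces[0](0.0) + 1.0
        x_hi = 1.0 - 1e-9
        _, F_hi = _signature(U, params, x_hi, tau)
        s_w = _snap_slope((anchor - F_hi) / (1.0 - x_hi), params.epsilon, 1e-5)
        c_w = anchor - s_w
        if abs(last.slope - s_w) <= tol:
            raise MapComplexityError(
                "degree-1 seam mismatch not resolvable by a single hidden "
                f"branch at theta=1 (residual {seam})"
            )
        x = (c_w - last.intercept) / (last.slope - s_w)
        probe = (x + 1.0) / 2.0
        _, Fp = _signature(U, params, probe, tau)
        if not (last.left < x < 1.0) or abs(s_w * probe + c_w - Fp) > max(tol, 1e-8):
            raise MapComplexityError(
                "degree-1 seam mismatch: a branch near theta=1 was missed "
                f"(residual {seam})"
            )
        pieces[-1] = AffinePiece(last.left, x, last.slope, last.intercept)
        pieces.append(AffinePiece(x, 1.0, s_w, c_w))

    model = StroboscopicMapModel(forcing=forcing, params=params, pieces=pieces)
    model.fixed_points = find_fixed_points(model, tol=tol)
    return model


def _snap_slope(slope, eps, tol):
    """Snap a fitted slope to the nearest integer power of (1 + eps)."""
    if slope <= 0:
        return slope
    k = round(math.log(slope) / math.log(1 + eps))
    cand = (1 + eps) ** k
    return cand if abs(cand - slope) <= max(tol, 1e-7 * cand) else slope


def find_fixed_points(model: StroboscopicMapModel, tol: float = 1e-9) -> list:
    """Solve ``F(theta) = theta + m`` on every piece; classify by slope.

    Slope < 1: stable; slope > 1: unstable; slope = 1 with integer offset:
    a neutral continuum reported as a segment.
    """
    out = []
    for p in model.pieces:
        if abs(p.slope - 1) <= tol:
            if circle_distance(p.intercept, 0) <= tol:
                out.append(
                    FixedPoint(p.left, p.slope, "neutral", (p.left, p.right))
                )
            continue
        # g(theta) - theta = (slope-1) theta + intercept spans an interval;
        # each integer m inside it yields a fixed point mod 1
        d_l = (p.slope - 1) * p.left + p.intercept
        d_r = (p.slope - 1) * p.right + p.intercept
        lo, hi = min(d_l, d_r), max(d_l, d_r)
        m = math.ceil(lo - tol)
        while m <= hi + tol:
            theta = (m - p.intercept) / (p.slope - 1)
            if p.left - tol <= theta < p.right + tol:
                kind = "stable" if p.slope < 1 else "unstable"
                out.append(FixedPoint(frac_part(theta), p.slope, kind))
            m += 1
    return out


def classify_stability(tw: TravelingWave, tol: float = 1e-12) -> str:
    """Stability of a constructed (case-a) wave from the closed-form
    criterion: stable iff the oscillator leaves its response window before
    the forcing leaves the stimulus window (t1 < t0, i.e. alpha > alpha0);
    the t0 = t1 tie is a neutral boundary.  Constructed waves are never
    unstable (that requires the opposite shape class)."""
    if abs(tw.t1 - tw.t0) <= tol:
        warnings.warn(
            "t0 = t1: wave sits on the stability boundary; classified neutral"
        )
        return "neutral"
    return "stable" if tw.t1 < tw.t0 else "neutral"


@dataclass(frozen=True)
class RotationNumberEstimate:
    value: float
    n_iter: int
    #: difference between full- and half-orbit estimates (convergence check)
    diagnostic: float


def rotation_number(
    forcing: ForcingSignal,
    params: ModelParams,
    n_iter: int = 1000,
    theta0: float = 0.0,
    *,
    model: StroboscopicMapModel | None = None,
) -> RotationNumberEstimate:
    """Average drift per period ``lim F^n(theta)/n`` of the stroboscopic map.

    Estimated as ``(F^n(theta) - theta)/n``; the estimate is independent of
    theta up to O(1/n).  A map with a fixed point (any traveling wave) has
    rotation number exactly zero.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if model is None:
        model = strobe_decompose(forcing, params)
    orbit = model.iterate(theta0, n_iter)
    est = (orbit[-1] - theta0) / n_iter
    half = (orbit[n_iter // 2] - theta0) / max(n_iter // 2, 1)
    return RotationNumberEstimate(value=est, n_iter=n_iter, diagnostic=abs(est - half))


def iterate_map(model: StroboscopicMapModel, theta0, n: int) -> dict:
    """Orbit of the lift with convergence bookkeeping.

    Returns the orbit, the limit mod 1 when the tail is Cauchy, and the
    integer translate m of the limit (lift limit = limit mod 1 + m).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    orbit = model.iterate(theta0, n)
    limit = None
    translate = None
    if n >= 2 and abs(orbit[-1] - orbit[-2]) < 1e-9:
        limit = frac_part(orbit[-1])
        translate = round(orbit[-1] - limit)
    return {"orbit": orbit, "limit_mod1": limit, "translate": translate}


def composed_site_map(
    forcing: ForcingSignal,
    params: ModelParams,
    upstream_initials,
    theta_s,
    n: int,
) -> list:
    """Stroboscopic orbit of site ``s = len(upstream_initials) + 1``:
    ``theta_s(n tau) - n`` for n = 0..n, obtained by direct chain
    simulation (the non-autonomous composition of per-period maps)."""
    tau = forcing.period
    phases = list(upstream_initials) + [theta_s]
    sol = simulate_chain(forcing, ChainState(phases), params, n * tau)
    path = sol.paths[-1]
    return [path(k * tau) - k for k in range(n + 1)]


def find_unstable_initial(
    forcing: ForcingSignal,
    params: ModelParams,
    upstream_initials=(),
    bracket=(0.0, 1.0),
    *,
    precision: float = 1e-10,
    max_iter: int = 60,
    n_periods: int | None = None,
) -> float:
    """Locate the exceptional initial phase of site s by bisection.

    The orbit limit's integer translate m is a step function of the initial
    phase that jumps by 1 exactly at the unstable initial condition; the
    discontinuity is bisected to ``precision``.  ``n_periods`` defaults to
    enough periods for the local expansion rate (1 + eps) to resolve the
    requested precision.
    """
    if n_periods is None:
        n_periods = (
            int(math.ceil(math.log(2.0 / precision) / math.log(1 + params.epsilon)))
            + 20
        )

    def end_value(theta):
        return composed_site_map(forcing, params, upstream_initials, theta, n_periods)[-1]

    lo, hi = bracket
    v_lo, v_hi = end_value(lo), end_value(hi)
    if v_hi - v_lo < 0.5:
        raise ValueError(
            "no unstable point bracketed: orbit translates agree at both "
            f"bracket ends ({v_lo} vs {v_hi})"
        )
    for _ in range(max_iter):
        if hi - lo <= precision:
            break
        mid = (lo + hi) / 2
        if end_value(mid) - v_lo > 0.5:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2
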