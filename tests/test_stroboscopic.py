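"""Stroboscopic-map decomposition, fixed points, stability, composed maps.

Hand-derived worked-set expectations (eps=1/2, a0=3/10, a1=3/5, alpha=2/5,
tau=14/15): F consists of four affine branches
[0, 0.15):   rotation, offset 1/12
[0.15, 0.6): contraction, F = theta/1.5 + 2/15
[0.6, 0.7):  rotation, offset -1/15
[0.7, 1):    expansion, F = 1.5 theta - 5/12
with fixed points 0.4 (stable, slope 2/3) and 5/6 (unstable, slope 3/2).
"""

import math
import warnings
from fractions import Fraction

import numpy as np
import pytest

from oscwave import (
    ModelParams,
    build_tw,
    classify_stability,
    composed_site_map,
    evolve_site,
    find_fixed_points,
    find_unstable_initial,
    iterate_map,
    rotation_number,
    sample_admissible_fixture,
    strobe_decompose,
    strobe_eval,
)
from oscwave.stroboscopic import AffinePiece, StroboscopicMapModel


class TestStrobeEval:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (0.4, 0.4),                    # the wave phase is a fixed point
            (0.0, 1 / 12),                 # eps*(t0 - sigma)
            (0.9, 1.5 * 0.9 - 5 / 12),     # expanding branch
        ],
    )
    def test_worked_values(self, worked_tw, worked_params, theta, expected):
        assert strobe_eval(worked_tw.shape, worked_params, theta) == pytest.approx(
            expected, abs=1e-12
        )

    def test_iterates_match_long_simulation(self, worked_tw, worked_params):
        f, tau = worked_tw.shape, worked_tw.tau
        theta = 0.17
        path = evolve_site(f, theta, worked_params, 5 * tau)
        x = theta
        for n in range(1, 6):
            x = strobe_eval(f, worked_params, x)
            assert x == pytest.approx(path(n * tau) - n, abs=1e-11)


class TestDecomposition:
    def test_worked_four_pieces(self, worked_strobe_model):
        pieces = worked_strobe_model.pieces
        assert len(pieces) == 4
        lefts = [p.left for p in pieces]
        assert lefts == pytest.approx([0.0, 0.15, 0.6, 0.7], abs=1e-9)
        assert [p.slope for p in pieces] == pytest.approx(
            [1.0, 2 / 3, 1.0, 1.5], abs=1e-12
        )
        assert [p.intercept for p in pieces] == pytest.approx(
            [1 / 12, 2 / 15, -1 / 15, -5 / 12], abs=1e-9
        )

    def test_worked_fixed_points(self, worked_strobe_model):
        fps = {fp.kind: fp for fp in worked_strobe_model.fixed_points}
        assert fps["stable"].theta == pytest.approx(0.4, abs=1e-9)
        assert fps["unstable"].theta == pytest.approx(5 / 6, abs=1e-9)

    def test_degree_one_identity(self, worked_strobe_model):
        assert worked_strobe_model.degree_check() <= 1e-12

    def test_model_agrees_with_direct_evaluation(
        self, worked_strobe_model, worked_tw, worked_params
    ):
        for theta in np.linspace(0, 1, 257)[:-1]:
            direct = strobe_eval(worked_tw.shape, worked_params, float(theta))
            assert worked_strobe_model(float(theta)) == pytest.approx(
                direct, abs=1e-12
            )

    def test_random_stable_fixtures_structure(self):
        for seed in range(15):
            params, alpha = sample_admissible_fixture(seed, mode="stable")
            tw = build_tw(params, alpha)
            model = strobe_decompose(tw.shape, params)
            assert model.degree_check() <= 1e-9
            # strictly increasing lift, degree 1
            xs = np.linspace(0, 0.999, 50)
            vals = [model(float(x)) for x in xs]
            assert all(b > a for a, b in zip(vals, vals[1:]))
            assert model(1.0) == pytest.approx(model(0.0) + 1, abs=1e-9)
            # slopes are integer powers of (1 + eps)
            for p in model.pieces:
                k = math.log(p.slope) / math.log(1 + params.epsilon)
                assert abs(k - round(k)) < 1e-6
            # the wave phase sits on a contracting branch
            fa = float(tw.shape(alpha)) % 1.0
            piece = next(p for p in model.pieces if p.left <= fa < p.right)
            assert piece.slope < 1


class TestFixedPoints:
    def test_pure_rotation_has_no_fixed_point(self, worked_tw, worked_params):
        model = StroboscopicMapModel(
            worked_tw.shape, worked_params, [AffinePiece(0.0, 1.0, 1.0, 0.37)]
        )
        assert find_fixed_points(model) == []

    def test_identity_map_reports_neutral_continuum(self, worked_tw, worked_params):
        model = StroboscopicMapModel(
            worked_tw.shape, worked_params, [AffinePiece(0.0, 1.0, 1.0, 0.0)]
        )
        fps = find_fixed_points(model)
        assert len(fps) == 1 and fps[0].kind == "neutral"
        assert fps[0].segment == (0.0, 1.0)


class TestClassifyStability:
    def test_worked_wave_is_stable(self, worked_tw):
        # alpha = 0.4 > alpha0 = 0.2, i.e. t1 = 2/15 < t0 = 3/10
        assert classify_stability(worked_tw) == "stable"

    def test_small_shift_is_neutral(self, worked_params):
        tw = build_tw(worked_params, 0.1)   # below alpha0: sigma = t0 branch
        assert tw.t1 > tw.t0
        assert classify_stability(tw) == "neutral"

    def test_boundary_tie_warns(self, worked_params):
        tw = build_tw(worked_params, 0.2)   # alpha = alpha0 exactly: t0 = t1
        with pytest.warns(UserWarning, match="boundary"):
            assert classify_stability(tw) == "neutral"

    def test_agrees_with_decomposed_local_slope(self):
        for seed in (3, 11, 21):
            params, alpha = sample_admissible_fixture(seed, mode="stable")
            tw = build_tw(params, alpha)
            model = strobe_decompose(tw.shape, params)
            fa = float(tw.shape(alpha)) % 1.0
            piece = next(p for p in model.pieces if p.left <= fa < p.right)
            assert classify_stability(tw) == "stable"
            assert piece.slope < 1


class TestRotationNumber:
    def test_wave_map_has_zero_rotation(self, worked_tw, worked_params, worked_strobe_model):
        est = rotation_number(
            worked_tw.shape, worked_params, n_iter=2000, model=worked_strobe_model
        )
        assert abs(est.value) < 1.5e-3  # bounded orbit: O(1/n) residue

    def test_pure_rotation_recovers_offset(self, worked_tw, worked_params):
        c = 0.237
        model = StroboscopicMapModel(
            worked_tw.shape, worked_params, [AffinePiece(0.0, 1.0, 1.0, c)]
        )
        orbit = model.iterate(0.1, 400)
        assert (orbit[-1] - 0.1) / 400 == pytest.approx(c, abs=1e-12)

    def test_estimate_independent_of_start(self, worked_tw, worked_params, worked_strobe_model):
        n = 500
        e1 = rotation_number(worked_tw.shape, worked_params, n, 0.05,
                             model=worked_strobe_model)
        e2 = rotation_number(worked_tw.shape, worked_params, n, 0.93,
                             model=worked_strobe_model)
        assert abs(e1.value - e2.value) < 2 / n


class TestIterateMap:
    def test_generic_orbit_contracts_to_wave_phase(self, worked_strobe_model):
        out = iterate_map(worked_strobe_model, 0.0, 100)
        assert out["limit_mod1"] == pytest.approx(0.4, abs=1e-9)
        # eventual geometric rate bounded by the contraction slope 2/3
        orbit = out["orbit"]
        errs = [abs(x - round(x - 0.4) - 0.4) for x in orbit[-20:]]
        for a, b in zip(errs, errs[1:]):
            if a > 1e-14:
                assert b / a <= 2 / 3 + 1e-6

    def test_unstable_point_is_fixed(self, worked_strobe_model):
        out = iterate_map(worked_strobe_model, 5 / 6, 50)
        assert all(abs(x - 5 / 6) < 1e-7 for x in out["orbit"][:20])

    def test_wave_phase_is_fixed(self, worked_strobe_model):
        out = iterate_map(worked_strobe_model, 0.4, 50)
        assert all(x == pytest.approx(0.4, abs=1e-12) for x in out["orbit"])


class TestComposedSiteMap:
    def test_site2_and_site3_limits(self, worked_tw, worked_params):
        o2 = composed_site_map(worked_tw.shape, worked_params, [0.37], 0.1, 300)
        assert o2[-1] % 1 == pytest.approx(13 / 15, abs=1e-6)
        o3 = composed_site_map(
            worked_tw.shape, worked_params, [0.37, 0.9], 0.1, 300
        )
        assert o3[-1] % 1 == pytest.approx(4 / 15, abs=1e-6)

    def test_unstable_upstream_blocks_wave_limit(
        self, worked_tw_rational, worked_params_rational
    ):
        # with site 1 pinned exactly on the unstable periodic solution, site 2
        # relaxes to the solution driven by that orbit -- not to f(2 alpha)
        orbit = composed_site_map(
            worked_tw_rational.shape,
            worked_params_rational,
            [Fraction(5, 6)],
            0.1,
            80,
        )
        tail = [float(x) % 1 for x in orbit[-5:]]
        assert max(tail) - min(tail) < 1e-9      # converged to a period-1 state
        assert abs(tail[-1] - 13 / 15) > 0.05    # but not to the wave


class TestFindUnstableInitial:
    def test_site1_unstable_point(self, worked_tw, worked_params):
        th = find_unstable_initial(worked_tw.shape, worked_params)
        assert th == pytest.approx(5 / 6, abs=1e-9)

    def test_site2_with_wave_upstream(self, worked_tw, worked_params):
        # upstream exactly on the wave: site-2 map is the shifted-forcing
        # stroboscopic map, whose unstable point is the time-alpha value of
        # the unstable periodic solution, u(alpha) = 0.3
        th = find_unstable_initial(
            worked_tw.shape, worked_params, upstream_initials=[0.4]
        )
        assert th == pytest.approx(0.3, abs=1e-9)

    def test_u_alpha_by_exact_flow(self, worked_tw_rational, worked_params_rational):
        # independent oracle for the previous test: evolve the unstable
        # periodic solution exactly and read off its value at alpha
        path = evolve_site(
            worked_tw_rational.shape, Fraction(5, 6), worked_params_rational,
            worked_tw_rational.tau,
        )
        assert path(Fraction(2, 5)) == Fraction(13, 10)
        assert path(worked_tw_rational.tau) - 1 == Fraction(5, 6)  # periodic

    def test_perturbations_straddle_the_unstable_point(
        self, worked_tw, worked_params
    ):
        for d, m in ((-1e-6, 0), (+1e-6, 1)):
            orbit = composed_site_map(
                worked_tw.shape, worked_params, [], 5 / 6 + d, 200
            )
            assert orbit[-1] == pytest.approx(0.4 + m, abs=1e-6)

    def test_unbracketed_search_errors(self, worked_tw, worked_params):
        with pytest.raises(ValueError, match="bracket"):
            find_unstable_initial(
                worked_tw.shape, worked_params, bracket=(0.0, 0.2)
            )
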