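"""Exact PL ECT/SECT computation, distances, gluing and decomposition."""

import numpy as np
import pytest

from ect1d.complex_model import (
    SampledCurve,
    arc_length,
    directional_variation,
    single_curve_complex,
)
from ect1d.ect_core import (
    BoundViolationError,
    CompatibleSubset,
    DirectionSet,
    ECTField,
    FieldMismatchError,
    InvalidInputError,
    PiecewiseLinear,
    StepFunction,
    build_compatible_subset,
    ect_distance,
    ect_field,
    ect_field_of_polylines,
    glue_check,
    pl_ect,
    polyline_ecc,
    sect_distance,
    sect_from_ect,
    uniform_directions,
)
from ect1d.synth_shapes import (
    analytic_circle_ect,
    make_circle,
    make_segment,
    make_wave_and_line,
)

from conftest import random_open_curve


class TestStepFunction:
    def test_zero_before_first_breakpoint(self):
        s = StepFunction([0.0, 1.0], [2.0, 1.0])
        assert s(-0.5) == 0.0
        assert s(0.0) == 2.0  # right-continuous: jump lands at the breakpoint
        assert s(1.5) == 1.0

    def test_from_jumps_merges_ties(self):
        s = StepFunction.from_jumps(np.array([1.0, 1.0, 2.0]), np.array([1.0, 1.0, -2.0]))
        assert list(s.breakpoints) == [1.0, 2.0]
        assert list(s.values) == [2.0, 0.0]

    def test_l1_distance_exact(self):
        s1 = StepFunction([0.0, 2.0], [1.0, 0.0])
        s2 = StepFunction([1.0, 3.0], [2.0, 0.0])
        # |diff| is 1 on [0,1), 1 on [1,2), 2 on [2,3)
        assert s1.l1_distance(s2, -1.0, 4.0) == pytest.approx(4.0)

    def test_algebra_roundtrip(self, rng):
        for _ in range(20):
            b1 = np.sort(rng.uniform(-1, 1, 4))
            b2 = np.sort(rng.uniform(-1, 1, 3))
            s1 = StepFunction(b1, rng.integers(-3, 4, 4))
            s2 = StepFunction(b2, rng.integers(-3, 4, 3))
            back = (s1 + s2) - s2
            grid = np.linspace(-1.5, 1.5, 301)
            assert np.array_equal(np.asarray(back(grid)), np.asarray(s1(grid)))


class TestCompatibleSubset:
    def test_minimal_loop_subdivision(self):
        X = make_circle(1.0, 512)
        A = build_compatible_subset(X, eps=7.0)
        assert A.n_points == 2  # vertex + one interior point
        assert len(A.edges) == 2  # two parallel sub-edges
        assert A.euler_characteristic() == 0

    def test_circle_subdivision_count(self):
        X = make_circle(1.0, 8192)
        A = build_compatible_subset(X, eps=0.1)
        assert len(A.edges) == int(np.ceil(2 * np.pi / 0.1))  # 63
        assert A.epsilon_dense < 0.1

    def test_segment_equal_split(self):
        X = make_segment((0, 0), (1, 0), n=100)
        A = build_compatible_subset(X, eps=0.3)
        assert len(A.edges) == 4
        assert np.allclose(A.sub_lengths, 0.25)

    def test_invalid_eps(self, unit_circle):
        with pytest.raises(InvalidInputError):
            build_compatible_subset(unit_circle, eps=0.0)


class TestPlEct:
    def test_triangle_terminal_value_zero(self, rng):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        A = CompatibleSubset(
            points=pts,
            edges=((0, 1), (1, 2), (2, 0)),
            sub_lengths=np.ones(3),
            vertex_index={"a": 0, "b": 1, "c": 2},
            locations=(),
        )
        for _ in range(5):
            v = rng.normal(size=2)
            v /= np.linalg.norm(v)
            s = pl_ect(A, v)
            assert s.terminal_value() == 0.0  # chi of a cycle

    def test_segment_midlevel_count(self):
        pts = np.array([[0.0, 0.0], [0.5, 0.0], [1.0, 0.0]])
        A = CompatibleSubset(
            points=pts,
            edges=((0, 1), (1, 2)),
            sub_lengths=np.full(2, 0.5),
            vertex_index={"a": 0, "b": 2},
            locations=(("e0", 0.5),),
        )
        s = pl_ect(A, [1.0, 0.0])
        assert s(0.6) == 1.0  # 2 vertices - 1 submerged chord
        assert s(-0.1) == 0.0
        assert s(2.0) == 1.0

    def test_value_below_min_projection_is_zero(self, fourier_curve, dirs8):
        E = ect_field(fourier_curve, 0.2, dirs8)
        for step in E.curves:
            assert step(step.breakpoints[0] - 1e-9) == 0.0


class TestEctField:
    def test_circle_profile(self, unit_circle, dirs8):
        E = ect_field(unit_circle, 0.05, dirs8)
        for step in E.curves:
            assert step(0.0) == 1.0  # an arc
            assert step(1.1) == 0.0  # the whole circle, chi = 0
            assert step(-1.1) == 0.0

    def test_segment_terminal_value_one(self, dirs8):
        X = make_segment((0, 0), (1, 0), n=50)
        E = ect_field(X, 0.1, dirs8)
        for step in E.curves:
            assert step.terminal_value() == 1.0

    def test_terminal_value_is_euler_characteristic(self, fourier_curve, dirs8):
        A = build_compatible_subset(fourier_curve, 0.1)
        E = ect_field(fourier_curve, 0.1, dirs8)
        for step in E.curves:
            assert step.terminal_value() == A.euler_characteristic()

    def test_bound_violation(self, unit_circle, dirs8):
        with pytest.raises(BoundViolationError):
            ect_field(unit_circle, 0.1, dirs8, a=0.5)


class TestEctDistance:
    def test_identity_zero(self, unit_circle, dirs8):
        E = ect_field(unit_circle, 0.1, dirs8)
        assert ect_distance(E, E) == 0.0

    def test_wave_line_separation(self):
        wave, line = make_wave_and_line(0.05)
        v = DirectionSet([[0.0, 1.0]])
        a = 1.6
        Ew = ect_field_of_polylines(wave, v, a)
        El = ect_field_of_polylines(line, v, a)
        assert ect_distance(Ew, El) >= 1.0

    def test_two_displaced_points(self):
        # degenerate 0-cell-only shapes: distance in direction (1,0) is delta
        delta = 0.25
        dirs = DirectionSet([[1.0, 0.0], [0.0, 1.0]])
        s1 = StepFunction([0.0], [1.0])
        s2x = StepFunction([delta], [1.0])
        s2y = StepFunction([0.0], [1.0])
        E1 = ECTField(dirs, (s1, s1), 1.0)
        E2 = ECTField(dirs, (s2x, s2y), 1.0)
        assert ect_distance(E1, E2) == pytest.approx(delta)

    def test_direction_mismatch(self, unit_circle):
        E1 = ect_field(unit_circle, 0.1, uniform_directions(8))
        E2 = ect_field(unit_circle, 0.1, uniform_directions(16))
        with pytest.raises(FieldMismatchError):
            ect_distance(E1, E2)

    def test_monotone_refinement_towards_analytic(self, unit_circle, dirs8):
        # nested (power-of-two) subdivisions so refinement only adds vertices
        ref = analytic_circle_ect(1.0, dirs8, 1.2)
        dists = []
        for k in (15, 31, 63, 127):  # yields 16, 32, 64, 128 sub-edges
            E = ect_field(unit_circle, 2 * np.pi / k, dirs8, a=1.2)
            dists.append(ect_distance(E, ref))
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(dists, dists[1:]))


class TestSect:
    def test_single_point_closed_form(self):
        # ECC of a point at the origin with a = 1: indicator of t >= 0.
        # SECT(t) = -(t+1)/2 below 0 and (t-1)/2 ... i.e. -1/2 at 0, 0 at +-1.
        dirs = DirectionSet([[1.0, 0.0]])
        E = ECTField(dirs, (StepFunction([0.0], [1.0]),), 1.0)
        S = sect_from_ect(E)
        pl = S.curves[0]
        assert pl(-1.0) == pytest.approx(0.0)
        assert pl(0.0) == pytest.approx(-0.5)
        assert pl(1.0) == pytest.approx(0.0, abs=1e-12)
        assert pl(-0.5) == pytest.approx(-0.25)

    def test_endpoints_vanish(self, fourier_curve, dirs8):
        S = sect_from_ect(ect_field(fourier_curve, 0.1, dirs8))
        for pl in S.curves:
            assert abs(pl.values[0]) < 1e-12
            assert abs(pl.values[-1]) < 1e-9

    def test_sect_distance_linearity(self, unit_circle, dirs8):
        S = sect_from_ect(ect_field(unit_circle, 0.1, dirs8))
        doubled = type(S)(
            S.directions,
            tuple(PiecewiseLinear(c.knots, 2 * c.values) for c in S.curves),
            S.a,
        )
        norm = max(c.l1_norm() for c in S.curves)
        assert sect_distance(S, doubled) == pytest.approx(norm, rel=1e-12)

    def test_sect_distance_vs_quadrature(self, rng, dirs8):
        from ect1d.synth_shapes import make_fourier_curve, random_fourier_spec

        X1 = make_fourier_curve(random_fourier_spec(1, n_samples=300))
        X2 = make_fourier_curve(random_fourier_spec(2, n_samples=300))
        a = 1.05 * max(X1.max_norm(), X2.max_norm())
        S1 = sect_from_ect(ect_field(X1, 0.2, dirs8, a=a))
        S2 = sect_from_ect(ect_field(X2, 0.2, dirs8, a=a))
        exact = sect_distance(S1, S2)
        grid = np.linspace(-a, a, 200_001)
        quad = max(
            np.trapezoid(np.abs(np.asarray(c1(grid)) - np.asarray(c2(grid))), grid)
            for c1, c2 in zip(S1.curves, S2.curves)
        )
        assert exact == pytest.approx(quad, abs=1e-5)

    def test_sect_ect_factor(self, dirs8):
        # SECT distances are bounded by (2a+1) times ECT distances
        from ect1d.stability_bounds import sect_factor
        from ect1d.synth_shapes import make_fourier_curve, random_fourier_spec

        for seed in range(5):
            X1 = make_fourier_curve(random_fourier_spec(seed, n_samples=300))
            X2 = make_fourier_curve(random_fourier_spec(seed + 50, n_samples=300))
            a = 1.05 * max(X1.max_norm(), X2.max_norm())
            E1 = ect_field(X1, 0.15, dirs8, a=a)
            E2 = ect_field(X2, 0.15, dirs8, a=a)
            d_ect = ect_distance(E1, E2)
            d_sect = sect_distance(sect_from_ect(E1), sect_from_ect(E2))
            assert d_sect <= sect_factor(a) * d_ect + 1e-9


class TestGluing:
    def test_point_identity(self):
        s = StepFunction([0.0], [1.0])
        assert glue_check(s, s, s, s)

    def test_two_segments_glued_at_endpoint(self, dirs8):
        p_mid = np.array([1.0, 1.0])
        seg1 = np.array([[0.0, 0.0], [0.5, 0.6], p_mid])
        seg2 = np.array([p_mid, [1.5, 0.4], [2.0, 0.0]])
        union = np.vstack([seg1, seg2[1:]])
        for v in dirs8.vectors:
            e_v = polyline_ecc(seg1, v)
            e_w = polyline_ecc(seg2, v)
            e_s = StepFunction.from_jumps(np.array([p_mid @ v]), np.array([1.0]))
            e_z = polyline_ecc(union, v)
            assert glue_check(e_v, e_w, e_s, e_z)

    def test_circle_split_into_arcs(self, dirs8):
        n = 64
        th_up = np.linspace(0, np.pi, n)
        th_dn = np.linspace(np.pi, 2 * np.pi, n)
        upper = np.column_stack([np.cos(th_up), np.sin(th_up)])
        lower = np.column_stack([np.cos(th_dn), np.sin(th_dn)])
        lower[-1] = upper[0]
        circle = np.vstack([upper, lower[1:]])
        for v in dirs8.vectors:
            e_v = polyline_ecc(upper, v)
            e_w = polyline_ecc(lower, v)
            e_s = StepFunction.from_jumps(
                np.array([upper[0] @ v, upper[-1] @ v]), np.array([1.0, 1.0])
            )
            e_z = polyline_ecc(circle, v, closed=True)
            assert glue_check(e_v, e_w, e_s, e_z)


class TestDecomposition:
    """The PL transform equals the sum of chord transforms minus
    (degree - 1) point transforms, almost everywhere."""

    @pytest.mark.parametrize("seed", range(6))
    def test_against_independent_rhs(self, seed):
        from ect1d.synth_shapes import make_fourier_curve, random_fourier_spec

        X = make_fourier_curve(random_fourier_spec(seed, n_samples=300))
        A = build_compatible_subset(X, 0.3)
        c = A.degrees()
        dirs = uniform_directions(16)
        for v in dirs.vectors:
            proj = A.points @ v
            lhs = pl_ect(A, v)
            # independent right-hand side: chords jump at their minimum
            # projection, points at their own projection
            positions = []
            jumps = []
            for i, j in A.edges:
                positions.append(min(proj[i], proj[j]))
                jumps.append(1.0)
            for i in range(A.n_points):
                positions.append(proj[i])
                jumps.append(-(c[i] - 1.0))
            rhs = StepFunction.from_jumps(np.array(positions), np.array(jumps))
            assert glue_check(lhs, StepFunction([], []), StepFunction([], []), rhs)


class TestEquivarianceAndBounds:
    def test_rotation_equivariance(self, fourier_curve, dirs8):
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        E = ect_field_of_polylines(fourier_curve, dirs8, a=3.0)
        E_rot = ect_field_of_polylines(fourier_curve.rotated(R), dirs8.rotated(R), a=3.0)
        for s1, s2 in zip(E.curves, E_rot.curves):
            assert np.allclose(s1.breakpoints, s2.breakpoints, atol=1e-9)
            assert np.array_equal(s1.values, s2.values)

    @pytest.mark.parametrize("seed", range(25))
    def test_variation_bounds_ecc_mass(self, seed):
        # integral of |ECC| between directional min and max is at most the
        # directional variation of the projection
        rng = np.random.default_rng(seed)
        curve = random_open_curve(seed)
        for _ in range(2):
            v = rng.normal(size=2)
            v /= np.linalg.norm(v)
            ecc = polyline_ecc(curve.points, v)
            proj = curve.points @ v
            zero = StepFunction([], [])
            mass = ecc.l1_distance(zero, proj.min(), proj.max())
            assert mass <= directional_variation(curve, v) + 1e-9
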