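import math

import numpy as np
import pytest

from sphellipse import (
    Branch,
    contact_function,
    interpolated_form,
    make_ellipse,
    maximize_lambda1,
    minimize_lambda2_interior,
    omega,
    overlap,
    quadratic_form,
    sign_test,
)
from sphellipse.contact import IndeterminateSignError
from sphellipse.cli_io import random_pair
from sphellipse.eigen3 import eigvals_sym3
from sphellipse.oracle import circle_contact_reference
from conftest import pair_stream, random_rotation


def circle(theta, rho, azimuth=0.0):
    """Circle of geodesic radius rho centered at polar angle theta."""
    c = [math.sin(theta) * math.cos(azimuth), math.sin(theta) * math.sin(azimuth), math.cos(theta)]
    axis = [math.cos(theta), 0, -math.sin(theta)] if abs(theta) > 1e-9 else [1, 0, 0]
    return make_ellipse(c, axis, rho, rho)


def forms(eA, eB):
    return quadratic_form(eA).matrix, quadratic_form(eB).matrix


class TestInterpolatedForm:
    def test_endpoints_and_average(self):
        A = np.diag([4.0, 4.0, 0.0])
        B = np.diag([2.0, 2.0, 0.0])
        assert np.allclose(interpolated_form(A, B, 0.0), A)
        assert np.allclose(interpolated_form(A, B, 1.0), B)
        assert np.allclose(interpolated_form(A, B, 0.5), np.diag([3.0, 3.0, 0.0]))

    def test_convex_combination_stays_psd(self, rng):
        fx = random_pair(11)
        A, B = forms(fx.eA, fx.eB)
        for t in rng.uniform(0, 1, size=20):
            assert min(eigvals_sym3(interpolated_form(A, B, t))) > -1e-12


class TestMaximizeLambda1:
    def test_identical_forms_flat_band(self):
        e = circle(0.0, 0.5)
        A, _ = forms(e, e)
        res = maximize_lambda1(A, A)
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_tangent_equal_circles_unit_value(self):
        res = maximize_lambda1(*forms(circle(0, math.pi / 6), circle(math.pi / 3, math.pi / 6)))
        assert res.value == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("method", ["brent", "gss"])
    def test_matches_dense_grid_scan(self, method):
        for fx in pair_stream(15, start_seed=100):
            A, B = forms(fx.eA, fx.eB)
            res = maximize_lambda1(A, B, method=method)
            grid = max(
                eigvals_sym3(interpolated_form(A, B, t))[0] for t in np.linspace(0, 1, 10_001)
            )
            assert res.value == pytest.approx(grid, abs=1e-6)

    def test_early_exit_gives_lower_bound_only(self):
        # clearly separated circles: Lambda1 >> 1
        A, B = forms(circle(0, 0.2), circle(2.0, 0.2))
        res = maximize_lambda1(A, B, early_exit_above=1.0)
        assert res.early_exit
        assert res.value > 1.0
        assert res.vector is None
        full = maximize_lambda1(A, B)
        assert res.n_evals <= full.n_evals
        assert res.value <= full.value + 1e-12

    def test_unimodality_of_lowest_band(self):
        # the lowest band must have a single interior maximum
        for fx in pair_stream(40, start_seed=300):
            A, B = forms(fx.eA, fx.eB)
            vals = np.array(
                [eigvals_sym3(interpolated_form(A, B, t))[0] for t in np.linspace(0, 1, 513)]
            )
            d = np.sign(np.diff(vals))
            switches = np.count_nonzero(np.diff(d[d != 0]))
            assert switches <= 1


class TestMinimizeLambda2:
    def test_equal_circles_beyond_halfpi(self):
        A, B = forms(circle(0, math.pi / 6), circle(2.0, math.pi / 6))
        res = minimize_lambda2_interior(A, B)
        assert res is not None
        assert res.value == pytest.approx(circle_contact_reference(4.0, 4.0, 2.0), abs=1e-8)

    def test_matches_grid_scan_when_present(self):
        found = 0
        for fx in pair_stream(40, start_seed=900):
            A, B = forms(fx.eA, fx.eB)
            ts = np.linspace(0, 1, 20_001)
            band = np.array([eigvals_sym3(interpolated_form(A, B, t))[1] for t in ts])
            i = int(np.argmin(band))
            res = minimize_lambda2_interior(A, B)
            if 0 < i < len(ts) - 1 and band[i] < min(band[0], band[-1]) - 1e-10:
                assert res is not None
                assert res.value == pytest.approx(band[i], abs=1e-6)
                found += 1
        assert found >= 3  # the stream must actually exercise the branch

    def test_identical_forms_constant_band_absent(self):
        e = circle(0.3, 0.4)
        A, _ = forms(e, e)
        assert minimize_lambda2_interior(A, A) is None


class TestSignTest:
    def test_same_direction_true(self):
        r = np.array([0.0, 0.0, 1.0])
        assert sign_test(r, r, r)

    def test_antipodal_contact_false(self):
        r = np.array([0.0, 0.0, 1.0])
        assert not sign_test(r, r, -r)

    def test_invariant_under_negation(self, rng):
        v, ra, rb = (x / np.linalg.norm(x) for x in rng.normal(size=(3, 3)))
        assert sign_test(v, ra, rb) == sign_test(-v, ra, rb)

    def test_orthogonal_flagged(self):
        with pytest.raises(IndeterminateSignError):
            sign_test([1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0])


class TestOmega:
    def test_min_of_nonzero_eigenvalues(self):
        e1 = make_ellipse([0, 0, 1], [1, 0, 0], 0.5, 0.15)  # eigs ~ (4.35, 44.8)
        e2 = circle(1.0, math.pi / 6)  # eigs (4, 4)
        assert omega(*forms(e1, e2)) == pytest.approx(4.0, abs=1e-9)

    def test_equal_circles(self):
        assert omega(*forms(circle(0, math.pi / 6), circle(1.0, math.pi / 6))) == pytest.approx(4.0)

    def test_always_above_one(self):
        for fx in pair_stream(20, start_seed=50):
            assert omega(*forms(fx.eA, fx.eB)) > 1.0


class TestContactFunction:
    def test_tangent_equal_circles(self):
        res = contact_function(circle(0, math.pi / 6), circle(math.pi / 3, math.pi / 6))
        assert res.F == pytest.approx(1.0, abs=1e-9)
        assert res.branch is Branch.LAMBDA1
        assert not res.overlap

    def test_antipodal_branch_equal_circles(self):
        res = contact_function(circle(0, math.pi / 6), circle(2.0, math.pi / 6))
        assert res.branch is Branch.LAMBDA2
        assert res.F == pytest.approx(circle_contact_reference(4.0, 4.0, 2.0), abs=1e-9)

    def test_omega_clip_unequal_circles(self):
        # alpha=4, beta=2 at theta=3.0: past the Eq-maximum, no valid contact
        eA = circle(0, math.asin(0.5))
        eB = circle(3.0, math.asin(1 / math.sqrt(2)))
        res = contact_function(eA, eB)
        assert res.branch is Branch.OMEGA
        assert res.F == pytest.approx(2.0, abs=1e-9)
        assert res.v is None and res.t_star is None

    def test_identical_ellipses_complete_overlap(self):
        e = make_ellipse([0.1, 0.2, 1], [1, 0, 0], 0.5, 0.2)
        res = contact_function(e, e)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.overlap

    def test_result_invariants(self):
        for fx in pair_stream(50, start_seed=2000):
            res = contact_function(fx.eA, fx.eB)
            assert res.F > 0 or res.F == 0.0
            assert res.overlap == (res.F < 1.0)
            assert res.F <= res.omega * (1 + 1e-9)
            if res.branch is not Branch.OMEGA:
                A, B = forms(fx.eA, fx.eB)
                # tangency of both grown forms at the contact point
                assert abs(float(res.v @ A @ res.v) - res.F) < 1e-6
                assert abs(float(res.v @ B @ res.v) - res.F) < 1e-6
                # stationarity (envelope condition) at the selected extremum
                assert abs(float(res.v @ (B - A) @ res.v)) < 1e-5
                # normals of the grown ellipses are antiparallel
                if res.n_a is not None and res.n_b is not None:
                    assert np.linalg.norm(np.cross(res.n_a, res.n_b)) < 1e-5
                    assert float(res.n_a @ res.n_b) < 0

    def test_pair_exchange_symmetry(self):
        for fx in pair_stream(30, start_seed=4000):
            r1 = contact_function(fx.eA, fx.eB)
            r2 = contact_function(fx.eB, fx.eA)
            assert r1.F == pytest.approx(r2.F, abs=1e-9)
            if r1.t_star is not None and r2.t_star is not None:
                assert r1.t_star == pytest.approx(1 - r2.t_star, abs=1e-4)

    def test_global_rotation_invariance(self, rng):
        for fx in pair_stream(15, start_seed=6000):
            F0 = contact_function(fx.eA, fx.eB).F
            R = random_rotation(rng)
            eAr = make_ellipse(R @ fx.eA.center, R @ fx.eA.major_axis, fx.eA.xi1, fx.eA.xi2)
            eBr = make_ellipse(R @ fx.eB.center, R @ fx.eB.major_axis, fx.eB.xi1, fx.eB.xi2)
            assert contact_function(eAr, eBr).F == pytest.approx(F0, abs=1e-9)

    def test_continuity_along_separation_path(self):
        # rotate one ellipse through all three branches; F must stay
        # continuous (branch switches included)
        xi1, xi2 = 0.5, 0.2
        eA = make_ellipse([0, 0, 1], [0.3, 1, 0], xi1, xi2)
        Fs, branches = [], []
        thetas = np.arange(0.25, 3.0, 1e-3)
        for th in thetas:
            eB = make_ellipse([math.sin(th), 0, math.cos(th)], [0.2, 1, 0.1], xi1, xi2)
            r = contact_function(eA, eB)
            Fs.append(r.F)
            branches.append(r.branch)
        Fs = np.array(Fs)
        d1 = np.abs(np.diff(Fs))
        assert d1.max() < 50 * 1e-3  # bounded slope, no jumps
        for i in range(1, len(branches)):
            if branches[i] != branches[i - 1]:
                assert d1[i - 1] < 1e-3  # switches sit where the branches agree
        assert len(set(branches)) == 3  # the path truly exercises all branches


class TestOverlap:
    def test_circles_below_and_above_radius_sum(self):
        rho = math.pi / 6
        assert overlap(circle(0, rho), circle(0.9 * 2 * rho, rho))
        assert not overlap(circle(0, rho), circle(1.1 * 2 * rho, rho))

    def test_antipodal_pair_not_overlapping(self):
        # quadratic-form level sets collide (antipode contact) but the true
        # ellipses are on opposite sides of the sphere
        eA = make_ellipse([0, 0, 1], [1, 0, 0], 0.3, 0.1)
        th = math.pi - 0.05
        eB = make_ellipse([math.sin(th), 0, math.cos(th)], [1, 0, 0], 0.3, 0.1)
        assert not overlap(eA, eB)

    def test_agrees_with_contact_function(self):
        for fx in pair_stream(60, start_seed=8000):
            assert overlap(fx.eA, fx.eB) == contact_function(fx.eA, fx.eB).overlap
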