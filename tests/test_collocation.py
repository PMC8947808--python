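"""Radau IIA schemes, implicit stepping, transcription, interpolation."""
import numpy as np
import pytest
import scipy.integrate

import fluxnlp as F
from fluxnlp.collocation import stability_function
from fluxnlp.network import NetworkError


@pytest.fixture(scope="module", params=[3, 5, 9])
def scheme(request):
    return F.radau_iia(request.param)


class TestSchemes:
    def test_invariants_to_1e12(self, scheme):
        s = scheme
        assert abs(s.c[-1] - 1.0) <= 1e-12           # right endpoint is a node
        assert abs(s.b.sum() - 1.0) <= 1e-12          # consistency
        assert np.abs(s.a[-1] - s.b).max() <= 1e-12   # stiffly accurate
        assert np.abs(s.B(0.0)).max() <= 1e-12        # B_a(0) = 0
        assert np.abs(s.B(1.0) - s.b).max() <= 1e-12  # B_a(1) = b_a
        assert s.order == 2 * s.s - 1

    def test_basis_reproduces_rk_matrix_at_nodes(self, scheme):
        # collocation identity: B_a(c_b) = a_{b a}
        for b_ in range(scheme.s):
            assert np.abs(scheme.B(scheme.c[b_]) - scheme.a[b_]).max() <= 1e-12

    def test_two_stage_nodes_are_third_and_one(self):
        s = F.radau_iia(3)
        assert s.c == pytest.approx([1.0 / 3.0, 1.0], abs=1e-12)

    def test_unsupported_order(self):
        with pytest.raises(NetworkError):
            F.radau_iia(7)

    def test_l_stability_damps_fast_modes(self, scheme):
        assert abs(stability_function(scheme, -1e8)) < 1e-6
        # A-stability on the negative real axis
        for z in (-0.1, -1.0, -10.0, -100.0):
            assert abs(stability_function(scheme, z)) < 1.0


class TestStepping:
    def test_linear_step_matches_stability_function(self, scheme):
        lam, h, x0 = -2.3, 0.7, 1.0
        f = lambda t, x: lam * x
        jac = lambda t, x: np.array([[lam]])
        x1, K, k = F.radau_step(f, jac, np.array([x0]), 0.0, h, scheme)
        assert x1[0] == pytest.approx(stability_function(scheme, lam * h) * x0,
                                      abs=1e-12)

    def test_convergence_order_on_smooth_nonlinear_ode(self, scheme):
        """Endpoint error scales as h^(2s-1): log-log slope within 15%."""
        f = lambda t, x: np.array([-1.5 * x[0] + np.sin(2.0 * x[0])
                                   + np.cos(3 * t)])
        jac = lambda t, x: np.array([[-1.5 + 2.0 * np.cos(2.0 * x[0])]])
        T = 3.0
        ref = scipy.integrate.solve_ivp(f, (0, T), [0.3], method="Radau",
                                        rtol=1e-13, atol=1e-15).y[0, -1]
        errs, hs = [], []
        sizes = {3: [4, 8, 16, 32], 5: [2, 4, 8, 16], 9: [2, 3, 4, 6]}[scheme.order]
        for n in sizes:
            grid = F.TimeGrid(np.linspace(0, T, n + 1))
            xs, _ = F.radau_integrate(f, jac, np.array([0.3]), grid, scheme)
            errs.append(abs(xs[-1, 0] - ref))
            hs.append(T / n)
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        expected = 2 * scheme.s - 1
        assert abs(slope - expected) <= 0.15 * expected

    def test_stage_derivatives_are_transcription_variables(self, scheme):
        f = lambda t, x: np.array([-x[0]])
        jac = lambda t, x: np.array([[-1.0]])
        grid = F.TimeGrid([0.0, 0.5, 1.5])
        xs, ks = F.radau_integrate(f, jac, np.array([1.0]), grid, scheme)
        system = F.transcribe(grid, scheme, 1)
        for g in range(grid.n_intervals):
            K = system.stage_states(xs[g], ks[g], grid.h[g])
            # stage balance: k = f(K)
            for a in range(scheme.s):
                assert ks[g][a, 0] == pytest.approx(-K[a, 0], abs=1e-10)
            # update equation reproduces the next node
            assert system.update(xs[g], ks[g], grid.h[g])[0] == \
                pytest.approx(xs[g + 1, 0], abs=1e-12)


class TestTimeGridAndInterpolation:
    def test_grid_validation(self):
        with pytest.raises(NetworkError):
            F.TimeGrid([0.0, 0.0, 1.0])
        with pytest.raises(NetworkError):
            F.TimeGrid([0.0])

    def test_measurement_on_node_assigned_left_interval(self):
        grid = F.TimeGrid([0.0, 1.0, 3.0])
        gamma, tau = grid.locate(1.0)
        assert gamma == 1 and tau == pytest.approx(1.0)
        gamma, tau = grid.locate(2.0)
        assert gamma == 2 and tau == pytest.approx(0.5)
        with pytest.raises(NetworkError):
            grid.locate(3.5)
        with pytest.raises(NetworkError):
            grid.locate(0.0)

    def test_geometric_grid_widens(self):
        grid = F.geometric_grid(20.0, 5, ratio=2.0)
        assert grid.nodes[0] == 0.0 and grid.nodes[-1] == pytest.approx(20.0)
        assert (np.diff(grid.h) > 0).all()

    def test_interpolation_endpoints_and_stages(self, scheme):
        f = lambda t, x: np.array([-1.7 * x[0]])
        jac = lambda t, x: np.array([[-1.7]])
        grid = F.TimeGrid([0.0, 0.8, 2.0])
        xs, ks = F.radau_integrate(f, jac, np.array([1.0]), grid, scheme)
        system = F.transcribe(grid, scheme, 1)
        # tau = 1 reproduces the interval-end node
        assert F.interpolate_at(system, xs, ks, 0.8)[0] == \
            pytest.approx(xs[1, 0], abs=1e-12)
        # tau = c_a reproduces the stage states
        K = system.stage_states(xs[0], ks[0], grid.h[0])
        for a in range(scheme.s):
            t_a = 0.0 + scheme.c[a] * grid.h[0]
            assert F.interpolate_at(system, xs, ks, t_a)[0] == \
                pytest.approx(K[a, 0], abs=1e-12)

    def test_interior_points_match_dense_integration(self):
        scheme = F.radau_iia(9)
        f = lambda t, x: np.array([-x[0] + np.cos(t)])
        jac = lambda t, x: np.array([[-1.0]])
        grid = F.TimeGrid(np.linspace(0.0, 3.0, 7))
        xs, ks = F.radau_integrate(f, jac, np.array([0.0]), grid, scheme)
        system = F.transcribe(grid, scheme, 1)
        ref = scipy.integrate.solve_ivp(f, (0, 3.0), [0.0], method="Radau",
                                        rtol=1e-12, atol=1e-14,
                                        dense_output=True)
        for t in np.linspace(0.1, 2.9, 15):
            assert abs(F.interpolate_at(system, xs, ks, float(t))[0] -
                       ref.sol(t)[0]) <= 1e-6


class TestTranscription:
    def test_variable_and_constraint_counts(self):
        system = F.transcribe(F.TimeGrid([0.0, 1.0, 2.0]), F.radau_iia(5), 32)
        G, s, n = 2, 3, 32
        assert system.n_vars_full == n * (1 + G * (2 * s + 1))
        assert system.n_constraints_full == 2 * G * s * n + G * n
        assert system.n_vars_reduced == n * G * (s + 1)
        assert system.n_constraints_reduced == G * (s + 1) * n

    def test_empty_grid_rejected(self):
        with pytest.raises(NetworkError):
            F.transcribe(F.TimeGrid([0.0]), F.radau_iia(3), 4)


class TestStiffStability:
    def test_overwide_first_interval_recovers_in_second(self, toy_study,
                                                        toy_truth):
        """An over-wide first interval is inaccurate, yet the second interval
        approaches the true steady state (the hallmark of stiff accuracy)."""
        v, p = toy_truth
        bound, pools = toy_study.bound, toy_study.pools
        p_k = pools.state_pools(p)
        inv_p = 1.0 / p_k
        f = lambda t, x: inv_p * bound.production(x, v)
        jac = lambda t, x: np.diag(inv_p) @ bound.jac_x(x, v).toarray()
        scheme = F.radau_iia(5)
        grid = F.TimeGrid([0.0, 10.0, 20.0])
        xs, ks = F.radau_integrate(f, jac, toy_study.x_init, grid, scheme)
        ref = F.integrate_labeling(bound, v, p_k,
                                   np.array([0.0, 2.5, 5.0, 7.5, 10.0, 20.0]),
                                   toy_study.x_init, dt=0.005)
        system = F.transcribe(grid, scheme, bound.n)
        err_first = max(
            np.abs(F.interpolate_at(system, xs, ks, t) - ref.at([t])[0]).max()
            for t in (2.5, 5.0, 7.5))
        err_final = np.abs(xs[2] - ref.at([20.0])[0]).max()
        x_ss = F.solve_steady_state(bound, v)
        assert err_final <= 0.02                        # accurate second interval
        assert np.abs(xs[2] - x_ss).max() <= 0.05       # approaches steady state
        assert err_first >= 10 * err_final              # poor first interval
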