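"""NLP assembly and solving: steady-state and nonstationary estimation."""
import dataclasses

import numpy as np
import pytest

import fluxnlp as F
from fluxnlp.network import NetworkError
from fluxnlp.measure import MeasurementModel


def _steady_mm(study, v, sd=0.01):
    """Noise-free steady-state measurement table at flux vector v."""
    x = F.solve_steady_state(study.bound, v)
    mm = study.mm
    vals = mm.simulate(x)[:, None]
    return dataclasses.replace(mm, times=np.zeros(0), values=vals,
                               sd=np.full_like(vals, sd))


def _one_pool_study():
    net = F.apply_config(
        F.parse_network("vin: S (a) -> A (a)\nvout: A (a) -> P (a)"),
        {"inputs": ["S"], "outputs": ["P"],
         "bounds": {"default": [0, 10], "vin": [1, 1]},
         "pool_bounds": {"default": [0.1, 10]}})
    net = F.split_reversible(net)
    arrays = F.build_model_arrays(net, "cumomer")
    tracers = {"S": [{"fraction": 1.0, "atoms": "U", "enrichment": 1.0}]}
    bound = F.bind_inputs(arrays, F.build_input_vector(net, arrays, tracers, 0.0))
    pools = F.build_pool_model(net, arrays)
    x0 = F.initial_state(net, arrays, 0.0)
    return net, arrays, bound, pools, x0


class TestSteadyNLP:
    def test_noise_free_data_gives_zero_residual(self, toy_study, toy_truth):
        v, _ = toy_truth
        prob = F.assemble_steady_nlp(toy_study.net, toy_study.bound,
                                     _steady_mm(toy_study, v))
        fit = F.solve_nlp(prob, prob.initial_point(v))
        assert fit.z <= 1e-10
        assert fit.feasibility <= 1e-7
        assert fit.ok

    def test_random_start_recovers_zero_residual(self, toy_study, toy_truth):
        v, _ = toy_truth
        prob = F.assemble_steady_nlp(toy_study.net, toy_study.bound,
                                     _steady_mm(toy_study, v))
        fit = F.solve_nlp(prob, prob.sample_start(3))
        assert fit.z <= 1e-6

    def test_scaling_factors_fixed_when_mids_complete(self, toy_study,
                                                      toy_truth):
        v, _ = toy_truth
        prob = F.assemble_steady_nlp(toy_study.net, toy_study.bound,
                                     _steady_mm(toy_study, v), scaling="fixed")
        assert prob.nh == 0
        prob_h = F.assemble_steady_nlp(toy_study.net, toy_study.bound,
                                       _steady_mm(toy_study, v),
                                       scaling="per_fragment")
        assert prob_h.nh == len(toy_study.mm.fragments)

    def test_variable_and_constraint_counts_two_reaction_fixture(self):
        net, arrays, bound, pools, x0 = _one_pool_study()
        mm = F.build_measurement_model(net, arrays, [F.FragmentDef("A1", "A", (1,))])
        vals = mm.simulate(F.solve_steady_state(bound, np.ones(2)))[:, None]
        mm = dataclasses.replace(mm, values=vals, sd=np.full_like(vals, 0.01))
        prob = F.assemble_steady_nlp(net, bound, mm)
        d = prob.describe()
        # 2 fluxes + 1 cumomer state; balance row for the state + 1 stoich row
        assert d["blocks"] == {"v": 2, "h": 0, "x": 1}
        assert d["n_vars"] == 3
        assert d["n_eq"] == 2


class TestInstNLP:
    def test_counts_match_hand_count_on_one_pool_fixture(self):
        net, arrays, bound, pools, x0 = _one_pool_study()
        times = [0.5, 1.5]
        mm = F.build_measurement_model(net, arrays,
                                       [F.FragmentDef("A1", "A", (1,))],
                                       times=times)
        vals = np.full((mm.n_rows, 2), 0.5)
        mm = dataclasses.replace(mm, values=vals, sd=np.full_like(vals, 0.01))
        grid = F.TimeGrid([0.0, 1.0, 2.0])
        prob = F.assemble_inst_nlp(net, bound, pools, mm, grid,
                                   F.radau_iia(3), x0)
        d = prob.describe()
        G, s, n = 2, 2, 1
        assert d["blocks"] == {"v": 2, "p_met": 1, "h": 0,
                               "x": G * n, "k": G * s * n}
        assert d["n_vars"] == 2 + 1 + G * n + G * s * n
        assert d["n_eq"] == G * s * n + G * n + 1     # + one stoich row
        assert d["printed_transcription"]["n_vars"] == n * (1 + G * (2 * s + 1))
        assert d["printed_transcription"]["n_constraints"] == \
            2 * G * s * n + G * n

    def test_measurement_time_outside_grid_rejected(self, toy_study, toy_data):
        _, df = toy_data
        mm = F.attach_measurements(toy_study.mm, df)
        with pytest.raises(NetworkError):
            F.assemble_inst_nlp(toy_study.net, toy_study.bound,
                                toy_study.pools, mm, F.TimeGrid([0.0, 10.0]),
                                toy_study.scheme, toy_study.x_init)

    def test_noise_free_fit_recovers_truth_at_high_order(self, toy_study,
                                                         toy_truth):
        """With exact data the refined transcription returns the generating
        parameters; the tiny residual floor is collocation model error
        relative to the reference integrator."""
        v, p = toy_truth
        traj, df = F.report.simulate_study(toy_study, seed=0, noise_sd=0.0)
        mm = F.attach_measurements(toy_study.mm, df)
        prob = F.assemble_inst_nlp(toy_study.net, toy_study.bound,
                                   toy_study.pools, mm, toy_study.grid,
                                   F.radau_iia(9), toy_study.x_init)
        fit = F.solve_nlp(prob, prob.initial_point(v, p))
        assert fit.z <= 0.5
        assert fit.feasibility <= 1e-7
        assert np.abs(fit.v - v).max() / v.max() <= 1e-3
        assert np.abs(fit.pools - p).max() / p.max() <= 1e-3

    def test_objective_audit(self, toy_problem, toy_truth):
        v, p = toy_truth
        fit = F.solve_nlp(toy_problem, toy_problem.initial_point(v, p))
        assert fit.z == pytest.approx(toy_problem.obj.value(fit.zvar), abs=1e-8)
        assert np.abs(toy_problem.eq_fun(fit.zvar)).max() == \
            pytest.approx(fit.feasibility, abs=1e-12)

    def test_restart_from_optimum_stays_put(self, toy_problem, toy_truth):
        v, p = toy_truth
        fit = F.solve_nlp(toy_problem, toy_problem.initial_point(v, p))
        again = F.solve_nlp(toy_problem, fit.zvar.copy())
        assert again.z <= fit.z + 1e-6
        assert np.abs(again.v - fit.v).max() <= 1e-4
        assert again.feasibility <= 1e-7

    def test_pools_unidentifiable_from_equilibrated_data(self, toy_study,
                                                         toy_truth):
        """Once labeling has equilibrated the objective is flat in the pool
        sizes: sampling only post-transient times leaves pools undetermined."""
        v, p = toy_truth
        times = np.array([60.0, 70.0, 80.0])
        mm = F.build_measurement_model(toy_study.net, toy_study.arrays,
                                       toy_study.config.fragments, times=times)
        traj = F.integrate_labeling(toy_study.bound, v,
                                    toy_study.pools.state_pools(p),
                                    np.concatenate([[0.0], times]),
                                    toy_study.x_init)
        df = F.generate_synthetic_measurements(traj, mm, 0.0, seed=0)
        mm = F.attach_measurements(mm, df)
        mm = dataclasses.replace(mm, sd=np.full_like(mm.sd, 0.01))
        grid = F.TimeGrid([0.0, 5.0, 15.0, 30.0, 60.0, 80.0])
        prob = F.assemble_inst_nlp(toy_study.net, toy_study.bound,
                                   toy_study.pools, mm, grid,
                                   F.radau_iia(5), toy_study.x_init)
        # doubling every pool barely moves the objective ...
        z_pools = [prob.obj.value(prob.initial_point(v, p * s))
                   for s in (1.0, 2.0)]
        assert abs(z_pools[1] - z_pools[0]) <= 0.1
        # ... while re-routing a fraction of the flux is strongly visible
        ids = toy_study.net.reaction_ids
        v_shift = v.copy()
        for rid, dv in (("v1", +0.1), ("v2", -0.1), ("v3", -0.1)):
            v_shift[ids.index(rid)] += dv
        z_flux = prob.obj.value(prob.initial_point(v_shift, p))
        assert z_flux >= 100 * max(z_pools[0], 1e-6)

    def test_equilibrated_inst_fit_matches_steady_fluxes(self, toy_study,
                                                         toy_truth):
        v, p = toy_truth
        # steady-state fit
        sprob = F.assemble_steady_nlp(toy_study.net, toy_study.bound,
                                      _steady_mm(toy_study, v))
        sfit = F.solve_nlp(sprob, sprob.initial_point(v))
        # nonstationary fit of post-equilibration samples
        times = np.array([60.0, 70.0, 80.0])
        mm = F.build_measurement_model(toy_study.net, toy_study.arrays,
                                       toy_study.config.fragments, times=times)
        traj = F.integrate_labeling(toy_study.bound, v,
                                    toy_study.pools.state_pools(p),
                                    np.concatenate([[0.0], times]),
                                    toy_study.x_init)
        df = F.generate_synthetic_measurements(traj, mm, 0.0, seed=0)
        mm = F.attach_measurements(mm, df)
        grid = F.TimeGrid([0.0, 5.0, 15.0, 30.0, 60.0, 80.0])
        iprob = F.assemble_inst_nlp(toy_study.net, toy_study.bound,
                                    toy_study.pools, mm, grid,
                                    F.radau_iia(5), toy_study.x_init)
        ifit = F.solve_nlp(iprob, iprob.initial_point(v, p))
        ids = toy_study.net.reaction_ids
        route = [ids.index(r) for r in ("v1", "v2", "v3", "v5", "v6", "v7")]
        assert np.abs(ifit.v[route] - sfit.v[route]).max() <= 1e-3


class TestMultistartRefine:
    def test_multistart_deterministic(self, toy_problem):
        fits1 = F.multistart(toy_problem, 2, seed=5, maxiter=200)
        fits2 = F.multistart(toy_problem, 2, seed=5, maxiter=200)
        assert [f.z for f in fits1] == [f.z for f in fits2]
        assert [f.seed for f in fits1] == [f.seed for f in fits2]

    def test_restart_seeds_reproducible_in_isolation(self):
        s0 = F.derive_restart_seed(42, 3)
        assert s0 == F.derive_restart_seed(42, 3)
        assert s0 != F.derive_restart_seed(42, 4)
        assert 0 <= s0 < 2 ** 31

    def test_results_sorted_by_objective(self, toy_problem):
        fits = F.multistart(toy_problem, 3, seed=11, maxiter=400)
        zs = [f.z for f in fits]
        assert zs == sorted(zs)

    def test_refine_improves_or_keeps_objective(self, toy_problem, toy_truth):
        v, p = toy_truth
        fit = F.solve_nlp(toy_problem, toy_problem.initial_point(v, p))
        refined, hi = F.refine(fit, toy_problem, scheme_order=5)
        assert refined.scheme_order == 5
        assert refined.feasibility <= 1e-7
        # the higher-order transcription reduces discretization error,
        # so the refit objective does not blow up
        assert refined.z <= fit.z * 1.5 + 1.0


class TestGoodnessOfFitAndBootstrap:
    def test_chi2_quantile_value(self):
        assert F.chi2_acceptance(25, 15, level=0.95) == pytest.approx(18.307,
                                                                      abs=1e-3)

    def test_chi2_monotone_in_level(self):
        lo = F.chi2_acceptance(20, 10, level=0.90)
        hi = F.chi2_acceptance(20, 10, level=0.99)
        assert hi > lo

    def test_chi2_nonpositive_dof_rejected(self):
        with pytest.raises(NetworkError):
            F.chi2_acceptance(10, 10)

    def test_bootstrap_collapses_for_tiny_sigma(self, toy_study, toy_truth):
        v, p = toy_truth
        traj, df = F.report.simulate_study(toy_study, seed=0, noise_sd=0.0)
        mm = F.attach_measurements(toy_study.mm, df)
        mm = dataclasses.replace(mm, sd=np.full_like(mm.sd, 1e-6))
        prob = F.assemble_inst_nlp(toy_study.net, toy_study.bound,
                                   toy_study.pools, mm, toy_study.grid,
                                   F.radau_iia(5), toy_study.x_init)
        fit = F.solve_nlp(prob, prob.initial_point(v, p))
        br = F.bootstrap_ci(prob, fit, n_boot=3, seed=9)
        point = np.concatenate([fit.v, fit.pools])
        assert np.abs(br.estimates - point).max() <= 1e-3
        assert br.n_failed == 0
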