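"""Forward simulation: cascade steady state, dynamics, synthetic data."""
import numpy as np
import pytest

import fluxnlp as F
from fluxnlp.network import NetworkError

from conftest import random_network, SMALL_NET_SEEDS
from oracle import IsotopomerOracle


def _one_pool():
    net = F.apply_config(
        F.parse_network("vin: S (a) -> A (a)\nvout: A (a) -> P (a)"),
        {"inputs": ["S"], "outputs": ["P"], "bounds": {"default": [0, 10],
                                                       "vin": [1, 1],
                                                       "vout": [1, 1]}})
    net = F.split_reversible(net)
    arrays = F.build_model_arrays(net, "cumomer")
    tracers = {"S": [{"fraction": 1.0, "atoms": "U", "enrichment": 1.0}]}
    bound = F.bind_inputs(arrays, F.build_input_vector(net, arrays, tracers, 0.0))
    return net, arrays, bound


class TestSteadyState:
    def test_fully_labeled_feed_saturates(self, toy_study):
        net = toy_study.net
        arrays = toy_study.arrays
        tr = {"Aext": [{"fraction": 1.0, "atoms": "U", "enrichment": 1.0}]}
        bound = F.bind_inputs(arrays, F.build_input_vector(net, arrays, tr, 0.0))
        v, _ = toy_study.truth_vectors()
        x = F.solve_steady_state(bound, v)
        assert np.abs(x - 1.0).max() < 1e-12

    def test_matches_long_time_integration(self, toy_study, toy_truth):
        v, p = toy_truth
        bound, pools = toy_study.bound, toy_study.pools
        x_ss = F.solve_steady_state(bound, v)
        traj = F.integrate_labeling(bound, v, pools.state_pools(p),
                                    np.array([0.0, 300.0]), toy_study.x_init,
                                    method="stiff")
        assert np.abs(traj.x[-1] - x_ss).max() <= 1e-6

    @pytest.mark.parametrize("seed", SMALL_NET_SEEDS)
    def test_brute_force_isotopomer_oracle_agreement(self, seed):
        net, tracers, v, _ = random_network(seed)
        arrays = F.build_model_arrays(net, "cumomer")
        bound = F.bind_inputs(arrays,
                              F.build_input_vector(net, arrays, tracers, 0.0))
        x = F.solve_steady_state(bound, v)
        orc = IsotopomerOracle(net, tracers)
        y = orc.steady_state(v)
        frs = [F.FragmentDef("a", "M3", (1, 2, 3)),
               F.FragmentDef("b", "M4", (1, 2))]
        mm = F.build_measurement_model(net, arrays, frs)
        mid_o = np.concatenate([orc.fragment_mid(y, f.metabolite, f.atoms)
                                for f in frs])
        assert np.abs(mm.simulate(x) - mid_o).max() <= 1e-8

    def test_unreachable_states_error(self, toy_study, toy_truth):
        v, _ = toy_truth
        v = v.copy()
        ids = toy_study.net.reaction_ids
        # switch off the C route entirely: C becomes unreachable
        v[ids.index("v2")] = 0.0
        v[ids.index("v3")] = 0.0
        v[ids.index("v1")] += 0.25
        v[ids.index("v7")] = 1.0
        with pytest.raises(NetworkError):
            F.solve_steady_state(toy_study.bound, v)


class TestIntegration:
    def test_single_pool_closed_form(self):
        net, arrays, bound = _one_pool()
        t = np.linspace(0, 5, 26)
        v = np.ones(2)
        traj = F.integrate_labeling(bound, v, np.array([2.0]), t,
                                    np.zeros(1), dt=0.02)
        expected = 1.0 - np.exp(-t / 2.0)
        assert np.abs(traj.x[:, 0] - expected).max() <= 1e-8

    def test_mid_sums_preserved_along_trajectory(self, toy_study, toy_data):
        traj, _ = toy_data
        mm = toy_study.mm
        for i in range(len(traj.t)):
            m = mm.simulate(traj.x[i])
            for ci in range(len(mm.fragments)):
                assert m[mm.fragment_rows(ci)].sum() == pytest.approx(1.0, abs=1e-6)

    def test_states_stay_physical(self, toy_data):
        traj, _ = toy_data
        assert traj.x.min() >= -1e-6 and traj.x.max() <= 1 + 1e-6

    def test_nonpositive_pool_rejected(self, toy_study, toy_truth):
        v, p = toy_truth
        bad = toy_study.pools.state_pools(p).copy()
        bad[0] = 0.0
        with pytest.raises(NetworkError, match="positive"):
            F.integrate_labeling(toy_study.bound, v, bad,
                                 np.array([0.0, 1.0]), toy_study.x_init)

    @pytest.mark.parametrize("seed", SMALL_NET_SEEDS)
    def test_trajectory_matches_oracle(self, seed):
        net, tracers, v, p_met = random_network(seed)
        arrays = F.build_model_arrays(net, "cumomer")
        bound = F.bind_inputs(arrays,
                              F.build_input_vector(net, arrays, tracers, 0.0))
        pools = F.build_pool_model(net, arrays)
        pv = np.array([p_met[m] for m in pools.metabolites])
        t = np.array([0.0, 0.5, 1.5, 4.0])
        x0 = F.initial_state(net, arrays, 0.0)
        traj = F.integrate_labeling(bound, v, pools.state_pools(pv), t, x0,
                                    dt=0.005)
        orc = IsotopomerOracle(net, tracers)
        Y = orc.integrate(v, p_met, t)
        frs = [F.FragmentDef("a", "M3", (1, 2, 3))]
        mm = F.build_measurement_model(net, arrays, frs)
        for i in range(len(t)):
            mid_o = orc.fragment_mid(Y[i], "M3", (1, 2, 3))
            assert np.abs(mm.simulate(traj.x[i]) - mid_o).max() <= 1e-8

    def test_cumomer_emu_trajectories_agree(self, toy_study, toy_truth):
        v, p = toy_truth
        net = toy_study.net
        frs = toy_study.config.fragments
        targets = [(f.metabolite, f.atoms) for f in frs]
        arr_e = F.build_model_arrays(net, "emu", targets=targets)
        tr = toy_study.config.tracers
        bnd_e = F.bind_inputs(arr_e, F.build_input_vector(net, arr_e, tr, 0.0))
        pools_e = F.build_pool_model(net, arr_e)
        p_e = np.array([dict(zip(toy_study.pools.metabolites, p))[m]
                        for m in pools_e.metabolites])
        t = np.array([0.0, 2.0, 6.0, 14.0])
        x0e = F.initial_state(net, arr_e, 0.0)
        te = F.integrate_labeling(bnd_e, v, pools_e.state_pools(p_e), t, x0e)
        tc = F.integrate_labeling(toy_study.bound, v,
                                  toy_study.pools.state_pools(p), t,
                                  toy_study.x_init)
        mm_c = toy_study.mm
        mm_e = F.build_measurement_model(net, arr_e, frs)
        for i in range(len(t)):
            assert np.abs(mm_c.simulate(tc.x[i]) -
                          mm_e.simulate(te.x[i])).max() <= 1e-8


class TestSyntheticMeasurements:
    def test_zero_noise_reproduces_model(self, toy_study, toy_truth):
        v, p = toy_truth
        times = np.array([2.0, 10.0])
        mm = F.build_measurement_model(toy_study.net, toy_study.arrays,
                                       toy_study.config.fragments, times=times)
        traj = F.integrate_labeling(toy_study.bound, v,
                                    toy_study.pools.state_pools(p),
                                    np.array([0.0, 2.0, 10.0]),
                                    toy_study.x_init)
        df = F.generate_synthetic_measurements(traj, mm, 0.0, seed=0)
        x2 = traj.at([2.0])[0]
        exact = mm.simulate(x2)
        got = df[df.time == 2.0]["value"].to_numpy()
        assert np.abs(got - exact).max() < 1e-12
        assert (df["sd"] == 1e-4).all()   # sd floor for noise-free tables

    def test_same_seed_identical_tables(self, toy_study, toy_data):
        traj, df1 = toy_data
        df2 = F.generate_synthetic_measurements(traj, toy_study.mm, 0.01, 42)
        assert df1.equals(df2)

    def test_empirical_noise_sd(self, toy_study, toy_truth):
        """~1e4 noise draws reproduce the nominal sd within 2%."""
        v, p = toy_truth
        times = np.array([4.0])
        mm = F.build_measurement_model(toy_study.net, toy_study.arrays,
                                       toy_study.config.fragments, times=times)
        traj = F.integrate_labeling(toy_study.bound, v,
                                    toy_study.pools.state_pools(p),
                                    np.array([0.0, 4.0]), toy_study.x_init)
        exact = mm.simulate(traj.at([4.0])[0])
        draws = []
        for seed in range(800):
            df = F.generate_synthetic_measurements(traj, mm, 0.01, seed)
            draws.append(df["value"].to_numpy() - exact)
        emp = np.std(np.concatenate(draws), ddof=1)   # 800 x 13 draws
        assert emp == pytest.approx(0.01, rel=0.02)

    def test_times_outside_trajectory_error(self, toy_study, toy_data):
        traj, _ = toy_data
        mm = F.build_measurement_model(toy_study.net, toy_study.arrays,
                                       toy_study.config.fragments,
                                       times=[25.0])
        with pytest.raises(NetworkError):
            F.generate_synthetic_measurements(traj, mm, 0.01, 0)
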