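"""Shared fixtures: the bundled toy study and small synthetic networks."""
from __future__ import annotations

import importlib.resources as ir

import numpy as np
import pytest

import fluxnlp as F
from fluxnlp.report import load_config, build_study, simulate_study


def toy_config_path():
    return ir.files("fluxnlp") / "examples" / "toy.yaml"


@pytest.fixture(scope="session")
def toy_study():
    return build_study(load_config(toy_config_path()))


@pytest.fixture(scope="session")
def toy_truth(toy_study):
    v, p = toy_study.truth_vectors()
    return v, p


@pytest.fixture(scope="session")
def toy_data(toy_study):
    """One fixed noisy dataset for the toy study (seed 42, sd 0.01)."""
    traj, df = simulate_study(toy_study, seed=42)
    return traj, df


@pytest.fixture(scope="session")
def toy_problem(toy_study, toy_data):
    _, df = toy_data
    return toy_study.problem(df, kind="inst")


# ---------------------------------------------------------------------------
# small synthetic networks with randomized atom maps

def _perm_word(rng, n):
    """Random permutation of the first n atom letters as a string."""
    letters = [chr(ord("a") + i) for i in range(n)]
    rng.shuffle(letters)
    return "".join(letters)


def random_network(seed: int):
    """A small branched network with randomized carbon rearrangements.

    Feed (3C) -> M1 -> {direct bypass to M3} and {cleavage M1 -> M2a + M2b,
    condensation M2a + M2b -> M3}, a reversible scramble M3 <-> M4, and an
    efflux.  12 internal carbons total; every internal metabolite is
    produced and consumed.  Atom maps are random permutations drawn from
    the seed, so each seed exercises different Q/P sparsity.
    """
    rng = np.random.default_rng(seed)
    w = _perm_word(rng, 3)
    r_in = f"rin: Sub (abc) -> M1 ({w})"
    w = _perm_word(rng, 3)
    r_byp = f"rbyp: M1 (abc) -> M3 ({w})"
    w = _perm_word(rng, 3)
    r_clv = f"rclv: M1 (abc) -> M2a ({w[:2]}) + M2b ({w[2]})"
    w = _perm_word(rng, 3)
    r_cnd = f"rcnd: M2a (ab) + M2b (c) -> M3 ({w})"
    w = _perm_word(rng, 3)
    r_rev = f"rrev: M3 (abc) <-> M4 ({w})"
    r_out = "rout: M3 (abc) -> Snk (abc)"
    text = "\n".join([r_in, r_byp, r_clv, r_cnd, r_rev, r_out])
    net = F.parse_network(text)
    net = F.apply_config(net, {
        "inputs": ["Sub"], "outputs": ["Snk"],
        "bounds": {"default": [0.0, 10.0], "rin": [1.0, 1.0]},
        "pool_bounds": {"default": [0.2, 3.0]}})
    net = F.split_reversible(net, exchange_cap=3.0)
    tracers = {"Sub": [
        {"fraction": 0.6, "atoms": [1], "enrichment": 0.95},
        {"fraction": 0.4, "atoms": "U", "enrichment": 0.99}]}
    # strictly positive interior flux distribution: with rin = rout = 1,
    # the free choices are the route split and the exchange magnitude
    beta = rng.uniform(0.25, 0.75)
    rho = rng.uniform(0.2, 1.5)
    flux = {"rin": 1.0, "rbyp": beta, "rclv": 1.0 - beta, "rcnd": 1.0 - beta,
            "rrev_f": rho, "rrev_r": rho, "rout": 1.0}
    v = np.array([flux[r] for r in net.reaction_ids])
    assert np.abs(net.S @ v).max() < 1e-12
    p_met = dict(zip(["M1", "M2a", "M2b", "M3", "M4"],
                     np.exp(rng.uniform(np.log(0.3), np.log(2.0), 5))))
    return net, tracers, v, p_met


SMALL_NET_SEEDS = [0, 1, 2]
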