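"""Forward simulation of labeling states: steady state, dynamics, fixtures.

The steady-state solver exploits the cascade structure of the balances:
the balance of a weight-w cumomer (or size-w EMU fraction block) couples
linearly to states of the same weight and only through products of
strictly lower weights, so the full nonlinear system splits into a
sequence of sparse linear solves by ascending weight.

The dynamic integrator implements the classic fixed-step 4th-order
Runge-Kutta scheme (the pathway used to generate the reference synthetic
trajectories, default step 0.02) plus an adaptive stiff fallback through
``scipy.integrate.solve_ivp``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.sparse
import scipy.sparse.linalg

from .network import NetworkError
from .labeling import BoundArrays
from .measure import MeasurementModel, TABLE_COLUMNS

__all__ = [
    "Trajectory",
    "solve_steady_state",
    "integrate_labeling",
    "generate_synthetic_measurements",
]


@dataclass
class Trajectory:
    t: np.ndarray               # time points
    x: np.ndarray               # (len(t), n_states)
    method: str
    dt: float | None = None

    def at(self, t_query: np.ndarray) -> np.ndarray:
        """Linear interpolation of the stored states at query times."""
        t_query = np.atleast_1d(np.asarray(t_query, float))
        out = np.empty((len(t_query), self.x.shape[1]))
        for j in range(self.x.shape[1]):
            out[:, j] = np.interp(t_query, self.t, self.x[:, j])
        return out


def solve_steady_state(bound: BoundArrays, v: np.ndarray,
                       tol: float = 1e-10) -> np.ndarray:
    """Solve the steady-state balances by the weight cascade.

    At each weight level a sparse linear system ``A x_w = -rhs`` is
    solved, where A collects the (weight-preserving) unimolecular terms
    and rhs the contributions of lower weights and of the fed substrates.
    A singular level system means some states are unreachable at this flux
    distribution (zero-flux dead ends) and raises an error naming them.
    """
    n = bound.n
    x = np.zeros(n)
    level = bound.level_of
    for w in bound.levels:
        sel = np.flatnonzero(level == w)
        pos = -np.ones(n, dtype=int)
        pos[sel] = np.arange(len(sel))
        rows, cols, data = [], [], []
        r, k, j, c = bound.lin
        for e in range(len(k)):
            if level[k[e]] == w:
                if level[j[e]] == w:
                    rows.append(pos[k[e]])
                    cols.append(pos[j[e]])
                    data.append(c[e] * v[r[e]])
        A = scipy.sparse.csr_matrix((data, (rows, cols)),
                                    shape=(len(sel), len(sel)))
        # rhs: full production evaluated with current x and this level zeroed
        g = bound.production(x, v)
        rhs = g[sel]
        try:
            lu = scipy.sparse.linalg.splu(A.tocsc())
            x_w = lu.solve(-rhs)
        except RuntimeError as exc:
            bad = [str(bound.arrays.states[i]) for i in sel]
            raise NetworkError(
                f"singular balance system at weight {w}; unreachable states "
                f"among {bad}") from exc
        x[sel] = x_w
        resid = np.abs(A @ x_w + rhs).max() if len(sel) else 0.0
        if not np.isfinite(x_w).all() or resid > 1e-6:
            bad = [str(bound.arrays.states[i]) for i in sel]
            raise NetworkError(
                f"weight-{w} cascade solve failed (residual {resid:.2e}); "
                f"states {bad} may be unreachable at this flux distribution")
    g = bound.production(x, v)
    if np.abs(g).max() > max(tol, 1e-8 * max(1.0, np.abs(v).max())):
        raise NetworkError(
            f"steady-state balance residual {np.abs(g).max():.2e} exceeds "
            "tolerance")
    return x


def integrate_labeling(bound: BoundArrays, v: np.ndarray, p_k: np.ndarray,
                       t_grid: np.ndarray, x0: np.ndarray,
                       method: str = "rk4", dt: float = 0.02) -> Trajectory:
    """Integrate p_k dx_k/dt = production_k(x, v) from x(0) = x0.

    ``t_grid`` lists the output times (must start at the initial time).
    ``method`` is ``"rk4"`` (fixed step, the default fixture pathway) or
    ``"stiff"`` (adaptive Radau via scipy with analytic Jacobian).
    """
    p_k = np.asarray(p_k, float)
    if (p_k <= 0).any():
        raise NetworkError("pool sizes must be strictly positive")
    t_grid = np.asarray(t_grid, float)
    inv_p = 1.0 / p_k

    def f(t, x):
        return inv_p * bound.production(x, v)

    if method == "stiff":
        def jac(t, x):
            return scipy.sparse.diags(inv_p) @ bound.jac_x(x, v)
        sol = scipy.integrate.solve_ivp(
            f, (t_grid[0], t_grid[-1]), x0, method="Radau", t_eval=t_grid,
            jac=jac, rtol=1e-9, atol=1e-11)
        if not sol.success:
            raise NetworkError("stiff integration failed: " + sol.message)
        return Trajectory(sol.t, sol.y.T, "stiff")
    if method != "rk4":
        raise NetworkError(f"unknown integration method {method!r}")

    xs = [np.array(x0, float)]
    x = np.array(x0, float)
    t = t_grid[0]
    for t_next in t_grid[1:]:
        span = t_next - t
        nstep = max(1, int(np.ceil(span / dt - 1e-12)))
        h = span / nstep
        for _ in range(nstep):
            k1 = f(t, x)
            k2 = f(t + h / 2, x + h / 2 * k1)
            k3 = f(t + h / 2, x + h / 2 * k2)
            k4 = f(t + h, x + h * k3)
            x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        if np.max(x) > 1.01 or np.min(x) < -0.01:
            raise NetworkError(
                "state escaped [-0.01, 1.01] during fixed-step integration; "
                "reduce dt or use method='stiff'")
        t = t_next
        xs.append(x.copy())
    return Trajectory(t_grid, np.array(xs), "rk4", dt)


def generate_synthetic_measurements(traj: Trajectory, mm: MeasurementModel,
                                    noise_sd: float, seed: int,
                                    sd_floor: float = 1e-4) -> pd.DataFrame:
    """Noisy measurement table from a trajectory, in the TSV dialect.

    m_meas = (M x(t) + m0) + N(0, noise_sd), deterministic for a seed.
    The recorded sd column is max(noise_sd, sd_floor) so that objective
    weights stay finite for noise-free tables.
    """
    if len(mm.times) == 0:
        raise NetworkError("measurement model carries no measurement times")
    if mm.times.min() < traj.t.min() - 1e-12 or mm.times.max() > traj.t.max() + 1e-12:
        raise NetworkError("measurement times outside the trajectory span")
    rng = np.random.default_rng(seed)
    x_at = traj.at(mm.times)
    sd = max(float(noise_sd), sd_floor)
    records = []
    for j, t in enumerate(mm.times):
        m = mm.simulate(x_at[j])
        if noise_sd > 0:
            m = m + rng.normal(0.0, noise_sd, size=m.shape)
        for i, (ci, mass, dmass) in enumerate(mm.row_meta):
            frag = mm.fragments[ci]
            records.append({
                "fragment_id": frag.id, "metabolite": frag.metabolite,
                "atoms": ",".join(map(str, frag.atoms)),
                "daughter_atoms": ",".join(map(str, frag.daughter)),
                "formula": frag.formula, "time": t, "mass": mass,
                "daughter_mass": dmass if dmass >= 0 else "",
                "value": m[i], "sd": sd})
    return pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)
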