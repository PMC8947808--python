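"""Flux/pool estimation as an equality-constrained nonlinear program.

Both the steady-state problem and the isotopically nonstationary problem
are posed with the state variables *inside* the optimization: the labeling
balances (steady) or their collocation transcription (nonstationary) enter
as equality constraints, and the solver updates states and parameters
simultaneously.  No trajectory is ever re-integrated inside an iteration —
this is precisely what distinguishes the formulation from shooting
estimators.

Variable blocks
    v       fluxes (all nonnegative after reversible splitting)
    p_met   metabolite pool sizes (nonstationary only)
    h       measurement scaling factors (optional; fixed to 1 when the
            fitted MIDs are complete and normalized)
    x_gi    states at the time-grid nodes
    k_agi   collocation stage derivatives

The stage states K and the interpolated/measured states are affine in
(x, k) and are folded in at evaluation time; the reported problem
structure still counts the full printed transcription.  All residuals are
affine in the variables, so the objective is an exact sparse quadratic;
the only curvature lives in the bilinear balance constraints, for which
the exact Lagrangian Hessian is supplied.  The default backend is
scipy's trust-constr interior/SQP method, satisfying the solver contract
(sparse first derivatives, equality feasibility tolerance, status report);
any equivalent sparse NLP solver could be substituted.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse as sps
import scipy.stats

from .network import Network, NetworkError, count_independent_fluxes, \
    sample_feasible_fluxes_pools
from .labeling import BoundArrays, PoolModel
from .measure import MeasurementModel
from .collocation import CollocationScheme, TimeGrid, TranscribedSystem, \
    radau_integrate, transcribe
from .simulate import solve_steady_state, integrate_labeling

__all__ = [
    "FitResult",
    "BootstrapResult",
    "SteadyProblem",
    "InstProblem",
    "assemble_steady_nlp",
    "assemble_inst_nlp",
    "solve_nlp",
    "multistart",
    "refine",
    "chi2_acceptance",
    "bootstrap_ci",
    "derive_restart_seed",
]

FEASIBILITY_TOL = 1e-7  # default equality feasibility tolerance of the backend


@dataclass
class FitResult:
    v: np.ndarray
    pools: np.ndarray | None
    h: np.ndarray | None
    z: float
    status: str                  # optimal | locally-optimal | iteration-limit | infeasible
    feasibility: float
    n_iter: int
    zvar: np.ndarray             # full solution vector
    scheme_order: int | None = None
    seed: int | None = None
    x_nodes: np.ndarray | None = None   # (Gamma+1, n) node states
    stage_k: list | None = None         # per-interval (s, n) stage derivatives

    @property
    def ok(self) -> bool:
        return self.status in ("optimal", "locally-optimal")


@dataclass
class BootstrapResult:
    names: list[str]
    estimates: np.ndarray        # (n_ok, n_params)
    mean: np.ndarray
    sd: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_failed: int = 0


# ---------------------------------------------------------------------------
# shared objective machinery: every residual is affine in the variables

class _QuadObjective:
    """z(obj) = || J zvar + r0 ||^2 with constant sparse J."""

    def __init__(self, J: sps.csr_matrix, r0: np.ndarray):
        self.J = J.tocsr()
        self.r0 = r0
        self.H = (2.0 * (self.J.T @ self.J)).tocsr()

    def value(self, z):
        r = self.J @ z + self.r0
        return float(r @ r)

    def grad(self, z):
        return 2.0 * (self.J.T @ (self.J @ z + self.r0))

    def hess(self, z):
        return self.H

    def residuals(self, z):
        return self.J @ z + self.r0


def _coo_accumulate(parts, shape):
    """Build a CSR matrix from (rows, cols, data) triplets."""
    if not parts:
        return sps.csr_matrix(shape)
    rows = np.concatenate([p[0] for p in parts])
    cols = np.concatenate([p[1] for p in parts])
    data = np.concatenate([p[2] for p in parts])
    return sps.csr_matrix((data, (rows, cols)), shape=shape)


def _block(mat, row_off, col_off):
    m = mat.tocoo()
    return (m.row + row_off, m.col + col_off, m.data)


def _independent_rows(S: np.ndarray) -> np.ndarray:
    """Row-reduce a matrix to a maximal linearly independent row subset.

    Duplicate mass balances (metabolites with identical stoichiometric
    rows) would make the equality Jacobian rank-deficient and force the
    backend into dense factorizations.
    """
    if S.size == 0:
        return S
    sv = np.linalg.svd(S, compute_uv=False)
    rank = int(np.sum(sv > 1e-10 * sv[0]))
    if rank == S.shape[0]:
        return S
    _, _, piv = scipy.linalg.qr(S.T, pivoting=True)
    return S[np.sort(piv[:rank])]


# ---------------------------------------------------------------------------
# steady-state problem (Eq-1-type structure)

class SteadyProblem:
    """Steady-state MFA NLP: minimise weighted SSR subject to the balances.

    Blocks: v | h | x.  Equalities: balance residuals g(x, v) = 0 and
    S v = 0; inequalities R v <= b; flux bounds; x in [0, 1]; zero-order
    cumomers and fed-substrate states are pinned constants inside the
    bound arrays.
    """

    kind = "steady"

    def __init__(self, net: Network, bound: BoundArrays,
                 mm: MeasurementModel, scaling: str = "fixed",
                 state_box: tuple[float, float] | None = None):
        if mm.values is None:
            raise NetworkError("measurement model carries no measured values")
        self.net = net
        self.bound = bound
        self.mm = mm
        self.scaling = scaling
        self.state_box = state_box
        self.nr = bound.n_reactions
        self.n = bound.n
        self.nh = len(mm.fragments) if scaling == "per_fragment" else 0
        self.off_v, self.off_h = 0, self.nr
        self.off_x = self.nr + self.nh
        self.nz = self.off_x + self.n
        self._build_objective()

    # objective ---------------------------------------------------------
    def _build_objective(self):
        mm = self.mm
        vals = mm.values[:, 0]
        sd = mm.sd[:, 0]
        rows, cols, data = [], [], []
        Mc = (mm.M.tocoo())
        inv = 1.0 / sd
        # labeling residuals: (h * meas - (M x + m0)) / sd
        rows.append(Mc.row)
        cols.append(Mc.col + self.off_x)
        data.append(-Mc.data * inv[Mc.row])
        r0 = -mm.m0 * inv
        if self.nh:
            U = mm.U.tocoo()
            rows.append(U.row)
            cols.append(U.col + self.off_h)
            data.append(vals[U.row] * inv[U.row])
        else:
            r0 = r0 + vals * inv
        extra_rows, extra_r0 = [], []
        nrow = mm.n_rows
        for rid, val, sdv in self.net.flux_measurements:
            r = self.net.reaction_index(rid)
            rows.append(np.array([nrow]))
            cols.append(np.array([self.off_v + r]))
            data.append(np.array([-1.0 / sdv]))
            extra_r0.append(val / sdv)
            nrow += 1
        J = _coo_accumulate(
            [(np.concatenate(rows), np.concatenate(cols), np.concatenate(data))],
            (nrow, self.nz))
        self.obj = _QuadObjective(J, np.concatenate([r0, np.array(extra_r0)]))

    # constraints -------------------------------------------------------
    def eq_fun(self, z):
        v = z[:self.nr]
        x = z[self.off_x:]
        return self.bound.production(x, v)

    def eq_jac(self, z):
        v = z[:self.nr]
        x = z[self.off_x:]
        parts = [_block(self.bound.jac_v(x), 0, self.off_v),
                 _block(self.bound.jac_x(x, v), 0, self.off_x)]
        return _coo_accumulate(parts, (self.n, self.nz))

    def eq_hess(self, z, lam):
        v = z[:self.nr]
        r, k, i, j, c = self.bound.quad
        parts = []
        if len(k):
            w = 0.5 * c * lam[k]
            # d2/dKi dKj and cross d2/dv dK
            parts.append((i + self.off_x, j + self.off_x, w * v[r]))
            parts.append((j + self.off_x, i + self.off_x, w * v[r]))
            x = z[self.off_x:]
            parts.append((np.asarray(r) + self.off_v, i + self.off_x, w * x[j]))
            parts.append((i + self.off_x, np.asarray(r) + self.off_v, w * x[j]))
            parts.append((np.asarray(r) + self.off_v, j + self.off_x, w * x[i]))
            parts.append((j + self.off_x, np.asarray(r) + self.off_v, w * x[i]))
        rl, kl, jl, cl = self.bound.lin
        if len(kl):
            w = cl * lam[kl]
            parts.append((np.asarray(rl) + self.off_v, jl + self.off_x, w))
            parts.append((jl + self.off_x, np.asarray(rl) + self.off_v, w))
        return _coo_accumulate([(np.concatenate([p[0] for p in parts]),
                                 np.concatenate([p[1] for p in parts]),
                                 np.concatenate([p[2] for p in parts]))]
                               if parts else [], (self.nz, self.nz))

    def linear_constraints(self):
        out = []
        S = _independent_rows(self.net.stoichiometric_matrix())
        if S.size:
            A = sps.hstack([sps.csr_matrix(S),
                            sps.csr_matrix((S.shape[0], self.nz - self.nr))])
            out.append(scipy.optimize.LinearConstraint(A, 0.0, 0.0))
        if self.net.R.size:
            A = sps.hstack([sps.csr_matrix(self.net.R),
                            sps.csr_matrix((self.net.R.shape[0],
                                            self.nz - self.nr))])
            out.append(scipy.optimize.LinearConstraint(A, -np.inf, self.net.b))
        return out

    def bounds(self):
        lb_v, ub_v = self.net.bounds_arrays()
        xlo, xhi = self.state_box if self.state_box else (-np.inf, np.inf)
        lb = np.concatenate([lb_v, np.full(self.nh, 1e-3), np.full(self.n, xlo)])
        ub = np.concatenate([ub_v, np.full(self.nh, 1e3), np.full(self.n, xhi)])
        return scipy.optimize.Bounds(lb, ub)

    # starting points ---------------------------------------------------
    def initial_point(self, v0, pools0=None):
        try:
            x0 = solve_steady_state(self.bound, v0)
            x0 = np.clip(x0, 0.0, 1.0)
        except NetworkError:
            x0 = np.full(self.n, 0.1)
        z0 = np.concatenate([v0, np.ones(self.nh), x0])
        return z0

    def unpack(self, z) -> FitResult:
        v = z[:self.nr].copy()
        h = z[self.off_h:self.off_h + self.nh].copy() if self.nh else None
        return FitResult(v=v, pools=None, h=h, z=self.obj.value(z),
                         status="", feasibility=float(np.abs(self.eq_fun(z)).max()),
                         n_iter=0, zvar=z.copy())

    def with_values(self, values: np.ndarray) -> "SteadyProblem":
        mm = dataclasses.replace(self.mm, values=values)
        return SteadyProblem(self.net, self.bound, mm, self.scaling,
                             self.state_box)

    def fitted_measurements(self, z) -> np.ndarray:
        x = z[self.off_x:]
        return (self.mm.simulate(x))[:, None]

    def sample_start(self, seed):
        v0, _ = sample_feasible_fluxes_pools(self.net, seed)
        return self.initial_point(v0)

    def n_free_parameters(self) -> int:
        return count_independent_fluxes(self.net) + self.nh

    def describe(self) -> dict:
        return {"n_vars": self.nz, "n_eq": self.n + len(self.net.balanced),
                "blocks": {"v": self.nr, "h": self.nh, "x": self.n}}

    @property
    def n_eq(self):
        return self.n


# ---------------------------------------------------------------------------
# isotopically nonstationary problem (Eq-18-type structure)

class InstProblem:
    """Transcribed inst-MFA NLP.

    Equality rows: stage balances p_k k_agk = production_k(K_ag, v)
    (Gamma * s * n) followed by interval updates (Gamma * n); S v = 0 and
    R v <= b on the flux block; pool sizes enter through p = D p_met;
    the initial node x_0 is the pinned initial-condition vector.
    """

    kind = "inst"

    def __init__(self, net: Network, bound: BoundArrays, pools: PoolModel,
                 mm: MeasurementModel, grid: TimeGrid,
                 scheme: CollocationScheme, x_init: np.ndarray,
                 scaling: str = "fixed",
                 state_box: tuple[float, float] | None = None):
        if mm.values is None:
            raise NetworkError("measurement model carries no measured values")
        if len(mm.times) == 0:
            raise NetworkError("nonstationary fit needs measurement times")
        for t in mm.times:
            grid.locate(float(t))  # raises if outside the grid
        self.net, self.bound, self.pools, self.mm = net, bound, pools, mm
        self.grid, self.scheme = grid, scheme
        self.x_init = np.asarray(x_init, float)
        self.scaling = scaling
        self.state_box = state_box
        self.system: TranscribedSystem = transcribe(grid, scheme, bound.n)
        self.nr, self.n = bound.n_reactions, bound.n
        self.nm = pools.n_pools
        self.G, self.s = grid.n_intervals, scheme.s
        self.nt = len(mm.times)
        self.nh = len(mm.fragments) * self.nt if scaling == "per_fragment" else 0
        self.off_v = 0
        self.off_p = self.nr
        self.off_h = self.nr + self.nm
        self.off_x = self.off_h + self.nh
        self.off_k = self.off_x + self.G * self.n
        self.nz = self.off_k + self.G * self.s * self.n
        self.n_eq = self.G * self.s * self.n + self.G * self.n
        self._Dcoo = pools.D.tocoo()
        self._build_objective()
        self._build_update_rows()

    # -- variable indexing ---------------------------------------------
    def x_slice(self, gamma):  # gamma in 1..G
        o = self.off_x + (gamma - 1) * self.n
        return slice(o, o + self.n)

    def k_slice(self, gamma, alpha):
        o = self.off_k + ((gamma - 1) * self.s + alpha) * self.n
        return slice(o, o + self.n)

    def x_gamma(self, z, gamma):
        if gamma == 0:
            return self.x_init
        return z[self.x_slice(gamma)]

    def k_gamma(self, z, gamma):
        o = self.off_k + (gamma - 1) * self.s * self.n
        return z[o:o + self.s * self.n].reshape(self.s, self.n)

    def h_index(self, ci, mu):
        return self.off_h + ci * self.nt + mu

    # -- objective ------------------------------------------------------
    def _build_objective(self):
        mm, grid, scheme = self.mm, self.grid, self.scheme
        n_rows, nt = mm.n_rows, self.nt
        Mc = mm.M.tocoo()
        rows, cols, data = [], [], []
        r0 = np.zeros(n_rows * nt)
        sd_flat = np.empty(n_rows * nt)
        for mu, t in enumerate(mm.times):
            gamma, tau = grid.locate(float(t))
            h_g = grid.h[gamma - 1]
            Bv = scheme.B(tau) * h_g
            base = mu * n_rows
            inv = 1.0 / mm.sd[:, mu]
            sd_flat[base:base + n_rows] = mm.sd[:, mu]
            # -(M x_mu + m0)/sd with x_mu = x_{gamma-1} + h sum_a B_a(tau) k_ag
            if gamma == 1:
                r0[base:base + n_rows] -= (mm.M @ self.x_init) * inv
            else:
                rows.append(Mc.row + base)
                cols.append(Mc.col + self.x_slice(gamma - 1).start)
                data.append(-Mc.data * inv[Mc.row])
            for a in range(self.s):
                rows.append(Mc.row + base)
                cols.append(Mc.col + self.k_slice(gamma, a).start)
                data.append(-Bv[a] * Mc.data * inv[Mc.row])
            r0[base:base + n_rows] -= mm.m0 * inv
            meas = mm.values[:, mu]
            if self.nh:
                U = mm.U.tocoo()
                rows.append(U.row + base)
                cols.append(np.array([self.h_index(c, mu) for c in U.col]))
                data.append(meas[U.row] * inv[U.row])
            else:
                r0[base:base + n_rows] += meas * inv
        extra_rows, extra_cols, extra_data, extra_r0 = [], [], [], []
        nrow = n_rows * nt
        for rid, val, sdv in self.net.flux_measurements:
            r = self.net.reaction_index(rid)
            extra_rows.append(nrow); extra_cols.append(self.off_v + r)
            extra_data.append(-1.0 / sdv); extra_r0.append(val / sdv)
            nrow += 1
        pool_col = {m: i for i, m in enumerate(self.pools.metabolites)}
        for met, val, sdv in self.net.pool_measurements:
            if met not in pool_col:
                raise NetworkError(f"pool measurement for untracked metabolite {met}")
            extra_rows.append(nrow); extra_cols.append(self.off_p + pool_col[met])
            extra_data.append(-1.0 / sdv); extra_r0.append(val / sdv)
            nrow += 1
        if extra_rows:
            rows.append(np.array(extra_rows))
            cols.append(np.array(extra_cols))
            data.append(np.array(extra_data))
            r0 = np.concatenate([r0, np.array(extra_r0)])
        J = _coo_accumulate([(np.concatenate(rows), np.concatenate(cols),
                              np.concatenate(data))], (nrow, self.nz))
        self.obj = _QuadObjective(J, r0)

    def _build_update_rows(self):
        """Constant Jacobian of x_g - x_{g-1} - h_g sum_a b_a k_ag = 0."""
        rows, cols, data = [], [], []
        idx = np.arange(self.n)
        for g in range(1, self.G + 1):
            base = (g - 1) * self.n
            rows.append(base + idx)
            cols.append(self.x_slice(g).start + idx)
            data.append(np.ones(self.n))
            if g > 1:
                rows.append(base + idx)
                cols.append(self.x_slice(g - 1).start + idx)
                data.append(-np.ones(self.n))
            h_g = self.grid.h[g - 1]
            for a in range(self.s):
                rows.append(base + idx)
                cols.append(self.k_slice(g, a).start + idx)
                data.append(np.full(self.n, -h_g * self.scheme.b[a]))
        self._J_update = _coo_accumulate(
            [(np.concatenate(rows), np.concatenate(cols), np.concatenate(data))],
            (self.G * self.n, self.nz))

    # -- equality constraints -------------------------------------------
    def eq_fun(self, z):
        v = z[:self.nr]
        p_k = self.pools.state_pools(z[self.off_p:self.off_p + self.nm])
        out = np.empty(self.n_eq)
        pos = 0
        for g in range(1, self.G + 1):
            x_prev = self.x_gamma(z, g - 1)
            k_g = self.k_gamma(z, g)
            K = self.system.stage_states(x_prev, k_g, self.grid.h[g - 1])
            for a in range(self.s):
                out[pos:pos + self.n] = p_k * k_g[a] - \
                    self.bound.production(K[a], v)
                pos += self.n
        for g in range(1, self.G + 1):
            x_prev = self.x_gamma(z, g - 1)
            k_g = self.k_gamma(z, g)
            out[pos:pos + self.n] = z[self.x_slice(g)] - x_prev - \
                self.grid.h[g - 1] * self.scheme.b @ k_g
            pos += self.n
        return out

    def eq_jac(self, z):
        v = z[:self.nr]
        p_met = z[self.off_p:self.off_p + self.nm]
        p_k = self.pools.state_pools(p_met)
        parts = []
        idx = np.arange(self.n)
        D = self._Dcoo
        pos = 0
        for g in range(1, self.G + 1):
            x_prev = self.x_gamma(z, g - 1)
            k_g = self.k_gamma(z, g)
            h_g = self.grid.h[g - 1]
            K = self.system.stage_states(x_prev, k_g, h_g)
            for a in range(self.s):
                Jx = self.bound.jac_x(K[a], v).tocoo()
                Jv = self.bound.jac_v(K[a]).tocoo()
                # d/dv
                parts.append((Jv.row + pos, Jv.col + self.off_v, -Jv.data))
                # d/dp_met via p_k = D p_met
                parts.append((D.row + pos, D.col + self.off_p,
                              D.data * k_g[a][D.row]))
                # d/dx_{g-1}
                if g > 1:
                    parts.append((Jx.row + pos,
                                  Jx.col + self.x_slice(g - 1).start, -Jx.data))
                # d/dk_bg: p_k on the own stage, minus h a_ab Jx through K
                parts.append((pos + idx, self.k_slice(g, a).start + idx, p_k))
                for b_ in range(self.s):
                    parts.append((Jx.row + pos,
                                  Jx.col + self.k_slice(g, b_).start,
                                  -h_g * self.scheme.a[a, b_] * Jx.data))
                pos += self.n
        J_stage = _coo_accumulate(parts, (self.G * self.s * self.n, self.nz))
        return sps.vstack([J_stage, self._J_update]).tocsr()

    def eq_hess(self, z, lam):
        """Exact Lagrangian Hessian of the stage-balance constraints.

        Bilinear terms: p_k * k (pools x stage derivatives) and the
        condensation products inside production(K, v) (states x states and
        fluxes x states), pulled back through the affine map z -> K_ag.
        """
        v = z[:self.nr]
        D = self._Dcoo
        parts = []
        r_q, k_q, i_q, j_q, c_q = self.bound.quad
        r_l, k_l, j_l, c_l = self.bound.lin
        pos = 0
        for g in range(1, self.G + 1):
            h_g = self.grid.h[g - 1]
            x_prev = self.x_gamma(z, g - 1)
            k_g = self.k_gamma(z, g)
            K = self.system.stage_states(x_prev, k_g, h_g)
            for a in range(self.s):
                lam_a = lam[pos:pos + self.n]
                pos += self.n
                # p x k cross terms
                parts.append((D.col + self.off_p,
                              self.k_slice(g, a).start + D.row,
                              D.data * lam_a[D.row]))
                parts.append((self.k_slice(g, a).start + D.row,
                              D.col + self.off_p,
                              D.data * lam_a[D.row]))
                # columns of the affine map z -> K_a: x_{g-1} (coeff 1) and
                # k_bg (coeff h a_ab)
                cols_K = []
                if g > 1:
                    cols_K.append((self.x_slice(g - 1).start, 1.0))
                for b_ in range(self.s):
                    w = h_g * self.scheme.a[a, b_]
                    if w != 0.0:
                        cols_K.append((self.k_slice(g, b_).start, w))
                if len(k_q):
                    wq = -0.5 * c_q * lam_a[k_q]
                    Ka = K[a]
                    for off1, w1 in cols_K:
                        # v x K cross terms
                        parts.append((r_q + self.off_v, off1 + i_q,
                                      w1 * wq * Ka[j_q]))
                        parts.append((off1 + i_q, r_q + self.off_v,
                                      w1 * wq * Ka[j_q]))
                        parts.append((r_q + self.off_v, off1 + j_q,
                                      w1 * wq * Ka[i_q]))
                        parts.append((off1 + j_q, r_q + self.off_v,
                                      w1 * wq * Ka[i_q]))
                        for off2, w2 in cols_K:
                            ww = w1 * w2 * wq * v[r_q]
                            parts.append((off1 + i_q, off2 + j_q, ww))
                            parts.append((off2 + j_q, off1 + i_q, ww))
                if len(k_l):
                    wl = -c_l * lam_a[k_l]
                    for off1, w1 in cols_K:
                        parts.append((r_l + self.off_v, off1 + j_l, w1 * wl))
                        parts.append((off1 + j_l, r_l + self.off_v, w1 * wl))
        return _coo_accumulate(parts, (self.nz, self.nz))

    # -- linear structure and bounds -------------------------------------
    def linear_constraints(self):
        out = []
        S = _independent_rows(self.net.stoichiometric_matrix())
        if S.size:
            A = sps.hstack([sps.csr_matrix(S),
                            sps.csr_matrix((S.shape[0], self.nz - self.nr))])
            out.append(scipy.optimize.LinearConstraint(A, 0.0, 0.0))
        if self.net.R.size:
            A = sps.hstack([sps.csr_matrix(self.net.R),
                            sps.csr_matrix((self.net.R.shape[0],
                                            self.nz - self.nr))])
            out.append(scipy.optimize.LinearConstraint(A, -np.inf, self.net.b))
        return out

    def bounds(self):
        lb_v, ub_v = self.net.bounds_arrays()
        plo, phi = self._pool_bound_arrays()
        xlo, xhi = self.state_box if self.state_box else (-np.inf, np.inf)
        lb = np.concatenate([lb_v, plo, np.full(self.nh, 1e-3),
                             np.full(self.G * self.n, xlo),
                             np.full(self.G * self.s * self.n, -np.inf)])
        ub = np.concatenate([ub_v, phi, np.full(self.nh, 1e3),
                             np.full(self.G * self.n, xhi),
                             np.full(self.G * self.s * self.n, np.inf)])
        return scipy.optimize.Bounds(lb, ub)

    def _pool_bound_arrays(self):
        lo, hi = [], []
        for m in self.pools.metabolites:
            l, h = self.net.pool_bounds.get(m, self.net.default_pool_bounds)
            lo.append(l); hi.append(h)
        return np.array(lo), np.array(hi)

    # -- starting points -------------------------------------------------
    def initial_point(self, v0, pools0):
        """Feasible start: states from an implicit-RK forward solve at (v0, p0).

        The integration is used once, before the optimization begins, to
        seed the transcription variables with a consistent trajectory;
        the solver itself never re-integrates.
        """
        v0 = np.asarray(v0, float)
        p_k = self.pools.state_pools(np.asarray(pools0, float))
        inv_p = 1.0 / p_k

        def f(t, x):
            return inv_p * self.bound.production(x, v0)

        def jac(t, x):
            return sps.diags(inv_p) @ self.bound.jac_x(x, v0)

        try:
            x_nodes, ks = radau_integrate(f, jac, self.x_init, self.grid,
                                          self.scheme)
        except Exception:
            traj = integrate_labeling(self.bound, v0, p_k, self.grid.nodes,
                                      self.x_init, method="stiff")
            x_nodes = traj.x
            ks = [np.array([f(0.0, x_nodes[g + 1]) for _ in range(self.s)])
                  for g in range(self.G)]
        z0 = np.empty(self.nz)
        z0[:self.nr] = v0
        z0[self.off_p:self.off_p + self.nm] = pools0
        z0[self.off_h:self.off_h + self.nh] = 1.0
        for g in range(1, self.G + 1):
            z0[self.x_slice(g)] = np.clip(x_nodes[g], 0.0, 1.0)
            for a in range(self.s):
                z0[self.k_slice(g, a)] = ks[g - 1][a]
        return z0

    def sample_start(self, seed):
        v0, p0 = sample_feasible_fluxes_pools(self.net, seed)
        return self.initial_point(v0, p0)

    # -- results ----------------------------------------------------------
    def unpack(self, z) -> FitResult:
        v = z[:self.nr].copy()
        p = z[self.off_p:self.off_p + self.nm].copy()
        h = z[self.off_h:self.off_h + self.nh].copy() if self.nh else None
        x_nodes = np.vstack([self.x_init[None, :]] +
                            [z[self.x_slice(g)][None, :]
                             for g in range(1, self.G + 1)])
        ks = [self.k_gamma(z, g).copy() for g in range(1, self.G + 1)]
        return FitResult(v=v, pools=p, h=h, z=self.obj.value(z), status="",
                         feasibility=float(np.abs(self.eq_fun(z)).max()),
                         n_iter=0, zvar=z.copy(), scheme_order=self.scheme.order,
                         x_nodes=x_nodes, stage_k=ks)

    def fitted_measurements(self, z) -> np.ndarray:
        """Unscaled simulated measurements, (n_rows, n_times)."""
        res = self.obj  # labeling rows are the first n_rows * nt residuals
        mm = self.mm
        out = np.empty((mm.n_rows, self.nt))
        fit = self.unpack(z)
        for mu, t in enumerate(mm.times):
            gamma, tau = self.grid.locate(float(t))
            h_g = self.grid.h[gamma - 1]
            x_mu = fit.x_nodes[gamma - 1] + \
                h_g * self.scheme.B(tau) @ fit.stage_k[gamma - 1]
            out[:, mu] = mm.simulate(x_mu)
        return out

    def with_values(self, values: np.ndarray) -> "InstProblem":
        mm = dataclasses.replace(self.mm, values=values)
        return InstProblem(self.net, self.bound, self.pools, mm, self.grid,
                           self.scheme, self.x_init, self.scaling,
                           self.state_box)

    def n_free_parameters(self) -> int:
        return count_independent_fluxes(self.net) + self.nm + self.nh

    def describe(self) -> dict:
        sysd = self.system
        return {
            "n_vars": self.nz,
            "n_eq": self.n_eq + len(self.net.balanced),
            "blocks": {"v": self.nr, "p_met": self.nm, "h": self.nh,
                       "x": self.G * self.n, "k": self.G * self.s * self.n},
            "printed_transcription": {
                "n_vars": sysd.n_vars_full,
                "n_constraints": sysd.n_constraints_full},
            "interpolation_rows": self.nt * self.n,
            "measurement_rows": self.mm.n_rows * self.nt,
        }


# ---------------------------------------------------------------------------
# assembly fronts

def assemble_steady_nlp(net, bound, mm, scaling="fixed") -> SteadyProblem:
    return SteadyProblem(net, bound, mm, scaling=scaling)


def assemble_inst_nlp(net, bound, pools, mm, grid, scheme, x_init,
                      scaling="fixed") -> InstProblem:
    return InstProblem(net, bound, pools, mm, grid, scheme, x_init,
                       scaling=scaling)


# ---------------------------------------------------------------------------
# solving

def solve_nlp(problem, start, tol: float = FEASIBILITY_TOL,
              maxiter: int = 1500, verbose: int = 0) -> FitResult:
    """Solve an assembled problem from a start vector (or (v0, pools0)).

    Contract: the backend consumes sparse first derivatives (and the exact
    Lagrangian Hessian), honours the equality feasibility tolerance, and
    always surfaces a status; an infeasible start is repaired once by
    forward-integration re-initialization before giving up.
    """
    z0 = _coerce_start(problem, start)
    res = _run_trust_constr(problem, z0, tol, maxiter, verbose)
    if not np.isfinite(res.fun) or res.constr_violation > 1e-2:
        # repair: re-seed states by forward integration at the current v, p
        fit0 = problem.unpack(np.clip(z0, problem.bounds().lb,
                                      problem.bounds().ub))
        if problem.kind == "inst":
            z0 = problem.initial_point(fit0.v, fit0.pools)
        else:
            z0 = problem.initial_point(fit0.v)
        res = _run_trust_constr(problem, z0, tol, maxiter, verbose)
    fit = problem.unpack(res.x)
    feas = max(float(res.constr_violation), fit.feasibility)
    if feas <= tol:
        status = "optimal" if res.status in (1, 2) else "iteration-limit"
        if res.status == 2:
            status = "locally-optimal"
    else:
        status = "infeasible"
    fit.status = status
    fit.n_iter = int(res.niter)
    fit.feasibility = feas
    return fit


def _coerce_start(problem, start):
    if isinstance(start, np.ndarray) and start.size == problem.nz:
        return start.astype(float)
    if isinstance(start, tuple):
        return problem.initial_point(*start)
    raise NetworkError("start must be a full variable vector or (v0, pools0)")


def _run_trust_constr(problem, z0, tol, maxiter, verbose):
    nlc = scipy.optimize.NonlinearConstraint(
        problem.eq_fun, 0.0, 0.0, jac=problem.eq_jac, hess=problem.eq_hess)
    constraints = [nlc] + problem.linear_constraints()
    return scipy.optimize.minimize(
        problem.obj.value, z0, method="trust-constr",
        jac=problem.obj.grad, hess=problem.obj.hess,
        constraints=constraints, bounds=problem.bounds(),
        options={"maxiter": maxiter, "gtol": 1e-6, "xtol": 1e-12,
                 "barrier_tol": 1e-8, "verbose": verbose})


def derive_restart_seed(master_seed: int, i: int) -> int:
    """Counter-based per-restart seed, reproducible in isolation."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(i),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def multistart(problem, n_restarts: int, seed: int,
               tol: float = FEASIBILITY_TOL, maxiter: int = 1500):
    """Independent random restarts; results sorted by objective value."""
    if n_restarts < 1:
        raise NetworkError("n_restarts must be >= 1")
    fits = []
    failures = []
    for i in range(n_restarts):
        si = derive_restart_seed(seed, i)
        try:
            z0 = problem.sample_start(si)
            fit = solve_nlp(problem, z0, tol=tol, maxiter=maxiter)
            fit.seed = si
            fits.append(fit)
        except NetworkError as exc:
            failures.append((si, str(exc)))
    if not fits:
        raise NetworkError(f"all {n_restarts} restarts failed: {failures}")
    return sorted(fits, key=lambda f: f.z)


def refine(best: FitResult, problem: InstProblem, scheme_order: int = 9,
           tol: float = FEASIBILITY_TOL, maxiter: int = 1500):
    """Re-transcribe at a higher order and re-solve from the low-order optimum.

    The high-order transcription is warm-started with a forward implicit-RK
    solve at the low-order parameter estimates, which keeps the start
    feasible for the new constraint system.
    """
    from .collocation import radau_iia
    scheme = radau_iia(scheme_order)
    hi = InstProblem(problem.net, problem.bound, problem.pools, problem.mm,
                     problem.grid, scheme, problem.x_init, problem.scaling,
                     problem.state_box)
    z0 = hi.initial_point(best.v, best.pools)
    if hi.nh and best.h is not None:
        z0[hi.off_h:hi.off_h + hi.nh] = best.h
    fit = solve_nlp(hi, z0, tol=tol, maxiter=maxiter)
    fit.seed = best.seed
    return fit, hi


def chi2_acceptance(n_meas: int, n_params: int, level: float = 0.95) -> float:
    """SSR acceptance threshold: chi-square quantile at dof = n_meas - n_params."""
    dof = n_meas - n_params
    if dof <= 0:
        raise NetworkError(f"nonpositive degrees of freedom ({dof})")
    return float(scipy.stats.chi2.ppf(level, dof))


def bootstrap_ci(problem, fit: FitResult, n_boot: int, seed: int,
                 level: float = 0.95, tol: float = FEASIBILITY_TOL,
                 maxiter: int = 300) -> BootstrapResult:
    """Parametric bootstrap confidence intervals around a converged fit.

    Measurements are resampled as N(fitted value, sigma), the problem is
    refit warm-started from the point estimate, and the per-parameter
    spread of the refits gives sd and percentile intervals.
    """
    rng = np.random.default_rng(seed)
    fitted = problem.fitted_measurements(fit.zvar)
    names = [f"v[{rid}]" for rid in problem.net.reaction_ids]
    if problem.kind == "inst":
        names += [f"p[{m}]" for m in problem.pools.metabolites]
    estimates = []
    n_failed = 0
    for b in range(n_boot):
        noisy = fitted + rng.normal(0.0, problem.mm.sd)
        prob_b = problem.with_values(noisy)
        try:
            fb = solve_nlp(prob_b, fit.zvar.copy(), tol=tol, maxiter=maxiter)
            if not np.isfinite(fb.z) or fb.feasibility > 1e-4:
                raise NetworkError("bootstrap refit did not converge")
            est = fb.v if problem.kind == "steady" else \
                np.concatenate([fb.v, fb.pools])
            estimates.append(est)
        except NetworkError:
            n_failed += 1
    if n_failed > 0.1 * n_boot:
        import warnings
        warnings.warn(f"{n_failed}/{n_boot} bootstrap refits failed and were "
                      "excluded")
    if not estimates:
        raise NetworkError("all bootstrap refits failed")
    E = np.array(estimates)
    alpha = (1.0 - level) / 2.0
    return BootstrapResult(
        names=names, estimates=E, mean=E.mean(axis=0), sd=E.std(axis=0, ddof=1),
        ci_lower=np.quantile(E, alpha, axis=0),
        ci_upper=np.quantile(E, 1.0 - alpha, axis=0),
        n_failed=n_failed)
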