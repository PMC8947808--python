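"""Labeling-state enumeration and sparse balance arrays.

Two state frameworks are supported:

* **cumomer** — for every tracked metabolite with ``n`` carbons, all ``2^n``
  cumulated-isotopomer fractions.  The weight-0 cumomer is identically 1 and
  is treated as a pinned constant; the composite state vector ``x`` holds
  only the nontrivial states, ordered weight-major.
* **emu** — the minimal closed set of elementary metabolite units reachable
  backward from the measured fragments; the state variables are the EMU
  *fractional abundances* (one per mass shift), so a size-``w`` EMU
  contributes ``w + 1`` entries to ``x``.

For either framework the net production rate of state ``k`` is

    sum_r v_r ( 1/2 sum_ij Q_rkij x_i x_j + sum_j P_rkj x_j
                + sum_j Pinp_rkj xinp_j )

with ``Q`` the bimolecular (condensation) array, ``P`` unimolecular
production and consumption, and ``Pinp`` entry of fed substrates.  ``Q`` is
stored symmetrically: off-diagonal condensations appear once per ordering
with value ``s`` and self-condensations carry a diagonal ``2s``, so the
explicit 1/2 factor in the balance reproduces ``s * x_i * x_j`` exactly.

The arrays are built once per network; :func:`bind_inputs` folds the known
constants (weight-0 cumomers and input-substrate states) into numeric
coefficient tables used by the simulators and the NLP assembly.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse

from .network import Network, NetworkError

__all__ = [
    "StateIndex",
    "ModelArrays",
    "BoundArrays",
    "PoolModel",
    "enumerate_cumomers",
    "emu_decompose",
    "build_model_arrays",
    "build_input_vector",
    "initial_state",
    "build_pool_model",
    "bind_inputs",
    "NATURAL_13C",
]

NATURAL_13C = 0.0107  # default fractional 13C natural abundance


def popcount(mask: int) -> int:
    return bin(mask).count("1")


@dataclass(frozen=True, order=True)
class StateIndex:
    """One labeling state: a metabolite, an atom subset, optionally a mass.

    ``atoms`` is a bitmask over carbon positions (bit 0 = carbon 1).
    ``mass`` is the mass shift for EMU fractional abundances and -1 in the
    cumomer framework.  Ordering is weight-major, then metabolite name,
    then bitmask, then mass — a stable order that makes the weight cascade
    and the sparsity patterns reproducible.
    """

    weight: int
    metabolite: str
    atoms: int
    mass: int = -1

    @staticmethod
    def make(metabolite: str, atoms: int, mass: int = -1) -> "StateIndex":
        return StateIndex(popcount(atoms), metabolite, atoms, mass)

    @property
    def is_zero_order(self) -> bool:
        return self.weight == 0

    def positions(self) -> tuple[int, ...]:
        """1-based carbon positions in the atom subset."""
        return tuple(p + 1 for p in range(self.atoms.bit_length())
                     if self.atoms >> p & 1)

    def __repr__(self):
        pos = ",".join(map(str, self.positions())) or "-"
        tail = f";M+{self.mass}" if self.mass >= 0 else ""
        return f"{self.metabolite}{{{pos}{tail}}}"


@dataclass(frozen=True)
class Term:
    """One production/consumption entry of the balance arrays.

    ``net`` holds 0, 1 or 2 composite-state indices; ``inp`` holds indices
    into the input-state vector whose (constant) values multiply ``val``.
    Two-factor terms follow the symmetric-Q storage convention described in
    the module docstring.
    """

    r: int
    k: int
    net: tuple[int, ...]
    inp: tuple[int, ...]
    val: float


@dataclass
class ModelArrays:
    framework: str                       # "cumomer" | "emu"
    states: list[StateIndex]             # nontrivial tracked states, ordered
    index: dict[StateIndex, int]
    inp_states: list[StateIndex]         # constant states (fed substrates)
    inp_index: dict[StateIndex, int]
    terms: list[Term]
    n_reactions: int
    emus: list[tuple[str, int]] = field(default_factory=list)  # EMU framework only

    @property
    def n_states(self) -> int:
        return len(self.states)

    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.states])


# ---------------------------------------------------------------------------
# state enumeration

def enumerate_cumomers(net: Network, include_zero_order: bool = True):
    """All cumomer states of the tracked metabolites, weight-major order.

    Returns the full ``2^n`` enumeration per metabolite; zero-order states
    (weight 0, pinned to 1) lead the ordering when included.
    """
    states = []
    for m in net.internal_metabolites:
        n = net.metabolites[m].n_carbons
        if n == 0:
            raise NetworkError(f"metabolite {m} has no mapped carbons")
        lo = 0 if include_zero_order else 1
        for mask in range(lo, 1 << n):
            states.append(StateIndex.make(m, mask))
    return sorted(states)


def _producing_maps(net: Network, met: str):
    """Yield (reaction index, product occurrence index, inverse atom map).

    The inverse map sends each product position of ``met`` to its
    (reactant occurrence, reactant position) source.
    """
    for r, rxn in enumerate(net.reactions):
        amap = rxn.atom_map_dict
        for pi, occ in enumerate(rxn.products):
            if occ.metabolite != met or occ.atoms is None:
                continue
            inv = {p: amap[(pi, p)] for p in range(len(occ.atoms))}
            yield r, pi, occ, inv


def emu_decompose(net: Network, targets) -> list[tuple[str, int]]:
    """Minimal closed EMU set reachable backward from the target fragments.

    ``targets`` is an iterable of ``(metabolite, atom bitmask)`` or
    ``(metabolite, positions iterable)``.  Returns ``(metabolite, mask)``
    pairs sorted by size then name then mask; input-substrate EMUs are
    included (their mass distributions are constants of the problem).
    """
    roles = {m: met.role for m, met in net.metabolites.items()}
    work: list[tuple[str, int]] = []
    for met, atoms in targets:
        mask = atoms if isinstance(atoms, int) else _positions_to_mask(atoms)
        n = net.metabolites[met].n_carbons
        if mask <= 0 or mask >= 1 << n:
            if mask != (1 << n) - 1 and mask >= 1 << n:
                raise NetworkError(
                    f"target fragment atoms {bin(mask)} exceed the "
                    f"{n}-carbon backbone of {met}")
        work.append((met, mask))
    closed: set[tuple[str, int]] = set()
    while work:
        emu = work.pop()
        if emu in closed:
            continue
        closed.add(emu)
        met, mask = emu
        if roles.get(met) == "input":
            continue
        for r, pi, occ, inv in _producing_maps(net, met):
            groups: dict[int, int] = {}
            for p in range(len(occ.atoms)):
                if mask >> p & 1:
                    ri, q = inv[p]
                    groups[ri] = groups.get(ri, 0) | (1 << q)
            rxn = net.reactions[r]
            for ri, sub in groups.items():
                work.append((rxn.reactants[ri].metabolite, sub))
    return sorted(closed, key=lambda e: (popcount(e[1]), e[0], e[1]))


def _positions_to_mask(positions) -> int:
    mask = 0
    for p in positions:
        mask |= 1 << (int(p) - 1)
    return mask


def emu_states(net: Network, emus) -> tuple[list[StateIndex], list[StateIndex]]:
    """Split an EMU list into tracked and input (constant) mass-fraction states."""
    tracked, inputs = [], []
    for met, mask in emus:
        w = popcount(mask)
        dest = inputs if net.metabolites[met].role == "input" else tracked
        for mass in range(w + 1):
            dest.append(StateIndex.make(met, mask, mass))
    return sorted(tracked), sorted(inputs)


# ---------------------------------------------------------------------------
# balance array construction

def build_model_arrays(net: Network, framework: str = "cumomer",
                       targets=None) -> ModelArrays:
    """Build the sparse Q/P/Pinp balance arrays for the chosen framework.

    ``targets`` (fragment atom sets) seeds the EMU decomposition and is
    required in EMU mode; the cumomer mode enumerates all states.
    """
    if not net.split_done:
        raise NetworkError("split reversible reactions before building arrays")
    if framework == "cumomer":
        states = [s for s in enumerate_cumomers(net) if not s.is_zero_order]
        return _build_terms_cumomer(net, states)
    if framework == "emu":
        if targets is None:
            raise NetworkError("EMU decomposition needs target fragments")
        emus = emu_decompose(net, targets)
        return _build_terms_emu(net, emus)
    raise NetworkError(f"unknown framework {framework!r}")


def _factor_state(net, met, sub, mass=-1):
    """(state, is_input) for a pre-image group of a production term."""
    role = net.metabolites[met].role
    return StateIndex.make(met, sub, mass), role == "input"


def _build_terms_cumomer(net: Network, states: list[StateIndex]) -> ModelArrays:
    index = {s: k for k, s in enumerate(states)}
    inp_states: list[StateIndex] = []
    inp_index: dict[StateIndex, int] = {}

    def inp_id(state: StateIndex) -> int:
        if state not in inp_index:
            inp_index[state] = len(inp_states)
            inp_states.append(state)
        return inp_index[state]

    terms: list[Term] = []
    tracked = set(net.internal_metabolites)
    # consumption: every reaction consuming the metabolite drains each cumomer
    for r, rxn in enumerate(net.reactions):
        for occ in rxn.reactants:
            if occ.metabolite in tracked and occ.atoms is not None:
                n = len(occ.atoms)
                for mask in range(1, 1 << n):
                    k = index[StateIndex.make(occ.metabolite, mask)]
                    terms.append(Term(r, k, (k,), (), -occ.coeff))
    # production: product cumomer = product of reactant cumomers of the
    # atom-map pre-image, grouped by reactant occurrence
    for met in tracked:
        n = net.metabolites[met].n_carbons
        for r, pi, occ, inv in _producing_maps(net, met):
            rxn = net.reactions[r]
            for mask in range(1, 1 << n):
                k = index[StateIndex.make(met, mask)]
                groups: dict[int, int] = {}
                for p in range(n):
                    if mask >> p & 1:
                        ri, q = inv[p]
                        groups[ri] = groups.get(ri, 0) | (1 << q)
                terms.extend(_emit_production(
                    net, r, k, occ.coeff,
                    [(rxn.reactants[ri].metabolite, sub, -1)
                     for ri, sub in sorted(groups.items())],
                    index, inp_id))
    return ModelArrays("cumomer", states, index, inp_states, inp_index,
                       terms, len(net.reactions))


def _build_terms_emu(net: Network, emus) -> ModelArrays:
    tracked_states, input_states = emu_states(net, emus)
    index = {s: k for k, s in enumerate(tracked_states)}
    inp_index = {s: j for j, s in enumerate(input_states)}
    tracked_emus = {(m, a) for m, a in emus
                    if net.metabolites[m].role != "input"}

    def inp_id(state: StateIndex) -> int:
        return inp_index[state]

    terms: list[Term] = []
    # consumption: any reaction consuming the metabolite consumes the EMU
    for r, rxn in enumerate(net.reactions):
        for occ in rxn.reactants:
            for met, mask in tracked_emus:
                if occ.metabolite == met and occ.atoms is not None:
                    w = popcount(mask)
                    for mass in range(w + 1):
                        k = index[StateIndex.make(met, mask, mass)]
                        terms.append(Term(r, k, (k,), (), -occ.coeff))
    # production with mass-shift convolution over pre-image groups
    for met, mask in sorted(tracked_emus):
        w = popcount(mask)
        for r, pi, occ, inv in _producing_maps(net, met):
            rxn = net.reactions[r]
            groups: dict[int, int] = {}
            for p in range(len(occ.atoms)):
                if mask >> p & 1:
                    ri, q = inv[p]
                    groups[ri] = groups.get(ri, 0) | (1 << q)
            parts = [(rxn.reactants[ri].metabolite, sub)
                     for ri, sub in sorted(groups.items())]
            sizes = [popcount(sub) for _, sub in parts]
            for mass in range(w + 1):
                k = index[StateIndex.make(met, mask, mass)]
                for split in _mass_splits(mass, sizes):
                    terms.extend(_emit_production(
                        net, r, k, occ.coeff,
                        [(pm, psub, ms) for (pm, psub), ms in zip(parts, split)],
                        index, inp_id))
    arrays = ModelArrays("emu", tracked_states, index, input_states,
                         inp_index, terms, len(net.reactions))
    arrays.emus = list(emus)
    return arrays


def _mass_splits(total, sizes):
    """All ways to distribute `total` mass shifts over parts with capacities."""
    if len(sizes) == 1:
        return [(total,)] if total <= sizes[0] else []
    out = []
    for m0 in range(min(total, sizes[0]) + 1):
        for rest in _mass_splits(total - m0, sizes[1:]):
            out.append((m0,) + rest)
    return out


def _emit_production(net, r, k, coeff, parts, index, inp_id):
    """Terms for one production pathway; parts are (met, submask, mass)."""
    net_ids, inp_ids = [], []
    for met, sub, mass in parts:
        state, is_inp = _factor_state(net, met, sub, mass)
        if is_inp:
            inp_ids.append(inp_id(state))
        else:
            net_ids.append(index[state])
    inp_ids = tuple(sorted(inp_ids))
    if len(net_ids) == 0:
        return [Term(r, k, (), inp_ids, coeff)]
    if len(net_ids) == 1:
        return [Term(r, k, (net_ids[0],), inp_ids, coeff)]
    if len(net_ids) == 2:
        i, j = net_ids
        if i == j:
            return [Term(r, k, (i, i), inp_ids, 2.0 * coeff)]
        return [Term(r, k, (i, j), inp_ids, coeff),
                Term(r, k, (j, i), inp_ids, coeff)]
    raise NetworkError(
        "a production pathway couples more than two tracked states "
        "(>2-molecular condensation in labeling space is not supported)")


# ---------------------------------------------------------------------------
# input vector, initial conditions, pool model

def _atom_enrichments(met_carbons: int, tracer_components, natural_abundance: float):
    """Per-component (fraction, per-atom enrichment list)."""
    comps = []
    total = 0.0
    for comp in tracer_components:
        frac = float(comp.get("fraction", 1.0))
        total += frac
        enrich = float(comp.get("enrichment", 1.0))
        if not (0.0 <= enrich <= 1.0):
            raise NetworkError(f"tracer enrichment {enrich} outside [0, 1]")
        atoms = comp.get("atoms", "U")
        if atoms in ("U", "u", "all"):
            labeled = set(range(1, met_carbons + 1))
        else:
            labeled = {int(a) for a in atoms}
        e = [enrich if p in labeled else natural_abundance
             for p in range(1, met_carbons + 1)]
        comps.append((frac, e))
    if abs(total - 1.0) > 1e-9:
        raise NetworkError(f"tracer mixture fractions sum to {total}, not 1")
    return comps


def build_input_vector(net: Network, arrays: ModelArrays, tracers,
                       natural_abundance: float = NATURAL_13C) -> np.ndarray:
    """Constant values for every input state of the arrays.

    ``tracers`` maps substrate name -> list of mixture components, each a
    dict with keys ``fraction``, ``atoms`` (1-based positions or "U") and
    ``enrichment``.  Unlisted substrates and unlisted atoms sit at natural
    abundance.  Cumomer value of atom set A = sum over the mixture of
    f * prod_{a in A} enrichment(a); EMU entries are the corresponding mass
    distributions.
    """
    x_inp = np.zeros(len(arrays.inp_states))
    for j, state in enumerate(arrays.inp_states):
        met = state.metabolite
        n = net.metabolites[met].n_carbons
        comps = _atom_enrichments(n, tracers.get(met, [{"fraction": 1.0,
                                                        "atoms": [],
                                                        "enrichment": 0.0}]),
                                  natural_abundance)
        positions = state.positions()
        if state.mass < 0:  # cumomer
            x_inp[j] = sum(f * np.prod([e[p - 1] for p in positions])
                           for f, e in comps)
        else:  # EMU mass fraction
            val = 0.0
            for f, e in comps:
                dist = np.ones(1)
                for p in positions:
                    dist = np.convolve(dist, [1.0 - e[p - 1], e[p - 1]])
                val += f * dist[state.mass]
            x_inp[j] = val
    return x_inp


def initial_state(net: Network, arrays: ModelArrays,
                  natural_abundance: float = NATURAL_13C,
                  overrides: dict | None = None) -> np.ndarray:
    """Initial composite state vector for the labeling dynamics.

    Tracked metabolites start at natural isotope abundance (cumomer of
    weight w = na^w; EMU mass fractions binomial), unless ``overrides``
    supplies tracer-style components for a metabolite (an impulse input of
    label at t = 0).
    """
    overrides = overrides or {}
    x0 = np.zeros(arrays.n_states)
    for k, state in enumerate(arrays.states):
        met = state.metabolite
        n = net.metabolites[met].n_carbons
        if met in overrides:
            comps = _atom_enrichments(n, overrides[met], natural_abundance)
        else:
            comps = [(1.0, [natural_abundance] * n)]
        positions = state.positions()
        if state.mass < 0:
            x0[k] = sum(f * np.prod([e[p - 1] for p in positions])
                        for f, e in comps)
        else:
            val = 0.0
            for f, e in comps:
                dist = np.ones(1)
                for p in positions:
                    dist = np.convolve(dist, [1.0 - e[p - 1], e[p - 1]])
                val += f * dist[state.mass]
            x0[k] = val
    return x0


@dataclass
class PoolModel:
    """Maps metabolite pool sizes to per-state pool sizes, p_k = (D p)_k."""

    metabolites: list[str]
    D: scipy.sparse.csr_matrix  # n_states x n_metabolites, one 1 per row

    def state_pools(self, p_met: np.ndarray) -> np.ndarray:
        return self.D @ p_met

    @property
    def n_pools(self) -> int:
        return len(self.metabolites)


def build_pool_model(net: Network, arrays: ModelArrays) -> PoolModel:
    """0/1 matrix D tying every state of a metabolite to one shared pool."""
    mets = sorted({s.metabolite for s in arrays.states})
    col = {m: i for i, m in enumerate(mets)}
    rows = np.arange(arrays.n_states)
    cols = np.array([col[s.metabolite] for s in arrays.states])
    D = scipy.sparse.csr_matrix(
        (np.ones(arrays.n_states), (rows, cols)),
        shape=(arrays.n_states, len(mets)))
    return PoolModel(mets, D)


# ---------------------------------------------------------------------------
# numeric binding

class BoundArrays:
    """Balance arrays with input constants folded in; fast evaluation.

    Provides the net production rate g(x, v) and its sparse Jacobians with
    respect to x and v.  Terms are compiled to flat numpy index arrays:

    * ``const``: 0 tracked factors  -> g_k += c * v_r
    * ``lin``:   1 tracked factor   -> g_k += c * v_r * x_j
    * ``quad``:  2 tracked factors  -> g_k += 1/2 c * v_r * x_i * x_j
    """

    def __init__(self, arrays: ModelArrays, x_inp: np.ndarray):
        self.arrays = arrays
        self.x_inp = np.asarray(x_inp, float)
        self.n = arrays.n_states
        self.n_reactions = arrays.n_reactions
        const, lin, quad = [], [], []
        for t in arrays.terms:
            c = t.val * float(np.prod([self.x_inp[j] for j in t.inp])) \
                if t.inp else t.val
            if len(t.net) == 0:
                const.append((t.r, t.k, c))
            elif len(t.net) == 1:
                lin.append((t.r, t.k, t.net[0], c))
            else:
                quad.append((t.r, t.k, t.net[0], t.net[1], c))
        self.const = _cols(const, 3)
        self.lin = _cols(lin, 4)
        self.quad = _cols(quad, 5)
        w = arrays.weights()
        self.level_of = w if arrays.framework == "cumomer" else \
            np.array([s.weight for s in arrays.states])
        self.levels = sorted(set(self.level_of.tolist()))

    # -- evaluation ----------------------------------------------------
    def production(self, x: np.ndarray, v: np.ndarray) -> np.ndarray:
        g = np.zeros(self.n)
        r, k, c = self.const
        if len(k):
            np.add.at(g, k, c * v[r])
        r, k, j, c = self.lin
        if len(k):
            np.add.at(g, k, c * v[r] * x[j])
        r, k, i, j, c = self.quad
        if len(k):
            np.add.at(g, k, 0.5 * c * v[r] * x[i] * x[j])
        return g

    def jac_x(self, x: np.ndarray, v: np.ndarray) -> scipy.sparse.csr_matrix:
        rows, cols, data = [], [], []
        r, k, j, c = self.lin
        if len(k):
            rows.append(k); cols.append(j); data.append(c * v[r])
        r, k, i, j, c = self.quad
        if len(k):
            rows.append(k); cols.append(i); data.append(0.5 * c * v[r] * x[j])
            rows.append(k); cols.append(j); data.append(0.5 * c * v[r] * x[i])
        if not rows:
            return scipy.sparse.csr_matrix((self.n, self.n))
        return scipy.sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n))

    def jac_v(self, x: np.ndarray) -> scipy.sparse.csr_matrix:
        rows, cols, data = [], [], []
        r, k, c = self.const
        if len(k):
            rows.append(k); cols.append(r); data.append(c)
        r, k, j, c = self.lin
        if len(k):
            rows.append(k); cols.append(r); data.append(c * x[j])
        r, k, i, j, c = self.quad
        if len(k):
            rows.append(k); cols.append(r); data.append(0.5 * c * x[i] * x[j])
        if not rows:
            return scipy.sparse.csr_matrix((self.n, self.n_reactions))
        return scipy.sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n_reactions))


def _cols(entries, n):
    if not entries:
        return tuple(np.zeros(0, dtype=int) if i < n - 1 else np.zeros(0)
                     for i in range(n))
    arr = list(zip(*entries))
    return tuple(np.array(a, dtype=(float if i == n - 1 else int))
                 for i, a in enumerate(arr))


def bind_inputs(arrays: ModelArrays, x_inp: np.ndarray) -> BoundArrays:
    """Fold the constant input-state values into numeric coefficient tables."""
    return BoundArrays(arrays, x_inp)
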