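"""Metabolic network parsing, stoichiometry and feasible-point sampling.

A network is written one reaction per line::

    # three-carbon transfer with scrambling
    v1: A (abc) -> B (bca)
    v2: C (ab) + D (c) <-> E (abc)
    v3: 2 X (a) -> Y (ab)      # self-condensation

Lowercase letters name carbon atoms.  Letters on the reactant side declare
atoms; the letters of each product state which reactant atom lands at each
product position.  Species without a parenthesised map (cofactors) carry no
carbon bookkeeping.  Reversible reactions are written with ``<->`` and are
split into separate forward/reverse irreversible reactions before any
labeling mathematics, since all flux values must be nonnegative.

Roles (which metabolites are fed substrates, which are external sinks),
flux bounds and flux measurements come from a separate structured config,
see :func:`apply_config`.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize
import scipy.sparse

__all__ = [
    "Metabolite",
    "Occurrence",
    "Reaction",
    "Network",
    "NetworkError",
    "parse_network",
    "split_reversible",
    "count_independent_fluxes",
    "sample_feasible_fluxes_pools",
]

DEFAULT_FLUX_UB = 100.0


class NetworkError(ValueError):
    """Raised for malformed network definitions or infeasible stoichiometry."""


@dataclass(frozen=True)
class Metabolite:
    name: str
    n_carbons: int
    role: str = "balanced"  # balanced | input | output

    def __post_init__(self):
        if self.n_carbons < 0:
            raise NetworkError(f"metabolite {self.name}: negative carbon count")
        if self.role not in ("balanced", "input", "output"):
            raise NetworkError(f"metabolite {self.name}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Occurrence:
    """One species slot on one side of a reaction."""

    metabolite: str
    coeff: float
    atoms: tuple[str, ...] | None  # letters, or None for unmapped species


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[Occurrence, ...]
    products: tuple[Occurrence, ...]
    reversible: bool = False
    v_lb: float = 0.0
    v_ub: float = DEFAULT_FLUX_UB
    # atom_map[(product_occ_index, product_pos)] = (reactant_occ_index, reactant_pos)
    # positions are 0-based; filled in by the parser
    atom_map: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = ()

    @property
    def atom_map_dict(self) -> dict[tuple[int, int], tuple[int, int]]:
        return dict(self.atom_map)

    def carbon_count(self, side: str) -> float:
        occs = self.reactants if side == "reactants" else self.products
        return sum(o.coeff * len(o.atoms) for o in occs if o.atoms is not None)


@dataclass
class Network:
    """Parsed reaction network with stoichiometric structure.

    ``S`` rows run over balanced metabolites, columns over reactions.
    ``R, b`` hold linear inequality constraints ``R v <= b`` (used for
    net-flux bounds of split reversible reactions).
    """

    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    R: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    b: np.ndarray = field(default_factory=lambda: np.zeros(0))
    flux_measurements: list[tuple[str, float, float]] = field(default_factory=list)
    pool_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_pool_bounds: tuple[float, float] = (1e-2, 1e2)
    pool_measurements: list[tuple[str, float, float]] = field(default_factory=list)
    split_done: bool = False

    # -- index helpers -------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction_index(self, rid: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == rid:
                return i
        raise NetworkError(f"unknown reaction {rid!r}")

    @property
    def balanced(self) -> list[str]:
        return [m for m, met in self.metabolites.items() if met.role == "balanced"]

    @property
    def internal_metabolites(self) -> list[str]:
        """Metabolites whose labeling state is tracked (everything not fed)."""
        return [m for m, met in self.metabolites.items()
                if met.role == "balanced" and met.n_carbons > 0]

    def stoichiometric_matrix(self) -> np.ndarray:
        rows = {m: q for q, m in enumerate(self.balanced)}
        S = np.zeros((len(rows), len(self.reactions)))
        for r, rxn in enumerate(self.reactions):
            for occ in rxn.reactants:
                if occ.metabolite in rows:
                    S[rows[occ.metabolite], r] -= occ.coeff
            for occ in rxn.products:
                if occ.metabolite in rows:
                    S[rows[occ.metabolite], r] += occ.coeff
        return S

    @property
    def S(self) -> np.ndarray:
        return self.stoichiometric_matrix()

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.v_lb for r in self.reactions])
        ub = np.array([r.v_ub for r in self.reactions])
        return lb, ub

    def pool_bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for m in self.internal_metabolites:
            l, h = self.pool_bounds.get(m, self.default_pool_bounds)
            lo.append(l)
            hi.append(h)
        return np.array(lo), np.array(hi)


# ---------------------------------------------------------------------------
# parsing

_TERM_RE = re.compile(
    r"^\s*(?:(?P<coeff>\d+(?:\.\d+)?)\s+)?(?P<name>[A-Za-z_]\w*)"
    r"\s*(?:\(\s*(?P<map>[a-z]+)\s*\))?\s*$"
)


def _parse_side(text: str, rid: str, lineno: int) -> list[Occurrence]:
    occs = []
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise NetworkError(
                f"line {lineno}: reaction {rid}: cannot parse species term {term.strip()!r}")
        coeff = float(m.group("coeff") or 1.0)
        amap = tuple(m.group("map")) if m.group("map") else None
        occs.append(Occurrence(m.group("name"), coeff, amap))
    return occs


def _build_atom_map(rid: str, lineno: int, reactants, products):
    donors: dict[str, tuple[int, int]] = {}
    for ri, occ in enumerate(reactants):
        if occ.atoms is None:
            continue
        for q, letter in enumerate(occ.atoms):
            if letter in donors:
                raise NetworkError(
                    f"line {lineno}: reaction {rid}: atom letter {letter!r} "
                    "used twice on the reactant side")
            donors[letter] = (ri, q)
    amap = []
    used = set()
    for pi, occ in enumerate(products):
        if occ.atoms is None:
            continue
        for p, letter in enumerate(occ.atoms):
            if letter not in donors:
                raise NetworkError(
                    f"line {lineno}: reaction {rid}: product atom {letter!r} "
                    "has no source on the reactant side (unbalanced carbon map)")
            if letter in used:
                raise NetworkError(
                    f"line {lineno}: reaction {rid}: reactant atom {letter!r} "
                    "consumed by two product positions")
            used.add(letter)
            amap.append(((pi, p), donors[letter]))
    missing = set(donors) - used
    if missing:
        raise NetworkError(
            f"line {lineno}: reaction {rid}: reactant atoms "
            f"{sorted(missing)} not placed in any product (unbalanced carbon map)")
    return tuple(amap)


def parse_network(text: str) -> Network:
    """Parse a network definition document into a :class:`Network`.

    Reversible reactions are flagged but not yet split; all metabolites
    default to the ``balanced`` role until :func:`apply_config` assigns
    substrate/sink roles and bounds.
    """
    metabolites: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    seen_ids = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise NetworkError(f"line {lineno}: expected 'id: reactants -> products'")
        rid, rest = line.split(":", 1)
        rid = rid.strip()
        if rid in seen_ids:
            raise NetworkError(f"line {lineno}: duplicate reaction id {rid!r}")
        seen_ids.add(rid)
        reversible = "<->" in rest
        arrow = "<->" if reversible else "->"
        if arrow not in rest:
            raise NetworkError(f"line {lineno}: reaction {rid}: missing '->'")
        left, right = rest.split(arrow, 1)
        reactants = _parse_side(left, rid, lineno)
        products = _parse_side(right, rid, lineno)
        amap = _build_atom_map(rid, lineno, reactants, products)
        rxn = Reaction(rid, tuple(reactants), tuple(products),
                       reversible=reversible, atom_map=amap)
        # carbon conservation among mapped species (letters conserve by
        # construction; also require map length consistency with coefficients)
        for occ in reactants + products:
            if occ.atoms is not None and occ.coeff != 1.0 and len(occ.atoms) > 0:
                raise NetworkError(
                    f"line {lineno}: reaction {rid}: carbon-mapped species "
                    f"{occ.metabolite} must have unit stoichiometry; write one "
                    "occurrence per molecule")
        for occ in reactants + products:
            n = len(occ.atoms) if occ.atoms is not None else 0
            if occ.metabolite in metabolites:
                prev = metabolites[occ.metabolite]
                if occ.atoms is not None and prev.n_carbons != n:
                    raise NetworkError(
                        f"line {lineno}: metabolite {occ.metabolite} mapped with "
                        f"{n} carbons here but {prev.n_carbons} elsewhere")
                if occ.atoms is not None and prev.n_carbons == 0:
                    metabolites[occ.metabolite] = Metabolite(occ.metabolite, n)
            else:
                metabolites[occ.metabolite] = Metabolite(occ.metabolite, n)
        reactions.append(rxn)
    if not reactions:
        raise NetworkError("empty network definition")
    return Network(metabolites=metabolites, reactions=reactions)


def apply_config(net: Network, config: dict) -> Network:
    """Apply the structured config section: roles, bounds, measurements.

    Keys understood: ``inputs``, ``outputs`` (lists of metabolite names),
    ``bounds`` (mapping reaction id -> [lb, ub], with ``default``),
    ``flux_measurements`` (mapping id -> [value, sd]),
    ``pool_bounds`` (mapping metabolite -> [lb, ub], with ``default``),
    ``pool_measurements`` (mapping metabolite -> [value, sd]).
    """
    mets = dict(net.metabolites)
    for name in config.get("inputs", []):
        if name not in mets:
            raise NetworkError(f"config input {name!r}: unknown metabolite")
        mets[name] = replace(mets[name], role="input")
    for name in config.get("outputs", []):
        if name not in mets:
            raise NetworkError(f"config output {name!r}: unknown metabolite")
        mets[name] = replace(mets[name], role="output")
    for rxn in net.reactions:
        for occ in rxn.reactants:
            if mets[occ.metabolite].role == "output":
                raise NetworkError(
                    f"reaction {rxn.id}: output metabolite {occ.metabolite} "
                    "cannot be consumed")
        for occ in rxn.products:
            if mets[occ.metabolite].role == "input":
                raise NetworkError(
                    f"reaction {rxn.id}: input metabolite {occ.metabolite} "
                    "cannot be produced")

    bounds = dict(config.get("bounds", {}))
    default = tuple(bounds.pop("default", (0.0, DEFAULT_FLUX_UB)))
    reactions = []
    for rxn in net.reactions:
        lb, ub = bounds.pop(rxn.id, default)
        if not rxn.reversible and lb < 0:
            raise NetworkError(f"reaction {rxn.id}: negative lower bound on an "
                               "irreversible reaction")
        reactions.append(replace(rxn, v_lb=float(lb), v_ub=float(ub)))
    if bounds:
        raise NetworkError(f"bounds given for unknown reactions: {sorted(bounds)}")

    fm = []
    for rid, (val, sd) in dict(config.get("flux_measurements", {})).items():
        if rid not in [r.id for r in reactions]:
            raise NetworkError(f"flux measurement for unknown reaction {rid!r}")
        fm.append((rid, float(val), float(sd)))
    pb = dict(net.pool_bounds)
    cfg_pb = dict(config.get("pool_bounds", {}))
    default_pb = tuple(cfg_pb.pop("default", net.default_pool_bounds))
    for m, (lo, hi) in cfg_pb.items():
        if m not in mets:
            raise NetworkError(f"pool bounds for unknown metabolite {m!r}")
        pb[m] = (float(lo), float(hi))
    pm = []
    for m, (val, sd) in dict(config.get("pool_measurements", {})).items():
        if m not in mets:
            raise NetworkError(f"pool measurement for unknown metabolite {m!r}")
        pm.append((m, float(val), float(sd)))
    return Network(metabolites=mets, reactions=reactions,
                   R=net.R.copy() if net.R.size else np.zeros((0, len(reactions))),
                   b=net.b.copy(),
                   flux_measurements=fm, pool_bounds=pb,
                   default_pool_bounds=default_pb, pool_measurements=pm)


# ---------------------------------------------------------------------------
# reversible splitting

def split_reversible(net: Network, exchange_cap: float | None = None) -> Network:
    """Replace each reversible reaction by forward and reverse halves.

    All fluxes become nonnegative.  When the reversible reaction carried
    net-flux bounds ``[lb, ub]`` (lb possibly negative), inequality rows
    enforcing ``lb <= v_fwd - v_rev <= ub`` are appended to ``R v <= b``.
    The reverse atom map is the inverse of the forward map.  The
    directional fluxes get an upper bound of ``exchange_cap`` (at least
    the net upper bound), limiting how fast a bidirectional reaction may
    exchange label.
    """
    reactions: list[Reaction] = []
    ineq_rows: list[tuple[str, str, float, float]] = []  # (fwd, rev, lb, ub)
    for rxn in net.reactions:
        if not rxn.reversible:
            reactions.append(rxn)
            continue
        fwd_id, rev_id = rxn.id + "_f", rxn.id + "_r"
        inv_map = tuple((src, dst) for dst, src in rxn.atom_map)
        cap = max(abs(rxn.v_lb), abs(rxn.v_ub),
                  DEFAULT_FLUX_UB if exchange_cap is None else exchange_cap)
        reactions.append(Reaction(fwd_id, rxn.reactants, rxn.products,
                                  reversible=False, v_lb=0.0, v_ub=cap,
                                  atom_map=rxn.atom_map))
        reactions.append(Reaction(rev_id, rxn.products, rxn.reactants,
                                  reversible=False, v_lb=0.0, v_ub=cap,
                                  atom_map=inv_map))
        ineq_rows.append((fwd_id, rev_id, rxn.v_lb, rxn.v_ub))

    rid_index = {r.id: i for i, r in enumerate(reactions)}
    R_rows, b_vals = [], []
    for fwd, rev, lb, ub in ineq_rows:
        if np.isfinite(ub):
            row = np.zeros(len(reactions))
            row[rid_index[fwd]] = 1.0
            row[rid_index[rev]] = -1.0
            R_rows.append(row)
            b_vals.append(ub)
        if np.isfinite(lb):
            row = np.zeros(len(reactions))
            row[rid_index[fwd]] = -1.0
            row[rid_index[rev]] = 1.0
            R_rows.append(row)
            b_vals.append(-lb)
    R = np.array(R_rows) if R_rows else np.zeros((0, len(reactions)))
    b = np.array(b_vals)
    out = Network(metabolites=dict(net.metabolites), reactions=reactions,
                  R=R, b=b, flux_measurements=list(net.flux_measurements),
                  pool_bounds=dict(net.pool_bounds),
                  default_pool_bounds=net.default_pool_bounds,
                  pool_measurements=list(net.pool_measurements))
    out.split_done = True
    return out


# ---------------------------------------------------------------------------
# degrees of freedom and sampling

def count_independent_fluxes(net: Network, exclude_fixed: bool = True) -> int:
    """Number of reactions minus rank(S), minus exactly fixed fluxes.

    Numerical rank uses a tolerance of 1e-10 times the largest singular
    value.
    """
    if not net.reactions:
        raise NetworkError("empty network")
    S = net.stoichiometric_matrix()
    if S.size == 0:
        rank = 0
    else:
        sv = np.linalg.svd(S, compute_uv=False)
        rank = int(np.sum(sv > 1e-10 * sv[0])) if sv.size else 0
    n_fixed = 0
    if exclude_fixed:
        n_fixed = sum(1 for r in net.reactions if r.v_lb == r.v_ub)
    return len(net.reactions) - rank - n_fixed


def _feasible_lp(net: Network, c: np.ndarray) -> np.ndarray:
    S = net.stoichiometric_matrix()
    lb, ub = net.bounds_arrays()
    A_ub = net.R if net.R.size else None
    b_ub = net.b if net.R.size else None
    res = scipy.optimize.linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), A_ub=A_ub, b_ub=b_ub,
        bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        raise NetworkError(
            "flux polytope is infeasible or unbounded: " + res.message)
    return res.x


def sample_feasible_fluxes_pools(net: Network, seed: int,
                                 pool_bounds: tuple[np.ndarray, np.ndarray] | None = None,
                                 n_vertices: int = 6):
    """Draw a random feasible flux vector and pool-size vector.

    Each flux sample minimises ``n_vertices`` random normalized linear
    objectives over the polytope ``{S v = 0, R v <= b, lb <= v <= ub}``
    (random vertices / face points) and blends them with Dirichlet
    weights.  The blend keeps the sample feasible (the polytope is
    convex) while moving it off low-dimensional faces, so that starting
    points rarely pin a pathway flux exactly at a bound.  Pool sizes are
    drawn log-uniformly within their bounds.  Deterministic for a given
    seed.
    """
    if not net.split_done:
        raise NetworkError("split reversible reactions before sampling")
    rng = np.random.default_rng(seed)
    nr = len(net.reactions)
    vertices = []
    for _ in range(max(1, n_vertices)):
        c = rng.standard_normal(nr)
        c /= np.linalg.norm(c)
        vertices.append(_feasible_lp(net, c))
    w = rng.dirichlet(np.ones(len(vertices)))
    v = np.asarray(vertices).T @ w
    if pool_bounds is None:
        lo, hi = net.pool_bounds_arrays()
    else:
        lo, hi = pool_bounds
    pools = np.exp(rng.uniform(np.log(lo), np.log(hi)))
    return v, pools
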