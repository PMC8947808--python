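"""Mapping labeling states to mass-spectrometric measurements.

A measured *fragment* is an ordered set of backbone carbons of one
metabolite, optionally with a daughter subset (tandem MS) and an elemental
formula for the atoms outside the carbon backbone (natural-abundance
correction).  Simulated measurements are linear (affine) in the composite
state vector: ``m = M x + m0``, with the constant part coming from the
pinned weight-0 cumomers.

In the cumomer framework a fragment MID row is assembled by Moebius
inversion restricted to subsets of the fragment atoms; tandem parent/
daughter distributions come from the same inversion, so tandem data stays
linear in cumomer space.  In the EMU framework a fragment row simply
selects the mass fractions of the fragment's EMU; tandem fragments are not
expressible there and raise an error directing to cumomer mode.

Measurement tables are flat, diff-able TSV with columns
``fragment_id  metabolite  atoms  daughter_atoms  formula  time  mass
daughter_mass  value  sd``.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from .network import Network, NetworkError
from .labeling import ModelArrays, StateIndex, popcount, _positions_to_mask

__all__ = [
    "FragmentDef",
    "MeasurementModel",
    "cumomers_to_isotopomers",
    "isotopomers_to_cumomers",
    "tandem_mid",
    "natural_abundance_operator",
    "build_measurement_model",
    "read_measurement_table",
    "fragments_from_table",
    "attach_measurements",
]

# isotope abundance tables (mass-shift distributions, configurable)
ISOTOPES: dict[str, list[float]] = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0001],
    "Si": [0.92223, 0.04685, 0.03092],
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class FragmentDef:
    """A measured fragment: backbone atoms plus optional daughter/formula."""

    id: str
    metabolite: str
    atoms: tuple[int, ...]              # 1-based backbone carbon positions
    daughter: tuple[int, ...] = ()      # subset of atoms; empty = single MS
    formula: str = ""                   # elements outside the carbon backbone

    def __post_init__(self):
        if not set(self.daughter) <= set(self.atoms):
            raise NetworkError(
                f"fragment {self.id}: daughter atoms must be a subset of the "
                "backbone atoms")

    @property
    def is_tandem(self) -> bool:
        return len(self.daughter) > 0

    @property
    def mask(self) -> int:
        return _positions_to_mask(self.atoms)

    @property
    def daughter_mask_local(self) -> int:
        """Daughter atoms as a bitmask in fragment-local bit order."""
        mask = 0
        for i, p in enumerate(self.atoms):
            if p in self.daughter:
                mask |= 1 << i
        return mask


# ---------------------------------------------------------------------------
# cumomer <-> isotopomer transforms

def isotopomers_to_cumomers(iso: np.ndarray) -> np.ndarray:
    """Superset sums: cumomer[A] = sum over isotopomers B with B >= A."""
    x = np.array(iso, dtype=float)
    n = x.size.bit_length() - 1
    if 1 << n != x.size:
        raise ValueError("isotopomer vector length must be a power of two")
    for b in range(n):
        bit = 1 << b
        for mask in range(x.size):
            if not mask & bit:
                x[mask] += x[mask | bit]
    return x


def cumomers_to_isotopomers(cum: np.ndarray, clamp_tol: float = 1e-9) -> np.ndarray:
    """Moebius inversion of the cumulated sums back to isotopomer fractions.

    The inversion is exact in theory; negative entries within ``clamp_tol``
    of zero are treated as roundoff, clamped and renormalized, while larger
    negativity raises a ValueError (numerically inconsistent input).
    """
    x = np.array(cum, dtype=float)
    n = x.size.bit_length() - 1
    if 1 << n != x.size:
        raise ValueError("cumomer vector length must be a power of two")
    for b in range(n):
        bit = 1 << b
        for mask in range(x.size):
            if not mask & bit:
                x[mask] -= x[mask | bit]
    if x.min() < -clamp_tol:
        raise ValueError(
            f"cumomer values are inconsistent: isotopomer fraction "
            f"{x.min():.3e} below -{clamp_tol:.0e}")
    if x.min() < 0.0:
        x = np.clip(x, 0.0, None)
        s = x.sum()
        if s > 0:
            x /= s
    return x


def marginal_isotopomers(iso: np.ndarray, atom_bits: tuple[int, ...]) -> np.ndarray:
    """Marginal isotopomer distribution over a subset of atoms.

    ``atom_bits`` are 0-based bit positions of the kept atoms; the result
    is indexed by masks in the order of ``atom_bits``.
    """
    n = iso.size.bit_length() - 1
    out = np.zeros(1 << len(atom_bits))
    for mask in range(iso.size):
        sub = 0
        for i, b in enumerate(atom_bits):
            if mask >> b & 1:
                sub |= 1 << i
        out[sub] += iso[mask]
    return out


def tandem_mid(iso: np.ndarray, parent_atoms: tuple[int, ...],
               daughter_atoms: tuple[int, ...]) -> np.ndarray:
    """Joint (parent mass shift, daughter mass shift) distribution.

    ``iso`` is the isotopomer distribution of the whole metabolite
    (length 2^n); ``parent_atoms``/``daughter_atoms`` are 1-based carbon
    positions with daughter a subset of parent.  Entry (M, m) sums the
    isotopomer fractions with M labels among the parent atoms of which m
    fall in the daughter fragment.  Marginalising over the daughter axis
    recovers the parent MID.
    """
    if not set(daughter_atoms) <= set(parent_atoms):
        raise NetworkError("daughter atoms must be a subset of the parent atoms")
    bits = tuple(p - 1 for p in parent_atoms)
    sub = marginal_isotopomers(iso, bits)
    dmask = 0
    for i, p in enumerate(parent_atoms):
        if p in daughter_atoms:
            dmask |= 1 << i
    out = np.zeros((len(parent_atoms) + 1, len(daughter_atoms) + 1))
    for mask in range(sub.size):
        out[popcount(mask), popcount(mask & dmask)] += sub[mask]
    return out


def tandem_feasible(n_parent: int, n_daughter: int) -> np.ndarray:
    """Structural feasibility mask over (parent shift, daughter shift)."""
    feas = np.zeros((n_parent + 1, n_daughter + 1), dtype=bool)
    rest = n_parent - n_daughter
    for M in range(n_parent + 1):
        for m in range(n_daughter + 1):
            feas[M, m] = (m <= M) and (M - m <= rest)
    return feas


# ---------------------------------------------------------------------------
# natural abundance

def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    if not formula:
        return counts
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise NetworkError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise NetworkError(f"cannot parse formula {formula!r}")
    return counts


def natural_abundance_operator(formula, n_backbone: int,
                               isotopes: dict | None = None) -> np.ndarray:
    """Column-stochastic convolution from backbone MID to observed MID.

    ``formula`` counts the atoms *outside* the labeled carbon backbone
    (given as a dict or a string like ``"C6H12O5Si"``); their natural
    isotope distributions are convolved onto each backbone mass column.
    An empty formula yields the identity operator.
    """
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula or {})
    isotopes = isotopes or ISOTOPES
    dist = np.ones(1)
    for elem, cnt in counts.items():
        if cnt < 0:
            raise NetworkError(f"negative atom count for {elem}")
        if elem not in isotopes:
            raise NetworkError(f"no isotope table for element {elem!r}")
        for _ in range(cnt):
            dist = np.convolve(dist, isotopes[elem])
    shift = dist.size - 1
    op = np.zeros((n_backbone + 1 + shift, n_backbone + 1))
    for col in range(n_backbone + 1):
        op[col:col + dist.size, col] = dist
    return op


# ---------------------------------------------------------------------------
# measurement model

@dataclass
class MeasurementModel:
    """Linear map from the composite state vector to simulated measurements.

    ``m_sim = M x + m0`` row-by-row; ``row_meta`` carries
    (fragment index, mass, daughter mass) with daughter mass -1 for single
    MS.  ``U`` ties measurement rows to fragment scaling factors (one 1 per
    row).  Measured values/sd are matrices (n_rows, n_times); times is
    empty for steady-state data.
    """

    fragments: list[FragmentDef]
    M: scipy.sparse.csr_matrix
    m0: np.ndarray
    row_meta: list[tuple[int, int, int]]
    U: scipy.sparse.csr_matrix
    times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    values: np.ndarray | None = None
    sd: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return self.M.shape[0]

    @property
    def n_measurements(self) -> int:
        return self.n_rows * max(1, len(self.times))

    def simulate(self, x: np.ndarray) -> np.ndarray:
        return self.M @ x + self.m0

    def fragment_rows(self, ci: int) -> np.ndarray:
        return np.array([i for i, (c, _, _) in enumerate(self.row_meta) if c == ci])


def _cumomer_fragment_rows(arrays: ModelArrays, net: Network, frag: FragmentDef):
    """(rows, m0, meta) for one fragment in cumomer space.

    Expands marginal isotopomers over the fragment atoms in terms of the
    metabolite's cumomers (Moebius), then aggregates to (parent, daughter)
    mass shifts.  Returns dense rows over the composite state vector.
    """
    met = frag.metabolite
    n_met = net.metabolites[met].n_carbons
    if any(p > n_met or p < 1 for p in frag.atoms):
        raise NetworkError(
            f"fragment {frag.id}: atoms outside the {n_met}-carbon backbone "
            f"of {met}")
    fmask = frag.mask
    dmask = frag.daughter_mask_local
    np_, nd = len(frag.atoms), len(frag.daughter)
    if frag.is_tandem:
        feas = tandem_feasible(np_, nd)
        keys = [(M, m) for M in range(np_ + 1) for m in range(nd + 1) if feas[M, m]]
    else:
        keys = [(M, -1) for M in range(np_ + 1)]
    key_row = {key: i for i, key in enumerate(keys)}
    rows = np.zeros((len(keys), arrays.n_states))
    m0 = np.zeros(len(keys))
    # local bit order of the fragment atoms within the metabolite mask
    local_bits = [p - 1 for p in frag.atoms]
    for sub in range(1 << np_):  # isotopomer pattern B on fragment atoms
        M = popcount(sub)
        m = popcount(sub & dmask) if frag.is_tandem else -1
        row_i = key_row[(M, m)]
        # iso_F(B) = sum_{A superset of B within F} (-1)^{|A\B|} x_A
        rest = (~sub) & ((1 << np_) - 1)
        a_extra = rest
        while True:
            A_local = sub | a_extra
            sign = -1.0 if popcount(a_extra) % 2 else 1.0
            A_mask = 0
            for i in range(np_):
                if A_local >> i & 1:
                    A_mask |= 1 << local_bits[i]
            if A_mask == 0:
                m0[row_i] += sign
            else:
                k = arrays.index.get(StateIndex.make(met, A_mask))
                if k is None:
                    raise NetworkError(
                        f"fragment {frag.id}: state {met}/{bin(A_mask)} absent "
                        "from the composite vector")
                rows[row_i, k] += sign
            if a_extra == 0:
                break
            a_extra = (a_extra - 1) & rest
    return rows, m0, [(frag.id, M, m) for M, m in keys]


def _emu_fragment_rows(arrays: ModelArrays, net: Network, frag: FragmentDef):
    if frag.is_tandem:
        raise NetworkError(
            f"fragment {frag.id}: tandem fragments need the cumomer "
            "framework; rerun with framework='cumomer'")
    w = len(frag.atoms)
    rows = np.zeros((w + 1, arrays.n_states))
    for mass in range(w + 1):
        k = arrays.index.get(StateIndex.make(frag.metabolite, frag.mask, mass))
        if k is None:
            raise NetworkError(
                f"fragment {frag.id}: EMU {frag.metabolite}/{frag.atoms} not in "
                "the decomposition; add it to the targets")
        rows[mass, k] = 1.0
    return rows, np.zeros(w + 1), [(frag.id, mass, -1) for mass in range(w + 1)]


def build_measurement_model(net: Network, arrays: ModelArrays,
                            fragments: list[FragmentDef],
                            times=None) -> MeasurementModel:
    """Assemble M, m0, U and row bookkeeping for a fragment list."""
    all_rows, all_m0, metas, u_rows = [], [], [], []
    for ci, frag in enumerate(fragments):
        if arrays.framework == "cumomer":
            rows, m0, meta = _cumomer_fragment_rows(arrays, net, frag)
        else:
            rows, m0, meta = _emu_fragment_rows(arrays, net, frag)
        if frag.formula:
            if frag.is_tandem:
                raise NetworkError(
                    f"fragment {frag.id}: natural-abundance formulas are "
                    "supported for single-MS fragments only")
            op = natural_abundance_operator(frag.formula, len(frag.atoms))
            rows = op @ rows
            m0 = op @ m0
            meta = [(frag.id, mass, -1) for mass in range(rows.shape[0])]
        all_rows.append(rows)
        all_m0.append(m0)
        metas.extend((ci, M, m) for _, M, m in meta)
        u_rows.extend([ci] * rows.shape[0])
    M = scipy.sparse.csr_matrix(np.vstack(all_rows)) if all_rows else \
        scipy.sparse.csr_matrix((0, arrays.n_states))
    m0 = np.concatenate(all_m0) if all_m0 else np.zeros(0)
    n_rows = M.shape[0]
    U = scipy.sparse.csr_matrix(
        (np.ones(n_rows), (np.arange(n_rows), np.array(u_rows, dtype=int))),
        shape=(n_rows, len(fragments))) if n_rows else \
        scipy.sparse.csr_matrix((0, len(fragments)))
    times = np.asarray(times, float) if times is not None else np.zeros(0)
    return MeasurementModel(list(fragments), M, m0, metas, U, times)


# ---------------------------------------------------------------------------
# the measurement TSV dialect

TABLE_COLUMNS = ["fragment_id", "metabolite", "atoms", "daughter_atoms",
                 "formula", "time", "mass", "daughter_mass", "value", "sd"]


def _atoms_str(atoms) -> str:
    return ",".join(map(str, atoms))


def _parse_atoms(s) -> tuple[int, ...]:
    if s is None or (isinstance(s, float) and math.isnan(s)) or s == "":
        return ()
    return tuple(int(a) for a in str(s).split(","))


def read_measurement_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"fragment_id": str},
                     keep_default_na=False, na_values=[])
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise NetworkError(f"measurement table missing columns {sorted(missing)}")
    return df


def fragments_from_table(df: pd.DataFrame) -> list[FragmentDef]:
    frags = []
    for fid, grp in df.groupby("fragment_id", sort=False):
        row = grp.iloc[0]
        frags.append(FragmentDef(
            id=str(fid), metabolite=str(row["metabolite"]),
            atoms=_parse_atoms(row["atoms"]),
            daughter=_parse_atoms(row["daughter_atoms"]),
            formula=str(row["formula"]) if str(row["formula"]) not in ("", "nan") else ""))
    return frags


def attach_measurements(mm: MeasurementModel, df: pd.DataFrame) -> MeasurementModel:
    """Fill values/sd (and times) of a model from a measurement table.

    Rows of the table are matched on (fragment id, mass, daughter mass,
    time); unknown fragments or masses raise an error.
    """
    frag_ids = {f.id: i for i, f in enumerate(mm.fragments)}
    times = np.array(sorted(df["time"].astype(float).unique()))
    row_of = {}
    for i, (ci, M, m) in enumerate(mm.row_meta):
        row_of[(mm.fragments[ci].id, int(M), int(m))] = i
    values = np.full((mm.n_rows, max(1, len(times))), np.nan)
    sd = np.full_like(values, np.nan)
    t_index = {t: j for j, t in enumerate(times)}
    for _, rec in df.iterrows():
        fid = str(rec["fragment_id"])
        if fid not in frag_ids:
            raise NetworkError(f"measurement for unknown fragment {fid!r}")
        dm = rec["daughter_mass"]
        dm = int(dm) if str(dm) not in ("", "nan") else -1
        key = (fid, int(rec["mass"]), dm)
        if key not in row_of:
            raise NetworkError(f"measurement row {key} not in the model")
        values[row_of[key], t_index[float(rec["time"])]] = float(rec["value"])
        sd[row_of[key], t_index[float(rec["time"])]] = float(rec["sd"])
    if np.isnan(values).any():
        raise NetworkError("measurement table does not cover every model row "
                           "at every time")
    if (sd <= 0).any():
        raise NetworkError("measurement standard deviations must be positive")
    return MeasurementModel(mm.fragments, mm.M, mm.m0, mm.row_meta, mm.U,
                            times, values, sd)
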