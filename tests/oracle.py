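"""Independent brute-force oracles used by the test suite.

The isotopomer oracle enumerates every isotopomer of every tracked
metabolite and integrates (or relaxes to steady state) the full
isotopomer balance ODEs directly from the reaction atom maps — no
cumomers, EMUs, sparse arrays or cascade solves are involved, so it is
an independent check of the entire labeling pipeline.
"""
from __future__ import annotations

import itertools

import numpy as np
import scipy.integrate

from fluxnlp.network import Network
from fluxnlp.labeling import popcount


def _tracer_iso(n, components, na):
    """Isotopomer distribution of a substrate from tracer components."""
    out = np.zeros(1 << n)
    total = 0.0
    for comp in components:
        f = float(comp.get("fraction", 1.0))
        total += f
        e_at = comp.get("atoms", "U")
        enr = float(comp.get("enrichment", 1.0))
        labeled = set(range(1, n + 1)) if e_at in ("U", "u", "all") \
            else {int(a) for a in e_at}
        e = [enr if p in labeled else na for p in range(1, n + 1)]
        for mask in range(1 << n):
            pr = 1.0
            for p in range(n):
                pr *= e[p] if mask >> p & 1 else 1.0 - e[p]
            out[mask] += f * pr
    assert abs(total - 1.0) < 1e-9
    return out


class IsotopomerOracle:
    """Full isotopomer balance simulator for a (split) network."""

    def __init__(self, net: Network, tracers, natural_abundance=0.0):
        self.net = net
        self.mets = net.internal_metabolites
        self.nc = {m: net.metabolites[m].n_carbons for m in net.metabolites}
        self.offset = {}
        off = 0
        for m in self.mets:
            self.offset[m] = off
            off += 1 << self.nc[m]
        self.size = off
        self.na = natural_abundance
        self.inputs = {m: _tracer_iso(self.nc[m], tracers.get(
            m, [{"fraction": 1.0, "atoms": [], "enrichment": 0.0}]), natural_abundance)
            for m, met in net.metabolites.items() if met.role == "input"}

    def initial(self):
        y = np.zeros(self.size)
        for m in self.mets:
            y[self.offset[m]:self.offset[m] + (1 << self.nc[m])] = _tracer_iso(
                self.nc[m], [{"fraction": 1.0, "atoms": [],
                              "enrichment": 0.0}], self.na)
        return y

    def _iso(self, y, met):
        if met in self.offset:
            return y[self.offset[met]:self.offset[met] + (1 << self.nc[met])]
        return self.inputs[met]

    def rates(self, y, v):
        """Net isotopomer production rates (not yet divided by pools)."""
        dy = np.zeros(self.size)
        for r, rxn in enumerate(self.net.reactions):
            mapped = [(ri, occ) for ri, occ in enumerate(rxn.reactants)
                      if occ.atoms is not None]
            # consumption
            for ri, occ in mapped:
                if occ.metabolite in self.offset:
                    o = self.offset[occ.metabolite]
                    nbits = 1 << self.nc[occ.metabolite]
                    dy[o:o + nbits] -= occ.coeff * v[r] * self._iso(y, occ.metabolite)
            # production: enumerate reactant pattern combinations
            amap = rxn.atom_map_dict
            pat_spaces = [range(1 << self.nc[occ.metabolite]) for _, occ in mapped]
            occ_pos = {ri: slot for slot, (ri, _) in enumerate(mapped)}
            for combo in itertools.product(*pat_spaces):
                prob = 1.0
                for slot, (ri, occ) in enumerate(mapped):
                    prob *= self._iso(y, occ.metabolite)[combo[slot]]
                if prob == 0.0:
                    continue
                for pi, pocc in enumerate(rxn.products):
                    if pocc.atoms is None or pocc.metabolite not in self.offset:
                        continue
                    pat = 0
                    for p in range(self.nc[pocc.metabolite]):
                        ri, q = amap[(pi, p)]
                        if combo[occ_pos[ri]] >> q & 1:
                            pat |= 1 << p
                    dy[self.offset[pocc.metabolite] + pat] += \
                        pocc.coeff * v[r] * prob
        return dy

    def rhs(self, y, v, p_met):
        dy = self.rates(y, v)
        for m in self.mets:
            o = self.offset[m]
            dy[o:o + (1 << self.nc[m])] /= p_met[m]
        return dy

    def integrate(self, v, p_met, t_eval):
        sol = scipy.integrate.solve_ivp(
            lambda t, y: self.rhs(y, v, p_met), (0.0, float(t_eval[-1])),
            self.initial(), t_eval=t_eval, method="Radau",
            rtol=1e-11, atol=1e-13)
        assert sol.success
        return sol.y.T

    def steady_state(self, v, relax_time=400.0):
        pools = {m: 1.0 for m in self.mets}
        sol = scipy.integrate.solve_ivp(
            lambda t, y: self.rhs(y, v, pools), (0.0, relax_time),
            self.initial(), method="Radau", rtol=1e-12, atol=1e-14)
        assert sol.success
        y = sol.y[:, -1]
        assert np.abs(self.rates(y, v)).max() < 1e-9
        return y

    # -- observables ---------------------------------------------------
    def isotopomers(self, y, met):
        return self._iso(y, met).copy()

    def fragment_mid(self, y, met, atoms):
        iso = self._iso(y, met)
        n = self.nc[met]
        bits = [p - 1 for p in atoms]
        out = np.zeros(len(atoms) + 1)
        for mask in range(1 << n):
            k = sum(1 for b in bits if mask >> b & 1)
            out[k] += iso[mask]
        return out

    def tandem(self, y, met, parent, daughter):
        iso = self._iso(y, met)
        n = self.nc[met]
        out = np.zeros((len(parent) + 1, len(daughter) + 1))
        pb = [p - 1 for p in parent]
        db = [p - 1 for p in daughter]
        for mask in range(1 << n):
            M = sum(1 for b in pb if mask >> b & 1)
            m = sum(1 for b in db if mask >> b & 1)
            out[M, m] += iso[mask]
        return out


def emu_closure_graph(net: Network, targets):
    """Exhaustive backward closure over the full (metabolite, subset) universe.

    Builds the complete precursor graph over every nonempty atom subset of
    every metabolite, then takes the set reachable backward from the
    targets — an independent check of the on-demand decomposition.
    """
    edges: dict[tuple[str, int], set[tuple[str, int]]] = {}
    for met, metdef in net.metabolites.items():
        if metdef.role == "input" or metdef.n_carbons == 0:
            continue
        n = metdef.n_carbons
        for mask in range(1, 1 << n):
            node = (met, mask)
            edges.setdefault(node, set())
            for r, rxn in enumerate(net.reactions):
                amap = rxn.atom_map_dict
                for pi, occ in enumerate(rxn.products):
                    if occ.metabolite != met or occ.atoms is None:
                        continue
                    groups: dict[int, int] = {}
                    for p in range(n):
                        if mask >> p & 1:
                            ri, q = amap[(pi, p)]
                            groups[ri] = groups.get(ri, 0) | (1 << q)
                    for ri, sub in groups.items():
                        edges[node].add((rxn.reactants[ri].metabolite, sub))
    closed = set()
    stack = [(m, a if isinstance(a, int) else
              sum(1 << (p - 1) for p in a)) for m, a in targets]
    while stack:
        node = stack.pop()
        if node in closed:
            continue
        closed.add(node)
        for pre in edges.get(node, ()):
            stack.append(pre)
    return closed
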