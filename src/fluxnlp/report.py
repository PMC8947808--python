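"""Run configuration, workflow assembly, Escher export and report tables.

A single YAML config describes a study: the network file, metabolite
roles, bounds, tracers, fragments, measurement times, collocation
settings and estimation settings.  :func:`load_config` validates it and
:func:`build_study` assembles every model object needed by the estimation
API, so the command-line layer (and the reproduction script) stay thin.

Outputs are tidy TSV tables (fluxes, pools, measured-vs-fitted values,
interpolated trajectories) plus an Escher-readable JSON map of the
network; rendering is left to the user.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import Network, NetworkError, parse_network, apply_config, \
    split_reversible
from .labeling import build_model_arrays, build_input_vector, initial_state, \
    build_pool_model, bind_inputs, NATURAL_13C
from .measure import FragmentDef, build_measurement_model, \
    read_measurement_table, attach_measurements
from .simulate import integrate_labeling, generate_synthetic_measurements
from .collocation import TimeGrid, radau_iia
from .estimate import FitResult, InstProblem, assemble_inst_nlp, \
    assemble_steady_nlp

__all__ = ["RunConfig", "Study", "load_config", "build_study",
           "simulate_study", "export_escher", "write_fit_tables"]


@dataclass
class RunConfig:
    """Validated study configuration (all paths resolved)."""

    network_path: Path
    inputs: list[str]
    outputs: list[str]
    bounds: dict
    pool_bounds: dict
    tracers: dict
    natural_abundance: float
    framework: str
    fragments: list[FragmentDef]
    measurement_times: list[float]
    noise_sd: float
    scaling: str
    collocation_order: int
    time_nodes: list[float]
    n_restarts: int
    seed: int
    exchange_cap: float | None
    truth_fluxes: dict[str, float] = field(default_factory=dict)
    truth_pools: dict[str, float] = field(default_factory=dict)
    flux_measurements: dict = field(default_factory=dict)
    pool_measurements: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise NetworkError(f"config {path} is not a mapping")
    base = path.parent
    try:
        frags = [FragmentDef(id=str(f["id"]), metabolite=str(f["metabolite"]),
                             atoms=tuple(int(a) for a in f["atoms"]),
                             daughter=tuple(int(a) for a in f.get("daughter", ())),
                             formula=str(f.get("formula", "")))
                 for f in cfg.get("fragments", [])]
        coll = cfg.get("collocation", {})
        est = cfg.get("estimation", {})
        truth = cfg.get("truth", {})
        return RunConfig(
            network_path=base / cfg["network"],
            inputs=list(cfg.get("inputs", [])),
            outputs=list(cfg.get("outputs", [])),
            bounds=dict(cfg.get("bounds", {})),
            pool_bounds=dict(cfg.get("pool_bounds", {})),
            tracers=dict(cfg.get("tracers", {})),
            natural_abundance=float(cfg.get("natural_abundance", NATURAL_13C)),
            framework=str(cfg.get("framework", "cumomer")),
            fragments=frags,
            measurement_times=[float(t) for t in cfg.get("measurement_times", [])],
            noise_sd=float(cfg.get("noise_sd", 0.01)),
            scaling=str(cfg.get("scaling", "fixed")),
            collocation_order=int(coll.get("order", 3)),
            time_nodes=[float(t) for t in coll.get("nodes", [])],
            n_restarts=int(est.get("n_restarts", 10)),
            seed=int(est.get("seed", 1)),
            exchange_cap=(float(cfg["exchange_cap"])
                          if "exchange_cap" in cfg else None),
            truth_fluxes={k: float(v) for k, v in truth.get("fluxes", {}).items()},
            truth_pools={k: float(v) for k, v in truth.get("pools", {}).items()},
            flux_measurements=dict(cfg.get("flux_measurements", {})),
            pool_measurements=dict(cfg.get("pool_measurements", {})),
            raw=cfg)
    except KeyError as exc:
        raise NetworkError(f"config {path}: missing key {exc}") from exc


@dataclass
class Study:
    """Everything assembled for one study: network, arrays, measurement map."""

    config: RunConfig
    net: Network
    arrays: object
    bound: object
    pools: object
    x_init: np.ndarray
    mm: object               # measurement model without values
    grid: TimeGrid | None
    scheme: object | None

    def truth_vectors(self):
        cfg = self.config
        if not cfg.truth_fluxes:
            return None, None
        v = np.array([cfg.truth_fluxes[r] for r in self.net.reaction_ids])
        p = np.array([cfg.truth_pools[m] for m in self.pools.metabolites])
        return v, p

    def problem(self, measurements: pd.DataFrame, kind: str = "inst"):
        mm = attach_measurements(self.mm, measurements)
        if kind == "inst":
            return assemble_inst_nlp(self.net, self.bound, self.pools, mm,
                                     self.grid, self.scheme, self.x_init,
                                     scaling=self.config.scaling)
        return assemble_steady_nlp(self.net, self.bound, mm,
                                   scaling=self.config.scaling)


def build_study(cfg: RunConfig) -> Study:
    net = parse_network(cfg.network_path.read_text())
    net = apply_config(net, {
        "inputs": cfg.inputs, "outputs": cfg.outputs, "bounds": cfg.bounds,
        "pool_bounds": cfg.pool_bounds,
        "flux_measurements": cfg.flux_measurements,
        "pool_measurements": cfg.pool_measurements})
    net = split_reversible(net, exchange_cap=cfg.exchange_cap)
    targets = [(f.metabolite, f.atoms) for f in cfg.fragments]
    arrays = build_model_arrays(net, cfg.framework,
                                targets=targets if cfg.framework == "emu" else None)
    x_inp = build_input_vector(net, arrays, cfg.tracers, cfg.natural_abundance)
    bound = bind_inputs(arrays, x_inp)
    pools = build_pool_model(net, arrays)
    x_init = initial_state(net, arrays, cfg.natural_abundance)
    mm = build_measurement_model(net, arrays, cfg.fragments,
                                 times=cfg.measurement_times or None)
    grid = TimeGrid(cfg.time_nodes) if cfg.time_nodes else None
    scheme = radau_iia(cfg.collocation_order)
    return Study(cfg, net, arrays, bound, pools, x_init, mm, grid, scheme)


def simulate_study(study: Study, seed: int, noise_sd: float | None = None,
                   dt: float = 0.02):
    """Forward-simulate the study truth and emit a noisy measurement table."""
    v, p = study.truth_vectors()
    if v is None:
        raise NetworkError("config has no truth block to simulate from")
    sd = study.config.noise_sd if noise_sd is None else noise_sd
    times = np.asarray(study.config.measurement_times, float)
    t_grid = np.concatenate([[0.0], times])
    traj = integrate_labeling(study.bound, v, study.pools.state_pools(p),
                              t_grid, study.x_init, dt=dt)
    df = generate_synthetic_measurements(traj, study.mm, sd, seed)
    return traj, df


# ---------------------------------------------------------------------------
# Escher map export

def export_escher(net: Network, fluxes: dict[str, float] | None = None,
                  map_name: str = "network"):
    """Escher-readable JSON map (map schema 1-0-0) plus flux data values.

    Returns ``(map_document, reaction_data)``: the two-element map list
    that Escher loads as a map, and a flat ``{reaction id: flux}`` dict
    suitable for Escher's reaction-data input (empty when no fluxes are
    given).  Node layout is a simple circle; Escher users typically
    rearrange interactively.
    """
    mets = sorted(net.metabolites)
    n_m = len(mets)
    radius, cx, cy = 400.0, 500.0, 500.0
    nodes = {}
    met_node = {}
    next_id = 1
    for i, m in enumerate(mets):
        ang = 2.0 * math.pi * i / max(1, n_m)
        x = cx + radius * math.cos(ang)
        y = cy + radius * math.sin(ang)
        nid = str(next_id); next_id += 1
        nodes[nid] = {"node_type": "metabolite", "x": x, "y": y,
                      "bigg_id": m, "name": m, "label_x": x + 10,
                      "label_y": y + 10, "node_is_primary": True}
        met_node[m] = nid
    reactions = {}
    for ri, rxn in enumerate(net.reactions):
        species = [(o.metabolite, -o.coeff) for o in rxn.reactants] + \
               [(o.metabolite, o.coeff) for o in rxn.products]
        xs = [nodes[met_node[m]]["x"] for m, _ in species]
        ys = [nodes[met_node[m]]["y"] for m, _ in species]
        mx, my = float(np.mean(xs)), float(np.mean(ys))
        mid = str(next_id); next_id += 1
        nodes[mid] = {"node_type": "midmarker", "x": mx, "y": my}
        segments = {}
        for m, _ in species:
            sid = str(next_id); next_id += 1
            segments[sid] = {"from_node_id": met_node[m], "to_node_id": mid,
                             "b1": None, "b2": None}
        reactions[str(ri)] = {
            "name": rxn.id, "bigg_id": rxn.id, "reversibility": rxn.reversible,
            "label_x": mx + 10, "label_y": my - 10, "gene_reaction_rule": "",
            "genes": [],
            "metabolites": [{"bigg_id": m, "coefficient": c} for m, c in species],
            "segments": segments}
    doc = [
        {"map_name": map_name, "map_id": map_name,
         "map_description": "exported reaction network",
         "homepage": "https://escher.github.io",
         "schema": "https://escher.github.io/escher/jsonschema/1-0-0#"},
        {"reactions": reactions, "nodes": nodes, "text_labels": {},
         "canvas": {"x": 0.0, "y": 0.0, "width": 1000.0, "height": 1000.0}},
    ]
    data = {rid: float(val) for rid, val in (fluxes or {}).items()}
    return doc, data


# ---------------------------------------------------------------------------
# report tables

def write_fit_tables(study: Study, problem, fit: FitResult, outdir) -> dict:
    """Write flux/pool/fit tables and the interpolated trajectory as TSV.

    Returns the paths written.  Every run directory also receives a
    config snapshot and a small JSON run log sufficient to re-run the
    estimation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    flux_df = pd.DataFrame({"reaction": study.net.reaction_ids,
                            "flux": fit.v})
    paths["fluxes"] = outdir / "fluxes.tsv"
    flux_df.to_csv(paths["fluxes"], sep="\t", index=False)

    if fit.pools is not None:
        pool_df = pd.DataFrame({"metabolite": study.pools.metabolites,
                                "pool_size": fit.pools})
        paths["pools"] = outdir / "pools.tsv"
        pool_df.to_csv(paths["pools"], sep="\t", index=False)

    mm = problem.mm
    fitted = problem.fitted_measurements(fit.zvar)
    rows = []
    times = mm.times if len(mm.times) else [float("nan")]
    for mu, t in enumerate(times):
        for i, (ci, mass, dmass) in enumerate(mm.row_meta):
            frag = mm.fragments[ci]
            meas = mm.values[i, mu]
            sim = fitted[i, mu]
            sd = mm.sd[i, mu]
            rows.append({"fragment_id": frag.id, "time": t, "mass": mass,
                         "daughter_mass": dmass if dmass >= 0 else "",
                         "measured": meas, "fitted": sim,
                         "residual": meas - sim,
                         "weighted_residual": (meas - sim) / sd})
    paths["fit"] = outdir / "measurements_fit.tsv"
    pd.DataFrame(rows).to_csv(paths["fit"], sep="\t", index=False)

    if fit.x_nodes is not None and study.grid is not None:
        t_dense = np.linspace(study.grid.nodes[0], study.grid.nodes[-1], 201)
        from .collocation import interpolate_at
        recs = []
        for t in t_dense[1:]:
            x_t = interpolate_at(problem.system, fit.x_nodes, fit.stage_k,
                                 float(t))
            m_t = mm.simulate(x_t)
            for i, (ci, mass, dmass) in enumerate(mm.row_meta):
                recs.append({"fragment_id": mm.fragments[ci].id, "time": t,
                             "mass": mass,
                             "daughter_mass": dmass if dmass >= 0 else "",
                             "value": m_t[i]})
        paths["trajectory"] = outdir / "trajectory.tsv"
        pd.DataFrame(recs).to_csv(paths["trajectory"], sep="\t", index=False)

    log = {"objective": fit.z, "status": fit.status,
           "feasibility": fit.feasibility, "n_iter": fit.n_iter,
           "scheme_order": fit.scheme_order, "seed": fit.seed}
    paths["log"] = outdir / "runlog.json"
    paths["log"].write_text(json.dumps(log, indent=1))
    snap = outdir / "config_snapshot.yaml"
    snap.write_text(yaml.safe_dump(study.config.raw, sort_keys=False))
    paths["config"] = snap
    return paths
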