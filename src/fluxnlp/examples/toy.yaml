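# Study conditions for the toy network: an 80% [1-13C] / 20% U-13C feed
# switched on at t = 0, zero natural abundance, complete normalized MIDs
# of three B fragments measured every 2 time units on [0, 20] with sd
# 0.01.  The positional tracer resolves the route split; the uniformly
# labeled fraction adds isotopomer correlations through the
# cleavage/condensation route.
network: toy.net
inputs: [Aext]
outputs: [Bsink]
exchange_cap: 20.0
bounds:
  default: [0.0, 10.0]
  v0: [1.0, 1.0]       # uptake flux known exactly
pool_bounds:
  default: [0.05, 10.0]
tracers:
  Aext:
    - {fraction: 0.8, atoms: [1], enrichment: 1.0}
    - {fraction: 0.2, atoms: U, enrichment: 1.0}
natural_abundance: 0.0
framework: cumomer
fragments:
  - {id: B12, metabolite: B, atoms: [1, 2]}
  - {id: B23, metabolite: B, atoms: [2, 3]}
  - {id: B123, metabolite: B, atoms: [1, 2, 3]}
  - {id: E12, metabolite: E, atoms: [1, 2]}
measurement_times: [2, 4, 6, 8, 10, 12, 14, 16, 18, 20]
noise_sd: 0.01
scaling: fixed          # complete normalized MIDs -> scalings fixed to 1
collocation:
  order: 3
  nodes: [0.0, 1.0, 3.0, 6.0, 11.0, 20.0]
estimation:
  n_restarts: 10
  seed: 1
# generating truth used by `fluxnlp simulate` fixtures
truth:
  fluxes: {v0: 1.0, v1: 0.4, v2: 0.25, v3: 0.25, v4_f: 0.5, v4_r: 0.15,
           v5: 0.35, v6: 0.35, v7: 1.0}
  pools: {A: 1.5, B: 2.0, C: 0.8, D: 1.2, E: 0.5, F: 0.3}
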