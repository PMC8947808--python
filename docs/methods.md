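# Methods

## Model structure

Labeling states are tracked for every balanced metabolite with mapped
carbons.  Two frameworks share one balance structure:

* **Cumomers.** For an n-carbon metabolite, all 2ⁿ cumulated-isotopomer
  fractions; the weight-0 cumomer is identically 1.  The composite state
  vector holds only nontrivial states: weight-0 cumomers and the states
  of fed substrates are constants and are folded into the numeric
  coefficient tables when the tracer is bound (`bind_inputs`).  The
  cumomer framework supports tandem-MS observations, because the joint
  parent/daughter mass distribution is a linear image of the cumomers.
* **EMUs.** The minimal closed set of elementary metabolite units
  reachable backward from the measured fragments, with one state per
  mass shift of each EMU.  The state variables are the fractional
  abundances, so the same Q/P/Pinp balance template applies; condensation
  entries convolve mass shifts, and a self-condensation contributes a
  doubled diagonal entry so that the explicit ½ in the balance reproduces
  the stoichiometric rate exactly.

Production terms are built per product-occurrence of each reaction by
grouping the atom-map pre-image of every tracked atom subset by reactant
occurrence.  Terms coupling more than two tracked states (a condensation
drawing a single state's atoms from three or more tracked reactants) are
rejected; constants (inputs, weight-0) multiply into the coefficient.
Balances conserve MID normalization and cumomer monotonicity by
construction; the test suite verifies both pipelines against a
brute-force isotopomer simulator that works directly from the atom maps.

Reversible reactions are split into nonnegative forward/reverse halves
(the reverse atom map is the inverse); configured net-flux bounds become
rows of `R v ≤ b`.  The directional halves receive an upper bound
(`exchange_cap`, default 100 in flux units) that limits how fast a
bidirectional reaction may exchange label — exchange magnitude is
structurally weakly identified, and an explicit cap both reflects the
physiology and keeps random restarts out of the near-flat large-exchange
region.  Net fluxes are the robust reported quantities.

## Steady state and dynamics

The steady-state balances are solved by the weight (cumomer) / size (EMU)
cascade: bimolecular terms couple only strictly lower levels, so each
level is one sparse linear solve.  A singular level system is reported
with the unreachable states (zero-flux dead ends).  Dynamics integrate
`p_k dx_k/dt = production_k` with fixed-step RK4 (default dt = 0.02, the
pathway used to generate reference trajectories) or an adaptive stiff
integrator with analytic Jacobian.

## Collocation

Radau IIA schemes of orders 3, 5 and 9 (s = 2, 3, 5) are derived at
build time: the nodes are the roots of the right Radau polynomial
(computed to 30 significant digits via sympy), and the Runge–Kutta
matrix, weights and integrated-Lagrange basis B_α(τ) follow from exact
Lagrange integration on those nodes.  Scheme identities (c_s = 1,
Σb = 1, last row of a equals b, B_α(1) = b_α, B_α(c_β) = a_βα, the
stability function on the negative real axis) are asserted to 1e−12 in
the tests, replacing a table of literature decimals as the source of
truth.  Default grids widen geometrically because labeling dynamics are
stiff at early times; a measurement falling exactly on a grid node
belongs to the interval ending there (τ = 1).

## The NLP

Variable blocks: fluxes v, metabolite pools p, optional scaling factors
h, node states x_γ, stage derivatives k_αγ.  Two reductions are applied
relative to the fully written-out transcription, both exact linear
substitutions that leave the KKT system unchanged: the stage states
K_αγ = x_{γ−1} + h_γ Σ a_αβ k_βγ are reconstructed at evaluation time,
and the measurement-time states/simulated measurements are folded into
the objective through a precomputed sparse affine map.  Consequently
every residual is affine in the variables — the objective is an exact
sparse quadratic — and all model curvature lives in the bilinear stage
balances, for which the exact Lagrangian Hessian is assembled.  The
problem object still reports the counts of the full transcription for
inspection.

The balance rows of a metabolite whose stoichiometric row duplicates
another (parallel pools) are kept, but the stoichiometric equality block
is row-reduced to an independent subset before it reaches the solver;
rank-deficient equality Jacobians otherwise force dense factorizations.

Node states and stage derivatives are left unbounded by default
(`state_box=None`): the transcribed dynamics themselves keep fitted
trajectories in [0, 1], while box bounds on hundreds of states that sit
essentially on the bound at late times (fully labeled plateaus) cripple
interior-point progress.  A box can be supplied when states must be
clamped.

Solver backend: `scipy.optimize.minimize(method="trust-constr")` with
sparse constraint Jacobians, the exact Lagrangian Hessian, equality
feasibility tolerance 1e−7, gtol 1e−6 and xtol 1e−12.  The contract is
deliberately narrow (sparse first derivatives in, status and feasibility
out) so another sparse NLP code can be substituted.  Starts are made
feasible by a forward implicit-RK solve of the transcription at the
starting parameters — used once per start, never inside an iteration; a
failed solve is repaired once by re-initializing the states the same way.

Multistart draws starting fluxes by blending six random-objective LP
vertices of the flux polytope with Dirichlet weights (pools log-uniform
within bounds).  The blend keeps samples off low-dimensional faces: a
start with a pathway flux pinned exactly at zero can be a spurious corner
KKT point.  Per-restart seeds derive from the master seed by a
counter-based spawn, so any restart is reproducible in isolation.
Refinement re-transcribes at order 9 (or 5) and warm-starts from a
forward solve at the low-order optimum.  Goodness of fit uses the χ²
quantile at dof = measurements − (independent fluxes + free pools + free
scalings).  Confidence intervals use a parametric bootstrap (resample
measurements from the fitted values, refit warm-started from the point
estimate); nonparametric residual resampling is not offered because
time-series MIDs have no exchangeable residual blocks.

Scaling factors are free per fragment (per fragment and time point in
the nonstationary case) and are fixed to 1 when the configuration
declares the MIDs complete and normalized.

## Synthetic data and the toy study

The generator forward-integrates the configured truth with RK4
(dt = 0.02) and perturbs every measurement with i.i.d. Gaussian noise of
the configured σ (default 0.01); tables record max(σ, 1e−4) so that
noise-free fixtures keep finite weights.  It emulates isotopically
nonstationary labeling at metabolic steady state with known σ; it does
not emulate flux transients, correlated instrument error, missing mass
channels or peak-integration artifacts, so passing tests bound model and
estimator correctness, not instrument behavior.

The bundled toy study defines the package's reference conditions: three
A→B routes (direct; via C with carbon rotation; via a reversible
scramble and a cleavage/condensation pair through D, E, F), uptake fixed
at 1 → 3 independent fluxes, 6 pools.  Route maps place substrate
carbon 1 at B1/B3/B2 respectively, and the feed is 80% [1-¹³C] + 20%
U-¹³C with zero natural abundance: the positional tracer separates the
route split while the uniformly labeled fraction creates isotopomer
correlations through the condensation.  Measured fragments are B[1,2],
B[2,3], B[1,2,3] and E[1,2] every 2 time units on [0, 20] with σ = 0.01;
measuring the cleavage-route intermediate E is what makes the
"route 3 off" corner globally repulsive for the estimator.  The grid for
estimation is [0, 1, 3, 6, 11, 20] (dense early).  Generating values:
v1 = 0.4, v2 = v3 = 0.25, v4 = 0.5/0.15 (forward/reverse), v5 = v6 =
0.35, efflux 1.0; pools A…F = 1.5, 2.0, 0.8, 1.2, 0.5, 0.3; exchange cap
20.

Problem sizes in the default test run and the reproduction script are
chosen for a single desktop core: 10 restarts for the multistart study,
3–4 recovery replicates with 8 bootstrap refits at the 5th-order
refinement, and three randomized small networks (≤ 12 internal carbons)
for the oracle sweep.

## Numerical choices and degenerate inputs

* Natural ¹³C abundance defaults to 0.0107 (configurable); isotope
  tables for C, H, N, O, S, Si drive the column-stochastic
  natural-abundance convolution folded into the measurement matrix
  (single-MS fragments only; a tandem fragment with an extra-atom
  formula is rejected).
* Möbius inversion of cumomers clamps negativity within 1e−9 (roundoff)
  and renormalizes; larger negativity raises an error.
* Numerical rank uses 1e−10 times the largest singular value.
* Fixed fluxes are encoded as equal bounds; they count as neither free
  parameters nor independent fluxes.
* Zero-flux dead ends: the cascade solver names unreachable states; the
  NLP tolerates them (their balances vanish identically).

## Known limitations

* Exchange (bidirectional) flux magnitudes are recovered only up to the
  data's weak sensitivity; net fluxes are the reliable output, and the
  bootstrap quantifies the rest.  A small systematic bias from the
  3rd-order transcription on coarse grids is removed by the prescribed
  high-order refinement before parameters are interpreted.
* Condensations drawing one state's atoms from ≥ 3 tracked reactants are
  unsupported (no such reaction arises in carbon-mapped central
  metabolism).
* Only carbon is a tracer atom; other elements enter only through
  natural-abundance correction.  Bondomer/fluxomer state spaces and
  FVA-based model reduction are out of scope.
* The interior-point backend solves desktop-scale transcriptions (10²–10³
  states) comfortably; genome-scale problems would want a
  large-scale reduced-gradient or interior-point code behind the same
  problem interface.
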