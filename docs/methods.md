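# Methods

## Model and observation model

A model is an ODE `dy/dt = F(t, y, θ, u(t))` with `k` states, `l` parameters
at reference values `θ*`, an initial condition `y(0)` (possibly
θ-dependent), and an optional scalar or vector input signal `u(t)`. An
*experiment* selects observed components and times, may override the input
profile, perturb parameters (e.g. a rate set to 0 for a knockout), replace
the initial state (for relaxation protocols), and carries an observation
error scale σ (default 1, the unit-variance Gaussian convention under which
`SᵀS` is the Fisher information). Observation vectors are time-major: all
observed components at `t₁`, then `t₂`, …; every module relies on this one
ordering.

Simulation uses `scipy.integrate.solve_ivp` with LSODA (stiff-capable,
automatic switching) at `rtol = 1e-8`, `atol = 1e-10`. These are tight on
purpose: canonical correlations near 1 respond quadratically to angle errors
between sensitivity columns, so the columns need ≥ 6 accurate digits for
stable similarity values. Discontinuous input profiles declare breakpoints
and the integrator is restarted at each one. Steady-state protocols are
expressed as one late observation time rather than an algebraic solve (the
bundled gene-expression fixture uses `t = 40` with slowest rate 1, leaving a
transient of order `e⁻⁴⁰`); models with a closed-form steady state can
verify against it directly, as the test suite does.

## Sensitivities

Sensitivities `z_i(t) = ∂y/∂θ_i` solve the forward variational system
`dz_i/dt = (∂F/∂y) z_i + ∂F/∂θ_i`, `z_i(0) = ∂y(0)/∂θ_i`, integrated as one
augmented system of dimension `k(l+1)` per experiment (not per-parameter
loops — one pass shares the state trajectory and the solver's step-size
control across all columns). Analytic Jacobians are used when the model
provides them; config-file models get them automatically by symbolic
differentiation of the parsed right-hand sides; otherwise central finite
differences of the RHS are applied inside the augmented system. An
independent central-difference oracle (re-simulation at `θ_i ± 10⁻⁶ θ_i`,
integrated at `rtol = 1e-11` because the difference quotient amplifies
solver noise by `1/2h`) cross-checks the variational route to < 1e-4
relative error on every fixture.

The stacked matrix divides each experiment's rows by its σ and, under the
default log-parametrisation, multiplies column `i` by `θ_i*` (chain rule for
`log θ_i`), so `‖S_i‖` bounds *relative* estimation error and ζ = 1 has the
order-of-magnitude reading. The reference value is used for this scaling
even in experiments that override the parameter (e.g. to 0 in a knockout):
columns must mean the same thing in every block for stacking to be valid.

## Canonical correlations and similarity

Group-vs-group similarity is computed as principal angles between the column
spans: orthonormal bases via rank-revealing SVD (singular values below
`1e-10 × s_max` of a block are rank noise — sloppy models produce
numerically dependent columns), then singular values of `Q_AᵀQ_B`, clipped
into [0, 1]. Exactly `m = min(|A|, |B|)` values are reported, zero-padded
under rank deficiency, so the printed definition of the MI divisor `m` is
preserved (padding zeros contribute `log 1 = 0`). Generalized eigenproblems
on Fisher-matrix sub-blocks would give the same answer in exact arithmetic
but are avoided: the FIM of a sloppy model is near-singular and squares the
condition number.

`I(A, B) = −(1/m) Σ log(1 − ρ_i²)` in nats. The measure diverges as
`ρ → 1`; ρ is clipped at `1 − 1e-12` first, so perfectly compensated pairs
yield a large finite sentinel with a `capped` flag, and ranking among capped
pairs falls back to the linkage height (smaller = more similar). The
natural log is a documentation choice, not a consequential one: only the
ordering of similarities enters the clustering. Pairwise similarity uses
|cos(S_i, S_j)|: sign-opposite columns (production vs degradation rates) are
maximally compensative under signed perturbations; canonical correlations
are non-negative by construction. The per-parameter compensability
`ρ(θ_i, θ_−i)` is the first canonical correlation of `{S_i}` against the
span of the rest (equivalently |cos| between `S_i` and its projection onto
that span); an empty rest gives 0, a zero column gives 0 with a warning (the
ζ-condition covers insensitivity).

## (δ, ζ)-identifiability

`θ_i` is identifiable at (δ, ζ) iff `ρ(θ_i, θ_−i) < δ` and `‖S_i‖ > ζ`
(strict comparisons). `1/(1−δ²)` is the implied variance-inflation cap
(≈ 10.26 at the default 0.95), `1/ζ` the single-parameter asymptotic
variance cap. The scope of "the rest" is explicit: the global test uses all
model parameters, the clustering uses the current cluster's surviving
members (the within-cluster reading of the pruning rule; at the root, after
pruning, the two coincide on the survivors). A sweep mode recomputes the
verdict counts over a (δ, ζ) grid from one set of norms and correlations,
for robustness checks of threshold choices.

## Clustering

Agglomerative, from singletons; at each step the pair of clusters with the
highest MI (over surviving members) is merged. Tie-breaking is
deterministic: capped MI first (ties among capped broken by ascending
linkage height), then by the lexicographically smallest pair of member
indices. After a merge, while any member has `ρ ≥ δ` against the other
surviving members, the member with the largest ρ is removed (ties toward the
larger index) and correlations recomputed — one at a time, the conservative
reading of "removed until all satisfy". Pruned parameters never re-enter
later similarity computations but remain as annotated leaves in the exported
dendrogram. ζ-failing parameters participate in clustering (the similarity
picture is informative regardless) and are excluded from the final
identifiable set. Heights `(1/m) Σ (1−ρ²)` carry no monotonicity guarantee;
non-monotone steps are recorded, not corrected. Pruning always leaves at
least one member per cluster (a singleton has `ρ_rest = 0`), so the
partition identifiable ∪ non-identifiable is total, with a per-parameter
reason (δ-pruned at step s / ζ-fail).

Export: Newick (branch length = parent height − child height; pruned leaves
tagged `[&removed=s]` as a bracket comment, which standard parsers treat as
metadata) and a JSON merge table; a simple matplotlib dendrogram writer is a
convenience only.

## Experiment screening

`screen_experiments` adds each candidate experiment to the base design,
rebuilds the stacked matrix and counts (δ, ζ)-identifiable parameters;
candidates whose simulation fails are skipped with the error recorded. The
ranking sorts by count descending with candidate index as the tie-break.
`random_input_profiles` generates seeded piecewise-constant stimulation
profiles on a stated grid with amplitudes from a stated range — a documented,
reproducible generator for random-protocol searches.

## Built-in models and what they do (not) show

**Gene expression** (`dr/dt = k_r − g_r r`, `dp/dt = k_p r − g_p p`);
reference rates (2, 3, 1, 2), all order 1, chosen once so the steady state
is (2, 3). The steady-state protocol observes both species once at `t = 40`;
its four log-scale sensitivity columns follow in closed form from
`(k_r/g_r, k_r k_p/(g_r g_p))` and make every parameter fully compensated.
The decay protocol starts from mRNA at 15× and protein at 1.5× their
steady-state levels (strong transcript overexpression with modestly elevated
protein) and samples 16 log-spaced times in [0.05, 15] covering both
relaxation timescales; under it all four rates pass at (0.95, 1) with margin
(max ρ_rest ≈ 0.935). A weaker, symmetric push (2× both species) does *not*
clear δ = 0.95 — the qualitative contrast between the two protocols needs a
well-designed perturbation, which is itself an instructive property of the
δ-condition.

**IKKK sub-model**
`dy₁/dt = ka·y16(t)·(KN − y₁)·ka20/(ka20 + y9(t)) − ki·y₁` with reference
values (ka, KN, ka20, ki) = (1, 10, 0.5, 0.5). The forcings are documented
stand-ins: activated receptors `y16` as a pulse peaking at 3 at `t = 2`,
cytoplasmic A20 `y9` accumulating to a plateau of 5. Under wild-type
stimulation A20 feedback keeps `y₁` far below the pool `KN`, so
`(KN − y₁) ≈ KN` and ka, KN (and with the quasi-steady balance, ki) act
almost only through combinations — all three δ-fail. The A20 knockout
(`y9 ≡ 0`, which also makes the `ka20/(ka20+y9)` factor ≡ 1 and removes all
information about ka20 from that block) lets activation approach saturation,
and the knockout with blocked phosphatase (`ki` overridden to 0) isolates
the activation terms; the three experiments jointly make ka, KN and ki pass.
The fixture's contract is this qualitative pattern, not particular
correlation values, because the forcing shapes and reference values are
stand-ins.

**Random chains**: seeded linear mass-action chains in which selected
transport rates are products `αβ` of two parameters. In log scale the two
factors have *identical* sensitivity columns, so each planted pair is a
ground-truth `ρ = 1` compensation: clustering must merge it at numerically
zero height and prune exactly one member. Observing all states keeps the
unplanted remainder generically full-rank.

These fixtures emulate the structure of real identifiability problems
(ratio-type compensations, saturation-controlled correlation, knockout
designs) at desk scale. They do not emulate measurement noise realisations
(the analysis is a priori: σ enters only as a row scale), model
misspecification, or the size of full pathway models; passing tests
demonstrate the machinery and its numerical stability, not biological
conclusions about any particular system. The full 39-parameter NF-κB
analysis is supported through the config schema (`examples/nfkb_stub.yaml`
shows the layout) but its equations and experiment catalogue must be
supplied by the user; nothing about it is bundled or asserted.

## Numerical choices, at a glance

| choice | value | why |
|---|---|---|
| solver / tolerances | LSODA, 1e-8 / 1e-10 | CCs near 1 are tolerance-sensitive |
| FD-oracle step / tolerances | 1e-6·θ_i, 1e-11 / 1e-13 | balance truncation vs amplified solver noise |
| rank tolerance | 1e-10 × block s_max | sloppy columns are numerically dependent |
| ρ clip | 1 − 1e-12 | MI diverges at ρ = 1; ranking falls back to height |
| defaults δ, ζ | 0.95, 1 (log scale) | ~10-fold inflation cap; order-of-magnitude error cap |
| merge tie-break | MI, then height, then smallest indices | determinism with capped MI |
| prune tie-break | largest ρ, then larger index | single-removal, deterministic |

Acceptance-style reproduction (`scripts/acceptance.py`) runs the whole stack
at these sizes: 100 random CCA-oracle instances (row dimension ≤ 4, groups
≤ 2), 20 random chains of 4 states with one planted pair each, and the two
built-in models with all their experiments — a few seconds end to end.

## Known limitations

- The analysis is local (sensitivities at θ*); a globally different
  parameter regime can have a different identifiability pattern.
- The identifiable set is not guaranteed maximal; no subset search is done.
- Linkage heights may be non-monotone; dendrograms are drawn as recorded.
- No SDE/CME simulation, no parameter estimation from data, no SBML import,
  no profile-likelihood validation; screening ranks only by identifiable
  count, not optimal-design criteria.
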