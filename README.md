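# micca

Fisher-information based identifiability analysis and parameter clustering
for ODE models of biochemical dynamics.

Dynamical models in quantitative biology routinely carry tens of kinetic
parameters but are constrained by sparse time-course data. Two effects make
individual parameters impossible to estimate: a parameter may barely move
the observables (insensitivity), or its effect may be absorbed by
compensating changes in other parameters (collinearity). Pairwise
correlations miss the second effect — three parameters with low pairwise
correlations can still be jointly non-identifiable. `micca` quantifies
similarity between *groups* of parameters and turns it into a practical
identifiability workflow for modellers and experimental designers.

## The method

For a model `dy/dt = F(y, θ)` observed at components and times of interest,
the sensitivity vector of parameter `θ_i` is `S_i = ∂Y/∂θ_i`, computed by the
forward (variational) ODE system and stacked over all experiments; under
unit-variance Gaussian observation error the Fisher information matrix is
`FI(θ) = SᵀS`. Two parameter groups `θ_A`, `θ_B` span two subspaces of
observation space; their **canonical correlations** `1 ≥ ρ₁ ≥ … ≥ ρ_m ≥ 0`
(`m = min(|A|, |B|)`) are the cosines of the principal angles between those
subspaces. Under the asymptotic Gaussian posterior of the estimates, the
mutual information between the estimate blocks depends on the data only
through these correlations, giving the **MI-CCA similarity**

    I(θ_A, θ_B) = −(1/m) Σᵢ log(1 − ρᵢ²)   [nats].

A parameter `θ_i` is **(δ, ζ)-identifiable** when `ρ(θ_i, θ_−i) < δ` (its
canonical correlation with the span of all remaining parameters — the
compensability bound, allowing at most a `1/(1−δ²)`-fold variance inflation)
and `‖S_i‖ > ζ` (the sensitivity bound, capping the single-parameter
asymptotic variance at `1/ζ`). With log-parametrisation the defaults
`δ = 0.95, ζ = 1` read: learnable to better than an order of magnitude, at
most a ~10-fold variance inflation under joint estimation.

A **modified agglomerative clustering** merges the two clusters with the
highest MI-CCA at each step, verifies the δ-condition inside every newly
merged cluster, and prunes the most-correlated members until all survivors
satisfy it; linkage heights are the normalised `(1/m) Σ (1 − ρᵢ²)`, so fully
compensated groups join at height 0. The output is a dendrogram of the
compensation structure plus a set of identifiable parameters.

## Worked example

The built-in two-stage gene expression model (`dr/dt = k_r − g_r r`,
`dp/dt = k_p r − g_p p`) observed **only at steady state**
`(k_r/g_r, k_r k_p/(g_r g_p))`:

```bash
micca cluster --fixture gene_expression --experiment steady_state
```

prints

```
((k_r:0,g_r[&removed=1]:0):0.3076923077,(k_p:2.220446049e-16,g_p[&removed=2]:2.220446049e-16):0.3076923077);
identifiable: ['k_r', 'k_p']; non-identifiable: ['g_p', 'g_r']
```

The production/degradation pairs `(k_r, g_r)` and `(k_p, g_p)` merge at
height 0 — the steady state depends on them only through ratios, so each is
perfectly compensated by its partner and one member of each pair is pruned
(`[&removed=...]` tags). The two pairs join at height 0.31 (> 0): they are
correlated but not fully redundant. The global (δ, ζ) test,

```bash
micca identifiability --fixture gene_expression -e steady_state
```

```
parameter  sensitivity_norm  fim_diagonal  rho_rest  zeta_pass  delta_pass  identifiable
      k_r          3.605551          13.0       1.0       True       False         False
      k_p          3.000000           9.0       1.0       True       False         False
      g_r          3.605551          13.0       1.0       True       False         False
      g_p          3.000000           9.0       1.0       True       False         False
```

shows every parameter fully compensated by the rest (`rho_rest = 1`): nothing
is identifiable from a steady-state measurement alone. Switching to the
`decay` experiment — the relaxation after pushing mRNA and protein above
their steady-state levels — makes all four rates identifiable
(`rho_rest ≤ 0.94`, all flags true). The same workflow runs on any model
declared in a YAML/JSON config (see `examples/`), including experiment
screening (`micca screen`) and group-vs-group similarity queries
(`micca similarity`).

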