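# Two-stage constitutive gene expression model, declared via the config
# schema.  Mirrors the built-in `gene_expression` fixture: mRNA r produced at
# rate k_r and degraded at g_r; protein p translated at k_p per mRNA and
# degraded at g_p.
schema: micca-model/1
model:
  name: gene_expression
  states: [r, p]
  parameters:
    k_r: 2.0
    k_p: 3.0
    g_r: 1.0
    g_p: 2.0
  rhs:
    r: "k_r - g_r * r"
    p: "k_p * r - g_p * p"
  initial_condition: [0, 0]
experiments:
  - name: steady_state
    observe: [r, p]
    times: [40.0]
  - name: decay
    observe: [r, p]
    times: {start: 0.05, stop: 15.0, num: 16, spacing: log}
    initial_state: [30.0, 4.5]
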