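# STUB (synthetic placeholder): scaffolding for the 39-parameter NF-kB
# pathway model.  The full equations, reference parameter values and the
# catalogue of published experiments are NOT bundled with this package; a
# user holding them can paste the right-hand sides and parameter values into
# this schema and run e.g.
#
#   micca cluster --config nfkb.yaml --delta 0.95 --zeta 1.0 \
#       --out tree.newick --report report.json
#
# The two entries below only illustrate the expected layout; they are not
# the real model.
schema: micca-model/1
model:
  name: nfkb_stub
  states: [y1, y2]            # ... 19 states in the full model
  parameters:
    ka: 1.0                   # ... 39 parameters in the full model
    ki: 0.5
  rhs:
    y1: "ka * u - ki * y1"    # replace with the full right-hand sides
    y2: "ki * y1"
  initial_condition: [0, 0]
experiments:
  - name: tnf_physiological    # gradual increase, plateau, gradual decrease
    observe: [y1, y2]
    times: {start: 0.5, stop: 30.0, num: 30}
    input:
      times: [0, 5, 20, 25]
      values: [0, 1, 1, 0]
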