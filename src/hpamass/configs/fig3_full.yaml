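# Prolonged-stress scenario for the full mass-dynamics model:
# u = 4 for 90 days, then back to basal u = 1; 300 days total.
variant: full_mass
protocol:
  baseline: 1
  segments:
    - {kind: step, start: 0, end: 90, u: 4, unit: day}
span: {start: 0, end: 300, unit: day}
schedule: {start: 1, end: 299, step: 2, unit: day}
solver: {rtol: 1.0e-8, atol: 1.0e-10, method: LSODA}
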