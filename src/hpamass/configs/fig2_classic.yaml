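# Same prolonged-stress protocol run through the classic constant-mass
# cascade: hormones stay elevated during stress and relax within hours.
variant: classic
protocol:
  baseline: 1
  segments:
    - {kind: step, start: 0, end: 90, u: 4, unit: day}
span: {start: 0, end: 120, unit: day}
schedule: {start: 1, end: 119, step: 2, unit: day}
solver: {rtol: 1.0e-8, atol: 1.0e-10, method: LSODA}
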