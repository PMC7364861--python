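# Alternative-mechanism comparison: run the prolonged-stress scenario
# through the full model and each constant-mass slow mechanism. Only the
# full mass model shows an intermediate-withdrawal (IW) window.
variants: [full_mass, classic, gr_resistance, slow_clearance, slow_input]
stress: {u: 4, duration_days: 90, span_days: 300, slow_input_tau_days: 30}
schedule: {start: 1, end: 299, step: 2, unit: day}
normal_band: 0.05
blunt_threshold: 0.9
solver: {rtol: 1.0e-8, atol: 1.0e-10, method: LSODA}
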