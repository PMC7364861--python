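# GR-strength sweep: K_GR = 2 (strong feedback), 4 (moderate), 8 (weak)
# through the prolonged-stress scenario. Stronger feedback attenuates
# the post-stress dysregulation.
variant: full_mass
sweep: {param: K_GR, values: [2, 4, 8]}
stress: {u: 4, duration_days: 90, span_days: 300}
schedule: {start: 1, end: 299, step: 2, unit: day}
solver: {rtol: 1.0e-8, atol: 1.0e-10, method: LSODA}
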