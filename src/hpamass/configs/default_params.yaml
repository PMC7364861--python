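# Default parameter set, conventional symbol names and units:
# fast removal rates per minute, slow turnover/relaxation rates per day.
w1: 0.17        # CRH removal (per min; half-life ~4 min)
w2: 0.035       # ACTH removal (per min; half-life ~20 min)
w3: 0.0086      # cortisol removal (per min; half-life ~80 min)
wC: 0.099       # corticotroph mass turnover (per day)
wA: 0.049       # adrenal mass turnover (per day)
K_GR: 4         # GR halfway-effect constant (dimensionless cortisol units)
n: 3            # GR Hill exponent
wCRHE: 0.016    # exogenous CRH removal (per min)
W: 30           # CRH bolus width (min)
D: 20           # CRH bolus dose (dimensionless)
wR: 0.0231049060186648  # ln(2)/30 per day: GR-resistance relaxation
wCE: 0.0231049060186648 # ln(2)/30 per day: clearance-modifier relaxation
lam: 1          # resistance-response coefficient
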