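# Methods

## Model structure and assumptions

The package simulates the HPA cascade CRH → ACTH → cortisol together
with the functional masses of the two downstream secretory tissues. All
variables are non-dimensional with basal steady state 1; concretely, the
dimensional secretion constants (including per-unit-mass secretion rates
and blood-volume factors) are absorbed into the normalization, so the
only free parameters are removal/turnover rates and the feedback
constants. The assumptions that matter:

* **Separation of timescales.** Hormone half-lives are minutes
  (ln2/w₁ ≈ 4 min, ln2/w₂ ≈ 20 min, ln2/w₃ ≈ 81 min); mass turnover is
  weeks (ln2/w_C ≈ 7.0 d, ln2/w_A ≈ 14.1 d). On the timescale of a CRH
  test the masses are effectively frozen; on the timescale of mass
  change the hormones are at quasi-steady state.
* **Hormones as growth factors.** Corticotroph mass grows with CRH and
  adrenal cortical mass with ACTH, multiplicatively
  (dC/dt = w_C·C·(x₁−1)), which makes zero mass absorbing and makes the
  mass equations integral controllers: any fixed point requires
  x₁ = x₂ = 1 exactly.
* **Receptor feedback.** MR is saturated at physiological cortisol, so
  its Michaelis–Menten form reduces to M(x₃) = 1/x₃. GR is cooperative
  and low-affinity: G(x₃) = 1/(1 + (R·x₃/K_GR)ⁿ), n = 3, with the
  resistance factor R = 1 except in the GR-resistance variant. CRH
  secretion sees M·G; ACTH secretion sees G only.

### Feedback normalization

With the constants of the default table, G(1) = 64/65 ≈ 0.985, so the
raw products u·g₁(x₃) would place the basal fixed point slightly off the
all-ones state. The package divides g₁ and g₂ by their value at x₃ = 1
(evaluated at R = 1), consistent with absorbing constants into the
production terms; the all-ones state is then an *exact* fixed point.
The choice shifts all absolute levels by ≤1.5% and none of the
qualitative conclusions. For the GR-resistance variant the normalizing
constant is deliberately kept at its R = 1 value so that R ≠ 1 genuinely
rescales feedback strength; that variant's own basal fixed point
(x₁ = 1, x₂ = x₃ ≈ 1.0136, R ≈ 0.493) is solved numerically by
`make_variant` and used as its baseline and control state.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| w₁, w₂, w₃ | CRH / ACTH / cortisol removal | 0.17, 0.035, 0.0086 | /min |
| w_C, w_A | corticotroph / adrenal mass turnover | 0.099, 0.049 | /day |
| K_GR | GR halfway-effect constant | 4 | – |
| n | GR Hill exponent | 3 | – |
| w_CRHE | exogenous CRH removal | 0.016 | /min |
| D, W | CRH-test dose, bolus width | 20, 30 | –, min |
| w_R, w_CR | resistance / clearance relaxation | ln2/30 | /day |
| λ | resistance response coefficient | 1 | – |

The canonical internal unit is the minute; per-day rates are divided by
1440 when a parameter file is loaded, and public constructors take an
explicit `unit` tag (`"min"`/`"day"`). K_GR is the lever for feedback
strength: smaller K_GR (stronger feedback) lets less extra cortisol
suppress ACTH to its set point, so the adrenal grows less under stress
and the post-stress dysregulation is smaller. The slow-mechanism rates
w_R and w_CR are set to a one-month timescale so the alternatives get
the same opportunity to act as the mass dynamics.

## Scenarios and read-outs

The reference scenario is a step stress input u = 4 lasting 90 days out
of a 300-day span, started from the basal steady state. CRH tests are
counterfactual probes: the scheduled day's state is cloned from the main
trajectory and a separate 3-hour simulation is run with the boxcar dose
active and the background protocol still in force; the main trajectory
is never perturbed. Response ratios divide the test's peak ACTH and
cortisol by the peaks of a single control test at the basal state. The
default "peak" is the maximum absolute level over the window; an
increment mode (peak minus pre-injection level) is available because
either reading of a clinical "maximum response" is defensible.

Phase classification uses a normality band of ±5% around a control
ratio of 1 and an ACTH blunting threshold of 0.9. These numbers are
design choices, not fitted: the band is wide enough to absorb the ≤1.5%
normalization ambiguity and narrow enough to separate the phases
cleanly. Post-stress days are EW while cortisol responses are outside
the band, IW once cortisol is in band but ACTH is below the blunting
threshold, and LW otherwise; in-stress days split into ONSET (ACTH
ratio still above 1) and ADAPTED. Two consequences of the strict band
are worth knowing: transitional days (cortisol in band, ACTH between
0.9 and 0.95) merge into LW, and the post-IW cortisol undershoot
(ratios down to ≈0.94 in the reference scenario) re-enters EW for a few
weeks before final recovery. The IW window itself — normal cortisol
test with blunted ACTH — is what distinguishes the mass model from
every constant-mass variant.

The recovery-order read-out uses a sustained-entry definition (first
time a hormone enters a ±1% band around baseline and stays). This is a
proxy for the analytic statement, which concerns baseline *crossings*:
CRH and cortisol cross baseline simultaneously (both are functions of
the product A·C near baseline), and ACTH cannot cross before them
because corticotroph mass is still shrinking while CRH is below
baseline. At coarse band widths and slow turnover the proxy can invert
the order (a shallow ACTH excursion enters a wide band early), so the
turnover-robustness test checks crossing order directly.

## Numerics

* Integrator: SciPy `solve_ivp`, LSODA by default (stiffness-switching;
  the system mixes ~4-minute and multi-week eigenvalues), rtol 1e-8 /
  atol 1e-10. Tolerances are deliberately tight because event times
  (baseline crossings) are compared across the timescale gap; the test
  suite asserts that halving them moves the reported quantities by less
  than 0.1%.
* Discontinuities of u(t) and of CRH boxcars are integration
  breakpoints: the solver is restarted at every edge and the
  discontinuous terms are held constant within each segment, so no step
  straddles a jump.
* Output is the solver's dense solution sampled hourly, refined to
  1-minute resolution inside CRH-test windows; crossings are refined by
  Brent root finding on a monotone (PCHIP) interpolant of the samples.
* M(x₃) = 1/x₃ is singular at zero, so simulations enforce a positivity
  floor of 1e-9 on hormones and masses and raise with the offending
  time rather than clamping silently.
* Steady states come from bisection-safe bracketed root finding
  (`brentq`) on x₃ = u·G(x₃)/G(1); the bracket [1e-6, max(10, 10u)] is
  guaranteed by the monotonicity of G. The quasi-steady closed forms
  x₃ = √(A·C·u), x₁ = u/x₃, x₂ = x₃/A neglect the GR Hill term; their
  relative error scales as (x₃/K_GR)ⁿ, i.e. ~2% at x₃ = 0.4·K_GR but
  ~8% at x₃ = K_GR/2, which the exact mode (root-finding on the full
  fixed-point equation) avoids.
* Everything is deterministic; no random number generator is used
  anywhere, and repeated runs are bit-identical.

## What the scenarios do and do not show

The step-input protocols are idealized: real chronic stressors are not
square pulses, inputs carry circadian and ultradian structure, and
clinical CRH-test cohorts have inter-subject variability none of which
is modelled. Passing the included checks therefore demonstrates the
internal consistency of the mechanism — exact adaptation, the A·C = 1
identity, the IW mismatch and its absence in constant-mass variants,
the K_GR resilience ordering — not quantitative agreement with any
patient cohort. Problem sizes used throughout (300–500 simulated days,
CRH tests every 2–3 days, 3-hour test windows) were chosen so every
analysis reflects the slow dynamics fully; the entire suite runs in
seconds.

## Known limitations

* Hyperplasia and hypertrophy are not distinguished; "functional mass"
  is a single lumped capacity.
* The hypothalamic input u is exogenous; there is no feedback from
  cortisol onto the stressor itself, and no AVP/oxytocin modulation of
  ACTH secretion.
* The GR-resistance and slow-clearance variants are deliberately
  minimal (single relaxation equations); they are falsification
  controls, not validated models of those biological processes.
* Only one slow mechanism is active at a time; combinations are out of
  scope.
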