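"""Model variants: the full mass-dynamics model, the classic
constant-mass cascade, and three alternative slow mechanisms.

The alternatives each add a single slow (one-month timescale) process to
the classic three-hormone model while keeping gland masses frozen at 1:

* ``gr_resistance`` — a resistance factor R that weakens GR feedback
  under chronically high cortisol (dR/dt = wR*(1 - (1 + lam*x3^2)*R));
* ``slow_clearance`` — a clearance modifier C_R that slows cortisol
  removal (dx3/dt = w3*(A*x2 - x3/C_R), dC_R/dt = wCR*(x3 - C_R));
* ``slow_input`` — classic dynamics driven by an input that decays
  exponentially after stress instead of stepping back to baseline.

They exist to test (and reject) non-mass explanations of the post-stress
mismatch between normal cortisol and blunted ACTH responses: none of
them decouples ACTH from cortisol, so none produces the
intermediate-withdrawal window that the full mass model does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    ConfigurationError,
    DomainError,
    FULL_STATE_NAMES,
    ModelParameters,
    NumericalError,
    feedback_terms,
    full_rhs,
    steady_state,
)

__all__ = [
    "ModelDefinition",
    "VARIANT_IDS",
    "classic_rhs",
    "gr_resistance_rhs",
    "slow_clearance_rhs",
    "make_variant",
]

VARIANT_IDS = ("full_mass", "classic", "gr_resistance", "slow_clearance", "slow_input")

RHSFunc = Callable[[float, np.ndarray, ModelParameters, float, float], np.ndarray]


@dataclass(frozen=True)
class ModelDefinition:
    """A model variant behind a uniform evaluator interface.

    ``rhs(t, y, params, u, crh_dose)`` returns the derivative of the
    state vector laid out as ``state_names``.  ``baseline`` is the fixed
    point of the evaluator at u = 1, used as the default initial state
    and as the control condition for CRH tests.
    """

    variant_id: str
    state_names: tuple[str, ...]
    rhs: RHSFunc
    baseline: np.ndarray

    def __post_init__(self) -> None:
        base = np.asarray(self.baseline, dtype=float)
        object.__setattr__(self, "baseline", base)
        if base.shape != (len(self.state_names),):
            raise ConfigurationError(
                f"baseline shape {base.shape} does not match layout {self.state_names}"
            )

    @property
    def dim(self) -> int:
        return len(self.state_names)

    def index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise KeyError(f"variable {name!r} not in layout {self.state_names}") from None


def _check_dim(y: np.ndarray, dim: int, variant: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (dim,):
        raise ConfigurationError(f"{variant} expects {dim} state variables, got shape {y.shape}")
    return y


def classic_rhs(
    t: float, state: np.ndarray, params: ModelParameters, u: float, crh_dose: float = 0.0
) -> np.ndarray:
    """Classic constant-mass cascade; layout ``(x1, x2, x3, x1E)``.

    Identical to the full model with C = A = 1 frozen.  Hormones track
    the input with no slow adaptation: under sustained stress all three
    stay elevated, and after stress ends they relax within hours.
    """
    x1, x2, x3, x1E = _check_dim(state, 4, "classic")
    if u < 0:
        raise DomainError(f"stress input u must be non-negative, got {u}")
    g1, g2 = feedback_terms(x3, params)
    p = params
    return np.array([
        p.w1 * (u * g1 - x1),
        p.w2 * (g2 * (x1 + x1E) - x2),
        p.w3 * (x2 - x3),
        p.wCRHE * (crh_dose - x1E),
    ])


def gr_resistance_rhs(
    t: float, state: np.ndarray, params: ModelParameters, u: float, crh_dose: float = 0.0
) -> np.ndarray:
    """GR-resistance variant; layout ``(x1, x2, x3, x1E, R)``.

    Classic hormone dynamics with the GR Hill function evaluated at
    resistance factor R, while the feedback normalization stays frozen
    at the R = 1 constant so that R genuinely rescales feedback
    strength.  R relaxes toward 1/(1 + lam*x3^2): sustained high
    cortisol drives R down, i.e. weaker feedback.
    """
    x1, x2, x3, x1E, R = _check_dim(state, 5, "gr_resistance")
    if R <= 0:
        raise DomainError(f"resistance factor R must be strictly positive, got {R}")
    if u < 0:
        raise DomainError(f"stress input u must be non-negative, got {u}")
    g1, g2 = feedback_terms(x3, params, R=R)
    p = params
    return np.array([
        p.w1 * (u * g1 - x1),
        p.w2 * (g2 * (x1 + x1E) - x2),
        p.w3 * (x2 - x3),
        p.wCRHE * (crh_dose - x1E),
        p.wR * (1.0 - (1.0 + p.lam * x3 ** 2) * R),
    ])


def slow_clearance_rhs(
    t: float, state: np.ndarray, params: ModelParameters, u: float, crh_dose: float = 0.0
) -> np.ndarray:
    """Slow-cortisol-clearance variant; layout ``(x1, x2, x3, x1E, C_R)``.

    Classic dynamics with the cortisol removal term divided by the
    clearance modifier C_R (C_R = 2 halves the effective removal rate);
    C_R itself relaxes toward the cortisol level on the wCR timescale.
    The adrenal mass A of the cortisol equation is fixed at 1 here.
    """
    x1, x2, x3, x1E, C_R = _check_dim(state, 5, "slow_clearance")
    if C_R <= 0:
        raise DomainError(f"clearance modifier C_R must be strictly positive, got {C_R}")
    if u < 0:
        raise DomainError(f"stress input u must be non-negative, got {u}")
    g1, g2 = feedback_terms(x3, params)
    p = params
    A = 1.0  # adrenal mass, frozen in all constant-mass variants
    return np.array([
        p.w1 * (u * g1 - x1),
        p.w2 * (g2 * (x1 + x1E) - x2),
        p.w3 * (A * x2 - x3 / C_R),
        p.wCRHE * (crh_dose - x1E),
        p.wCR * (x3 - C_R),
    ])


def _full_mass_rhs(
    t: float, state: np.ndarray, params: ModelParameters, u: float, crh_dose: float = 0.0
) -> np.ndarray:
    return full_rhs(t, state, params, u, crh_dose)


def _gr_resistance_baseline(params: ModelParameters) -> np.ndarray:
    """Fixed point of the GR-resistance variant at u = 1.

    With the normalization frozen at R = 1, the basal resistance
    R* = 1/(1 + lam*x3^2) < 1 slightly weakens feedback, so the variant's
    own baseline sits a little off the all-ones point: x1 = 1 and
    x2 = x3 solve x3 = G(x3, R*(x3)) / G(1, 1).
    """

    def f(x3: float) -> float:
        R = 1.0 / (1.0 + params.lam * x3 ** 2)
        _, g2 = feedback_terms(x3, params, R=R)
        return g2 - x3

    lo, hi = 0.2, 5.0
    if f(lo) * f(hi) > 0:
        raise NumericalError("gr_resistance baseline root not bracketed on [0.2, 5]")
    x3 = brentq(f, lo, hi, xtol=1e-14)
    R = 1.0 / (1.0 + params.lam * x3 ** 2)
    return np.array([1.0, x3, x3, 0.0, R])


def make_variant(variant_id: str, params: ModelParameters) -> ModelDefinition:
    """Construct a :class:`ModelDefinition` for a recognized variant id.

    The ``slow_input`` variant shares the classic evaluator; what makes
    it "slow" is the exponentially decaying input protocol attached by
    the scenario (see :func:`hpamass.stimuli.prolonged_stress_protocol`).
    """
    if variant_id == "full_mass":
        base = steady_state(params, 1.0)
        return ModelDefinition(
            variant_id,
            FULL_STATE_NAMES,
            _full_mass_rhs,
            np.array([base.x1, base.x2, base.x3, base.C, base.A, 0.0]),
        )
    if variant_id in ("classic", "slow_input"):
        return ModelDefinition(
            variant_id,
            ("x1", "x2", "x3", "x1E"),
            classic_rhs,
            np.array([1.0, 1.0, 1.0, 0.0]),
        )
    if variant_id == "gr_resistance":
        return ModelDefinition(
            variant_id,
            ("x1", "x2", "x3", "x1E", "R"),
            gr_resistance_rhs,
            _gr_resistance_baseline(params),
        )
    if variant_id == "slow_clearance":
        return ModelDefinition(
            variant_id,
            ("x1", "x2", "x3", "x1E", "C_R"),
            slow_clearance_rhs,
            np.array([1.0, 1.0, 1.0, 0.0, 1.0]),
        )
    raise ConfigurationError(
        f"unknown variant {variant_id!r}; valid ids: {', '.join(VARIANT_IDS)}"
    )
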