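"""Core hormone-and-gland-mass model of the HPA axis.

The hypothalamic-pituitary-adrenal (HPA) axis is modelled as a
three-hormone cascade — CRH (``x1``), ACTH (``x2``), cortisol (``x3``) —
extended with two slow variables for the functional mass of the secreting
tissues: the pituitary corticotrophs ``C`` and the adrenal cortex ``A``.
The hormones act as growth factors for their downstream glands, which
turns the mass equations into integral feedback on CRH and ACTH: the only
steady state of ``dC/dt = wC*C*(x1 - 1)`` and ``dA/dt = wA*A*(x2 - 1)``
has ``x1 = x2 = 1``, so CRH and ACTH adapt exactly to any sustained
stress input ``u`` while cortisol and the gland masses track it.

All variables are dimensionless, normalized so that the basal
(``u = 1``) steady state is the all-ones vector.  Cortisol feeds back on
CRH through both the saturated mineralocorticoid receptor
(``M(x3) = 1/x3``) and the cooperative, low-affinity glucocorticoid
receptor (Hill function ``G``), and on ACTH through GR only.  The
feedback factors are renormalized by their value at the basal point so
that the all-ones state is an *exact* fixed point (see
:func:`feedback_terms`).

The canonical time unit is the **minute**; per-day rates are converted on
load.  Public constructors accept either unit through an explicit
``unit`` tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MINUTES_PER_DAY",
    "POSITIVITY_FLOOR",
    "DomainError",
    "ConfigurationError",
    "NumericalError",
    "ModelParameters",
    "ModelState",
    "FULL_STATE_NAMES",
    "feedback_mr",
    "feedback_gr",
    "feedback_terms",
    "full_rhs",
    "steady_state",
    "fast_quasi_steady_state",
]

MINUTES_PER_DAY = 1440.0

#: Hard positivity floor for hormone/mass variables during simulation.
#: Trajectories that reach it raise instead of being silently clamped,
#: because M(x3) = 1/x3 is singular at zero.
POSITIVITY_FLOOR = 1e-9


class DomainError(ValueError):
    """A model quantity left its mathematical domain (e.g. x3 <= 0)."""


class ConfigurationError(ValueError):
    """Invalid parameter set, unit tag, or scenario configuration."""


class NumericalError(RuntimeError):
    """Solver failure: lost bracket, step collapse, positivity breach."""


def _as_minutes_rate(value: float, unit: str) -> float:
    if unit == "min":
        return float(value)
    if unit == "day":
        return float(value) / MINUTES_PER_DAY
    raise ConfigurationError(f"unknown time unit {unit!r}; expected 'min' or 'day'")


def to_minutes(t: float, unit: str = "min") -> float:
    """Convert a time value in ``unit`` ('min' or 'day') to minutes."""
    if unit == "min":
        return float(t)
    if unit == "day":
        return float(t) * MINUTES_PER_DAY
    raise ConfigurationError(f"unknown time unit {unit!r}; expected 'min' or 'day'")


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Rate and feedback constants of the non-dimensionalized model.

    All rates are stored per **minute** (the canonical unit); use
    :meth:`from_config` to load a mapping keyed by the conventional
    symbol names with slow rates given per day.

    Attributes
    ----------
    w1, w2, w3 : float
        Removal rates of CRH, ACTH and cortisol (per minute).  Half-lives
        ln2/w are ~4, ~20 and ~80 minutes.
    wC, wA : float
        Turnover rates of corticotroph and adrenal functional mass
        (per minute internally; 0.099/day and 0.049/day by default).
    K_GR : float
        GR halfway-effect constant in dimensionless cortisol units.
        Larger K_GR means weaker glucocorticoid feedback.
    n : int
        GR Hill exponent (cooperativity), default 3.
    wCRHE : float
        Removal rate of exogenously injected CRH (per minute).
    W, D : float
        CRH-test bolus width (minutes) and dose (dimensionless).
    wR : float
        Relaxation rate of the GR-resistance variable R (per minute;
        ln2/30 per day by default, a one-month timescale).
    wCR : float
        Relaxation rate of the slow cortisol-clearance modifier
        (per minute; same one-month default).
    lam : float
        Resistance-response coefficient lambda in h(x3) = 1 + lam*x3^2.
    """

    w1: float = 0.17
    w2: float = 0.035
    w3: float = 0.0086
    wC: float = 0.099 / MINUTES_PER_DAY
    wA: float = 0.049 / MINUTES_PER_DAY
    K_GR: float = 4.0
    n: int = 3
    wCRHE: float = 0.016
    W: float = 30.0
    D: float = 20.0
    wR: float = math.log(2) / 30.0 / MINUTES_PER_DAY
    wCR: float = math.log(2) / 30.0 / MINUTES_PER_DAY
    lam: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3", "wC", "wA", "wCRHE", "wR", "wCR"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"rate {name} must be strictly positive, got {v}")
        if not (np.isfinite(self.K_GR) and self.K_GR > 1):
            raise ConfigurationError(f"K_GR must exceed 1, got {self.K_GR}")
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise ConfigurationError(f"Hill exponent n must be a positive integer, got {self.n!r}")
        if not (self.W > 0 and self.D >= 0 and self.lam >= 0):
            raise ConfigurationError("W must be positive; D and lam non-negative")

    # per-day symbols as they appear in configuration files
    _DAY_RATE_KEYS = ("wC", "wA", "wR", "wCR")
    _MIN_RATE_KEYS = ("w1", "w2", "w3", "wCRHE")

    @classmethod
    def from_config(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        """Build parameters from a mapping keyed by symbol names.

        Slow rates (``wC``, ``wA``, ``wR``, ``wCR``) are interpreted per
        day, fast rates (``w1``, ``w2``, ``w3``, ``wCRHE``) per minute,
        matching the conventional presentation.  ``wCE`` is accepted as
        an alias for ``wCR``; ``lambda`` for ``lam``.
        """
        data = dict(mapping)
        if "wCE" in data:
            data.setdefault("wCR", data.pop("wCE"))
        if "lambda" in data:
            data.setdefault("lam", data.pop("lambda"))
        kwargs: dict[str, float | int] = {}
        valid = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for key, value in data.items():
            if key not in valid:
                raise ConfigurationError(f"unknown parameter {key!r}")
            if key in cls._DAY_RATE_KEYS:
                kwargs[key] = float(value) / MINUTES_PER_DAY
            elif key == "n":
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def to_config(self) -> dict[str, float]:
        """Inverse of :meth:`from_config` (slow rates back to per day)."""
        out: dict[str, float] = {}
        for name in self.__dataclass_fields__:  # type: ignore[attr-defined]
            v = getattr(self, name)
            if name in self._DAY_RATE_KEYS:
                v = v * MINUTES_PER_DAY
            out[name] = v
        return out

    def with_overrides(self, overrides: Mapping[str, float] | None) -> "ModelParameters":
        """Apply config-style overrides (per-day slow rates) and revalidate."""
        if not overrides:
            return self
        cfg = self.to_config()
        cfg.update(overrides)
        return ModelParameters.from_config(cfg)


# --------------------------------------------------------------------------
# State
# --------------------------------------------------------------------------

FULL_STATE_NAMES = ("x1", "x2", "x3", "C", "A", "x1E")


@dataclass(frozen=True)
class ModelState:
    """Dimensionless state of the full model, baseline = all ones.

    ``x1E`` is exogenous (injected) CRH, zero at baseline.  ``R`` and
    ``C_R`` are extension slots used by the GR-resistance and
    slow-clearance model variants; both are 1 at baseline.
    """

    x1: float = 1.0
    x2: float = 1.0
    x3: float = 1.0
    C: float = 1.0
    A: float = 1.0
    x1E: float = 0.0
    R: float = 1.0
    C_R: float = 1.0

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "x3", "C", "A", "R", "C_R"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"state variable {name} must be strictly positive, got {v}")
        if not (np.isfinite(self.x1E) and self.x1E >= 0):
            raise DomainError(f"exogenous CRH x1E must be non-negative, got {self.x1E}")

    def to_array(self) -> np.ndarray:
        """Full-model layout ``(x1, x2, x3, C, A, x1E)``."""
        return np.array([self.x1, self.x2, self.x3, self.C, self.A, self.x1E])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        x1, x2, x3, C, A, x1E = (float(v) for v in np.asarray(y, dtype=float))
        return cls(x1=x1, x2=x2, x3=x3, C=C, A=A, x1E=x1E)


# --------------------------------------------------------------------------
# Feedback functions
# --------------------------------------------------------------------------

def feedback_mr(x3: float) -> float:
    """Saturated MR feedback, M(x3) = 1/x3.

    Cortisol saturates the high-affinity mineralocorticoid receptor at
    physiological levels, so the Michaelis-Menten form reduces to a
    reciprocal with the constant absorbed into the production terms.
    """
    x3 = float(x3)
    if not (np.isfinite(x3) and x3 > 0):
        raise DomainError(f"x3 must be strictly positive for MR feedback, got {x3}")
    return 1.0 / x3


def feedback_gr(x3: float, K_GR: float, n: int, R: float = 1.0) -> float:
    """Cooperative GR feedback, G(x3) = 1 / (1 + (R*x3/K_GR)^n).

    ``R`` is the resistance factor of the GR-resistance variant; R < 1
    weakens feedback.  Strictly decreasing in x3 for R > 0.
    """
    x3 = float(x3)
    R = float(R)
    if not (np.isfinite(x3) and x3 >= 0):
        raise DomainError(f"x3 must be non-negative for GR feedback, got {x3}")
    if not (np.isfinite(R) and R >= 0):
        raise DomainError(f"resistance factor R must be non-negative, got {R}")
    return 1.0 / (1.0 + (R * x3 / K_GR) ** n)


def feedback_terms(x3: float, params: ModelParameters, R: float = 1.0) -> tuple[float, float]:
    """Baseline-normalized feedback factors (g1, g2).

    g1(x3) = M(x3) G(x3) / [M(1) G(1)] acts on CRH secretion,
    g2(x3) = G(x3) / G(1) on ACTH secretion, where the normalizing G(1)
    is always evaluated at R = 1.  The normalization guarantees
    g1(1) = g2(1) = 1 at R = 1, making the all-ones state an exact fixed
    point of the full model at u = 1.
    """
    g0 = feedback_gr(1.0, params.K_GR, params.n, 1.0)
    g2 = feedback_gr(x3, params.K_GR, params.n, R) / g0
    g1 = feedback_mr(x3) * g2  # M(1) = 1
    return g1, g2


# --------------------------------------------------------------------------
# Right-hand side of the full model
# --------------------------------------------------------------------------

def full_rhs(
    t: float,
    state: "ModelState | np.ndarray",
    params: ModelParameters,
    u: float,
    crh_dose: float = 0.0,
) -> np.ndarray:
    """Time derivative of the full mass-dynamics model.

    State layout ``(x1, x2, x3, C, A, x1E)``; ``u`` is the stress input
    and ``crh_dose`` the instantaneous exogenous CRH infusion (the CRH
    test boxcar).  Returns derivatives per minute:

    .. code-block:: text

        dx1  = w1 * (u * g1(x3) - x1)
        dx2  = w2 * (C * g2(x3) * (x1 + x1E) - x2)
        dx3  = w3 * (A * x2 - x3)
        dC   = wC * C * (x1 - 1)
        dA   = wA * A * (x2 - 1)
        dx1E = wCRHE * (crh_dose - x1E)

    The mass-action structure is preserved: dC = 0 when C = 0 and
    dA = 0 when A = 0 (absorbing boundaries of the growth laws).
    """
    if isinstance(state, ModelState):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
    if y.shape != (6,):
        raise ConfigurationError(f"full model expects 6 state variables, got shape {y.shape}")
    if u < 0:
        raise DomainError(f"stress input u must be non-negative, got {u}")
    x1, x2, x3, C, A, x1E = y
    g1, g2 = feedback_terms(x3, params)
    p = params
    return np.array([
        p.w1 * (u * g1 - x1),
        p.w2 * (C * g2 * (x1 + x1E) - x2),
        p.w3 * (A * x2 - x3),
        p.wC * C * (x1 - 1.0),
        p.wA * A * (x2 - 1.0),
        p.wCRHE * (crh_dose - x1E),
    ])


# --------------------------------------------------------------------------
# Steady states
# --------------------------------------------------------------------------

def _gr_ratio(x3: float, params: ModelParameters, R: float = 1.0) -> float:
    """G(x3, R) / G(1, R=1) — the normalized GR factor."""
    return feedback_gr(x3, params.K_GR, params.n, R) / feedback_gr(1.0, params.K_GR, params.n, 1.0)


def steady_state(
    params: ModelParameters,
    u: float,
    *,
    tol: float = 1e-12,
) -> ModelState:
    """Unique fixed point of the full model at constant input ``u``.

    Integral feedback pins ``x1 = x2 = 1`` exactly.  Cortisol solves
    the scalar fixed-point equation ``x3 = u * G(x3)/G(1)`` (found by
    bracketing root search), and the masses follow as ``A = x3`` and
    ``C = 1/g2(x3)``.

    Raises
    ------
    NumericalError
        If the root is not bracketed in ``[1e-6, max(10, 10u)]``.
    """
    if not (np.isfinite(u) and u > 0):
        raise DomainError(f"constant input u must be strictly positive, got {u}")

    def f(x3: float) -> float:
        return u * _gr_ratio(x3, params) - x3

    lo, hi = 1e-6, max(10.0, 10.0 * u)
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise NumericalError(
            f"steady-state root not bracketed on [{lo}, {hi}]: f(lo)={flo:.3g}, f(hi)={fhi:.3g}"
        )
    x3 = brentq(f, lo, hi, xtol=tol, rtol=8.881784197001252e-16)
    _, g2 = feedback_terms(x3, params)
    state = ModelState(x1=1.0, x2=1.0, x3=x3, C=1.0 / g2, A=x3)
    residual = full_rhs(0.0, state, params, u)
    if np.max(np.abs(residual)) > 1e-8:
        raise NumericalError(f"steady-state residual too large: {residual}")
    return state


def fast_quasi_steady_state(
    C: float,
    A: float,
    u: float,
    params: ModelParameters,
    mode: Literal["exact", "approx"] = "approx",
) -> tuple[float, float, float]:
    """Quasi-steady hormones (x1, x2, x3) for frozen masses C, A.

    On the minutes-to-hours timescale the gland masses are constant and
    the hormone cascade equilibrates.  ``mode='approx'`` neglects the
    variation of G and returns the closed forms

        x3 = sqrt(A*C*u),  x1 = u/x3,  x2 = x3/A,

    which are exact in the limit x3 << K_GR.  ``mode='exact'`` solves
    x3 = sqrt(A*C*u) * G(x3)/G(1) by bracketed root finding and derives
    x1, x2 consistently.  The two agree to within the neglected
    G-deviation whenever x3 is well below K_GR.
    """
    if not (C > 0 and A > 0 and u > 0):
        raise DomainError(f"C, A, u must be strictly positive, got C={C}, A={A}, u={u}")
    s = math.sqrt(A * C * u)
    if mode == "approx":
        x3 = s
        return u / x3, x3 / A, x3
    if mode != "exact":
        raise ConfigurationError(f"unknown QSS mode {mode!r}; expected 'exact' or 'approx'")

    def f(x3: float) -> float:
        return s * _gr_ratio(x3, params) - x3

    lo, hi = 1e-9, max(10.0, 10.0 * s)
    if f(lo) * f(hi) > 0:
        raise NumericalError("QSS root not bracketed")
    x3 = brentq(f, lo, hi, xtol=1e-14)
    g1, _ = feedback_terms(x3, params)
    return u * g1, x3 / A, x3
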