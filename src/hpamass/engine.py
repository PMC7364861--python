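"""Scenario integration, event location, and trajectory I/O.

The model mixes a minutes-scale hormone cascade with weeks-scale mass
dynamics (a ~5000-fold timescale separation), so scenarios are
integrated with a stiff-capable adaptive solver (LSODA by default) at
tight tolerances, restarted at every discontinuity of the input
protocol and of CRH-test boxcars so that no step straddles a jump.
Everything is deterministic: identical configuration and tolerances
reproduce trajectories bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .model_core import (
    ConfigurationError,
    MINUTES_PER_DAY,
    ModelParameters,
    NumericalError,
    POSITIVITY_FLOOR,
    to_minutes,
)
from .stimuli import CRHTestSpec, InputProtocol, crh_dose_at, input_at
from .variants import ModelDefinition, make_variant

__all__ = [
    "ScenarioConfig",
    "Trajectory",
    "simulate",
    "find_crossings",
    "write_trajectory",
    "read_trajectory",
    "load_scenario",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to (re)run one simulation.

    Times are minutes unless constructed through :meth:`from_dict`,
    which honours per-field ``unit`` tags.  ``initial_state`` defaults
    to the variant's baseline (its fixed point at u = 1).
    """

    variant: str = "full_mass"
    params: ModelParameters = field(default_factory=ModelParameters)
    protocol: InputProtocol = field(default_factory=InputProtocol)
    t_start: float = 0.0
    t_end: float = 300.0 * MINUTES_PER_DAY
    initial_state: np.ndarray | None = None
    crh_tests: tuple[CRHTestSpec, ...] = ()
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    max_step: float = np.inf
    sample_step: float = 60.0      # coarse output grid, minutes
    crh_sample_step: float = 1.0   # fine grid inside CRH-test windows

    def __post_init__(self) -> None:
        if not (self.t_end > self.t_start):
            raise ConfigurationError(f"span must be positive, got [{self.t_start}, {self.t_end}]")
        if not (self.rtol > 0 and self.atol > 0):
            raise ConfigurationError("solver tolerances must be positive")
        if self.initial_state is not None:
            y0 = np.asarray(self.initial_state, dtype=float)
            object.__setattr__(self, "initial_state", y0)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioConfig":
        params = ModelParameters().with_overrides(data.get("params"))
        protocol = InputProtocol.from_dict(data.get("protocol", {}))
        span = data.get("span", {})
        unit = span.get("unit", "min")
        tests = tuple(CRHTestSpec.from_dict(t) for t in data.get("crh_tests", ()))
        solver = data.get("solver", {})
        return cls(
            variant=data.get("variant", "full_mass"),
            params=params,
            protocol=protocol,
            t_start=to_minutes(span.get("start", 0.0), unit),
            t_end=to_minutes(span.get("end", 300.0 if unit == "day" else 300.0 * MINUTES_PER_DAY), unit),
            initial_state=(np.asarray(data["initial_state"], dtype=float)
                           if data.get("initial_state") is not None else None),
            crh_tests=tests,
            rtol=float(solver.get("rtol", 1e-8)),
            atol=float(solver.get("atol", 1e-10)),
            method=str(solver.get("method", "LSODA")),
            sample_step=float(solver.get("sample_step", 60.0)),
            crh_sample_step=float(solver.get("crh_sample_step", 1.0)),
        )

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": self.params.to_config(),
            "protocol": self.protocol.to_dict(),
            "span": {"start": self.t_start, "end": self.t_end, "unit": "min"},
            "initial_state": (None if self.initial_state is None else list(map(float, self.initial_state))),
            "crh_tests": [t.to_dict() for t in self.crh_tests],
            "solver": {
                "rtol": self.rtol,
                "atol": self.atol,
                "method": self.method,
                "sample_step": self.sample_step,
                "crh_sample_step": self.crh_sample_step,
            },
        }


class Trajectory:
    """Time grid plus state matrix, with enough metadata to re-run.

    ``t`` is in minutes (strictly increasing), ``y`` has one column per
    state variable in ``state_names`` order.
    """

    def __init__(
        self,
        t: np.ndarray,
        y: np.ndarray,
        state_names: Sequence[str],
        variant: str,
        meta: dict | None = None,
    ) -> None:
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.state_names = tuple(state_names)
        self.variant = variant
        self.meta = dict(meta or {})
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0):
            raise ConfigurationError("trajectory time grid must be strictly increasing")
        if self.y.shape != (self.t.size, len(self.state_names)):
            raise ConfigurationError(
                f"state matrix shape {self.y.shape} does not match "
                f"({self.t.size}, {len(self.state_names)})"
            )
        self._interp: dict[str, PchipInterpolator] = {}

    def column(self, name: str) -> np.ndarray:
        try:
            return self.y[:, self.state_names.index(name)]
        except ValueError:
            raise KeyError(f"variable {name!r} not in layout {self.state_names}") from None

    def _interpolator(self, name: str) -> PchipInterpolator:
        if name not in self._interp:
            self._interp[name] = PchipInterpolator(self.t, self.column(name), extrapolate=False)
        return self._interp[name]

    def value_at(self, name: str, t: float) -> float:
        v = float(self._interpolator(name)(t))
        if np.isnan(v):
            raise ConfigurationError(f"time {t} outside trajectory span [{self.t[0]}, {self.t[-1]}]")
        return v

    def state_at(self, t: float) -> np.ndarray:
        return np.array([self.value_at(name, t) for name in self.state_names])

    @property
    def t_days(self) -> np.ndarray:
        return self.t / MINUTES_PER_DAY

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.state_names))
        df.insert(0, "t", self.t)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            self.variant == other.variant
            and self.state_names == other.state_names
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.y, other.y)
        )


def _sample_grid(config: ScenarioConfig, breakpoints: Sequence[float]) -> np.ndarray:
    pieces = [np.arange(config.t_start, config.t_end, config.sample_step), [config.t_end]]
    for spec in config.crh_tests:
        lo = max(spec.t_inj, config.t_start)
        hi = min(spec.t_inj + spec.window, config.t_end)
        if hi > lo:
            pieces.append(np.arange(lo, hi, config.crh_sample_step))
            pieces.append([hi])
    pieces.append([b for b in breakpoints if config.t_start <= b <= config.t_end])
    grid = np.unique(np.concatenate([np.asarray(p, dtype=float) for p in pieces]))
    return grid


def simulate(model: ModelDefinition, config: ScenarioConfig) -> Trajectory:
    """Integrate ``model`` over the scenario and sample its dense output.

    The integration is restarted at every protocol breakpoint and every
    CRH boxcar edge.  Raises :class:`NumericalError` if any hormone or
    mass variable touches the positivity floor (the MR feedback 1/x3 is
    singular there) or if the solver fails.
    """
    if config.variant != model.variant_id:
        raise ConfigurationError(
            f"config variant {config.variant!r} does not match model {model.variant_id!r}"
        )
    y0 = config.initial_state if config.initial_state is not None else model.baseline
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (model.dim,):
        raise ConfigurationError(f"initial state shape {y0.shape} != model dim {model.dim}")

    breaks = set(config.protocol.breakpoints())
    for spec in config.crh_tests:
        breaks.update(spec.breakpoints())
    breaks = sorted(b for b in breaks if config.t_start < b < config.t_end)
    edges = [config.t_start, *breaks, config.t_end]

    grid = _sample_grid(config, edges)

    def make_rhs(a: float, b: float):
        # the boxcar dose is constant between breakpoints; sample it at the
        # segment midpoint, and clip protocol evaluation into [a, b) so the
        # solver never sees the jump that sits exactly on a segment edge
        mid = 0.5 * (a + b)
        dose = sum(crh_dose_at(spec, mid) for spec in config.crh_tests)
        b_in = np.nextafter(b, a)

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            u = input_at(config.protocol, min(max(t, a), b_in))
            return model.rhs(t, y, config.params, u, dose)

        return rhs

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        seg_grid = grid[(grid >= a) & (grid <= b)]
        sol = solve_ivp(
            make_rhs(a, b),
            (a, b),
            y,
            method=config.method,
            rtol=config.rtol,
            atol=config.atol,
            max_step=config.max_step,
            dense_output=True,
            t_eval=seg_grid,
        )
        if not sol.success:
            raise NumericalError(f"integration failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1] if sol.t[-1] == b else sol.sol(b)
        ts.append(sol.t)
        ys.append(sol.y.T)

    t_all = np.concatenate(ts)
    y_all = np.vstack(ys)
    t_all, keep = np.unique(t_all, return_index=True)
    y_all = y_all[keep]

    mass_like = [i for i, n in enumerate(model.state_names) if n != "x1E"]
    floor_hit = y_all[:, mass_like] <= POSITIVITY_FLOOR
    if floor_hit.any():
        i, j = np.argwhere(floor_hit)[0]
        raise NumericalError(
            f"variable {model.state_names[mass_like[j]]!r} reached the positivity floor "
            f"at t = {t_all[i]:.6g} min"
        )

    meta = {
        "variant": model.variant_id,
        "state_names": list(model.state_names),
        "config": config.to_dict(),
        "stress_end": config.protocol.end_of_last_offbaseline(),
    }
    return Trajectory(t_all, y_all, model.state_names, model.variant_id, meta)


def find_crossings(
    traj: Trajectory,
    variable: str,
    level: float,
    direction: str = "any",
) -> list[float]:
    """Times (minutes) where ``variable`` crosses ``level``.

    Sign-change scan on the sampled grid followed by root refinement on
    a monotone (PCHIP) interpolant; ``direction`` filters for 'rising',
    'falling' or 'any'.  Returns an empty list when there is no
    crossing; grid points lying exactly on the level are treated as
    crossings only if the sign changes across them.
    """
    if direction not in ("rising", "falling", "any"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    f = traj.column(variable) - level
    interp = traj._interpolator(variable)
    times: list[float] = []
    sign = np.sign(f)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        a, b = traj.t[i], traj.t[i + 1]
        root = brentq(lambda t: float(interp(t)) - level, a, b, xtol=max(1e-6 * max(abs(a), 1.0), 1e-12))
        going_up = f[i + 1] > f[i]
        if direction == "any" or (direction == "rising") == going_up:
            times.append(root)
    return times


# --------------------------------------------------------------------------
# Trajectory files: JSON metadata header (comment lines) + CSV body
# --------------------------------------------------------------------------

_HEADER_PREFIX = "#meta "


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a JSON-header + CSV-body text file."""
    meta = dict(traj.meta)
    meta.setdefault("variant", traj.variant)
    meta["state_names"] = list(traj.state_names)
    with open(path, "w") as fh:
        fh.write(_HEADER_PREFIX + json.dumps(meta) + "\n")
        traj.to_frame().to_csv(fh, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    """Inverse of :func:`write_trajectory`; round-trips exactly."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_HEADER_PREFIX):
            raise ConfigurationError(f"{path}: line 1: missing metadata header")
        try:
            meta = json.loads(first[len(_HEADER_PREFIX):])
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"{path}: line 1: malformed metadata JSON: {exc}") from exc
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except Exception as exc:
            raise ConfigurationError(f"{path}: malformed CSV body: {exc}") from exc
    names = meta.get("state_names")
    if not names or list(df.columns) != ["t", *names]:
        raise ConfigurationError(
            f"{path}: line 2: columns {list(df.columns)} do not match metadata layout {names}"
        )
    return Trajectory(
        df["t"].to_numpy(),
        df[names].to_numpy(),
        names,
        meta.get("variant", "full_mass"),
        meta,
    )


def load_scenario(source) -> tuple[ModelDefinition, ScenarioConfig]:
    """Load a scenario from a YAML/JSON file path or a mapping.

    Returns the constructed model definition together with the config.
    """
    import yaml

    if isinstance(source, Mapping):
        data = source
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{source}: scenario file must contain a mapping")
    config = ScenarioConfig.from_dict(data)
    model = make_variant(config.variant, config.params)
    return model, config
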