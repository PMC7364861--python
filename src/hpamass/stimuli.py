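"""Stress-input protocols u(t) and exogenous CRH dosing.

The combined physiological/psychological stress input ``u`` drives CRH
secretion.  Scenarios describe it piecewise: step segments (e.g. the
prolonged-stress pulse u=4 for 90 days followed by return to u=1) or
exponentially relaxing segments (the slow-input alternative mechanism).
The CRH stimulation test injects a boxcar dose of exogenous CRH on top
of whatever input protocol is running.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model_core import ConfigurationError, MINUTES_PER_DAY, to_minutes

__all__ = [
    "Segment",
    "InputProtocol",
    "CRHTestSpec",
    "input_at",
    "crh_dose_at",
    "prolonged_stress_protocol",
]


@dataclass(frozen=True)
class Segment:
    """One piece of an input protocol, on [start, end) minutes.

    ``kind='step'`` holds ``u`` constant at ``value``;
    ``kind='exp'`` relaxes from ``value`` toward the protocol baseline
    with time constant ``tau`` minutes: u(t) = b + (value-b)*exp(-(t-start)/tau).
    """

    start: float
    end: float
    value: float
    kind: str = "step"
    tau: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start) and np.isfinite(self.end) and self.start < self.end):
            raise ConfigurationError(f"segment needs finite start < end, got [{self.start}, {self.end})")
        if self.value < 0:
            raise ConfigurationError(f"input value must be non-negative, got {self.value}")
        if self.kind not in ("step", "exp"):
            raise ConfigurationError(f"unknown segment kind {self.kind!r}")
        if self.kind == "exp" and not (self.tau and self.tau > 0):
            raise ConfigurationError("exponential segment requires a positive tau")


@dataclass(frozen=True)
class InputProtocol:
    """Piecewise stress input u(t); ``baseline`` outside all segments.

    Segments must not overlap.  Evaluation is right-continuous at
    segment boundaries (the value at a boundary belongs to the segment
    that starts there).
    """

    segments: tuple[Segment, ...] = ()
    baseline: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ConfigurationError(f"baseline input must be non-negative, got {self.baseline}")
        segs = tuple(sorted(self.segments, key=lambda s: s.start))
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ConfigurationError(
                    f"overlapping input segments: [{a.start},{a.end}) and [{b.start},{b.end})"
                )
        object.__setattr__(self, "segments", segs)

    # -- constructors ------------------------------------------------------
    @classmethod
    def constant(cls, u: float = 1.0) -> "InputProtocol":
        return cls(segments=(), baseline=u)

    @classmethod
    def step_pulse(
        cls,
        u: float,
        start: float,
        end: float,
        baseline: float = 1.0,
        unit: str = "min",
    ) -> "InputProtocol":
        """Single rectangular pulse of height ``u`` on [start, end)."""
        return cls(
            segments=(Segment(to_minutes(start, unit), to_minutes(end, unit), u),),
            baseline=baseline,
        )

    @classmethod
    def from_dict(cls, data: Mapping) -> "InputProtocol":
        segs = []
        for seg in data.get("segments", ()):
            unit = seg.get("unit", "min")
            tau = seg.get("tau")
            segs.append(
                Segment(
                    start=to_minutes(seg["start"], unit),
                    end=to_minutes(seg["end"], unit),
                    value=float(seg.get("u", seg.get("value", 1.0))),
                    kind=seg.get("kind", "step"),
                    tau=to_minutes(tau, unit) if tau is not None else None,
                )
            )
        return cls(segments=tuple(segs), baseline=float(data.get("baseline", 1.0)))

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "segments": [
                {
                    "start": s.start,
                    "end": s.end,
                    "u": s.value,
                    "kind": s.kind,
                    **({"tau": s.tau} if s.tau is not None else {}),
                }
                for s in self.segments
            ],
        }

    # -- queries -----------------------------------------------------------
    def breakpoints(self) -> list[float]:
        """Times at which u(t) may jump (integration restart points)."""
        pts: set[float] = set()
        for s in self.segments:
            pts.update((s.start, s.end))
        return sorted(pts)

    def end_of_last_offbaseline(self) -> float | None:
        """End time of the last step segment whose value differs from baseline.

        Used by the analysis layer as the stress-end anchor; None for a
        purely basal protocol.
        """
        ends = []
        for s in self.segments:
            if s.kind == "step" and s.value != self.baseline:
                ends.append(s.end)
            elif s.kind == "exp":
                # an exponential tail models lingering input *after* the
                # imposed stress ends, so the anchor is its start
                ends.append(s.start)
        return max(ends) if ends else None


def input_at(protocol: InputProtocol, t: float) -> float:
    """Evaluate u(t); right-continuous at segment boundaries."""
    for s in protocol.segments:
        if s.start <= t < s.end:
            if s.kind == "step":
                return s.value
            return protocol.baseline + (s.value - protocol.baseline) * float(
                np.exp(-(t - s.start) / s.tau)
            )
    return protocol.baseline


@dataclass(frozen=True)
class CRHTestSpec:
    """One CRH stimulation test: a boxcar dose of exogenous CRH.

    A dose ``D`` is infused on the half-open interval
    ``(t_inj, t_inj + W]`` minutes; hormones are observed for ``window``
    minutes after injection.  Defaults reproduce the calibration that
    matches mean test responses of non-stressed controls (D=20, W=30).
    """

    t_inj: float = 0.0
    D: float = 20.0
    W: float = 30.0
    wCRHE: float = 0.016
    window: float = 180.0

    def __post_init__(self) -> None:
        if not (self.D >= 0 and self.W > 0):
            # D = 0 is allowed as the null probe (no perturbation)
            raise ConfigurationError(f"dose D and width W must be positive, got D={self.D}, W={self.W}")
        if self.window < self.W:
            raise ConfigurationError(
                f"observation window ({self.window} min) must cover the bolus width ({self.W} min)"
            )
        if self.wCRHE <= 0:
            raise ConfigurationError(f"wCRHE must be positive, got {self.wCRHE}")

    def breakpoints(self) -> list[float]:
        return [self.t_inj, self.t_inj + self.W]

    def to_dict(self) -> dict:
        return {"t_inj": self.t_inj, "D": self.D, "W": self.W, "wCRHE": self.wCRHE, "window": self.window}

    @classmethod
    def from_dict(cls, data: Mapping) -> "CRHTestSpec":
        return cls(**{k: float(v) for k, v in data.items()})


def crh_dose_at(spec: CRHTestSpec, t: float) -> float:
    """Boxcar dose: D on (t_inj, t_inj + W], zero elsewhere."""
    return spec.D if spec.t_inj < t <= spec.t_inj + spec.W else 0.0


def prolonged_stress_protocol(
    u_stress: float = 4.0,
    duration_days: float = 90.0,
    start_day: float = 0.0,
    baseline: float = 1.0,
    exponential_tail_tau_days: float | None = None,
    tail_days: float = 3650.0,
) -> InputProtocol:
    """The prolonged-stress scenario: u = ``u_stress`` for ``duration_days``.

    With ``exponential_tail_tau_days`` set, the input does not step back
    to baseline at stress end but decays exponentially toward it (the
    slow-input alternative mechanism); the tail segment spans
    ``tail_days``.
    """
    t0 = start_day * MINUTES_PER_DAY
    t1 = (start_day + duration_days) * MINUTES_PER_DAY
    segs = [Segment(t0, t1, u_stress)]
    if exponential_tail_tau_days is not None:
        segs.append(
            Segment(
                t1,
                t1 + tail_days * MINUTES_PER_DAY,
                u_stress,
                kind="exp",
                tau=exponential_tail_tau_days * MINUTES_PER_DAY,
            )
        )
    return InputProtocol(segments=tuple(segs), baseline=baseline)
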