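"""Cardiovascular drivers of glymphatic flow.

Bulk interstitial-fluid (ISF) velocity in the perivascular pathway is
driven by arterial pulsations, so it scales with heart rate, and it is
attenuated as the arterial wall stiffens and transmits those pulsations
less effectively.  The model composes these as

    v(t) = v0 * (HR / 60) * compliance(S(t))

where S(t) is a dimensionless wall-stiffness multiple (1 = young vessel)
that may ramp up exponentially over the simulated lifespan.  Three
compliance laws are provided because the stiffness-to-velocity mapping is
not experimentally constrained:

``inverse``
    compliance = 1/S — pulsation transmission inversely proportional to
    stiffness; the default for heart-rate and ApoE scenarios.
``linear_floor``
    compliance falls linearly from 1 to 0 as S rises from 1 to its
    endpoint fold change.
``flow_off``
    convective inflow to the perivascular space is shut off entirely;
    used by the vessel-stiffening scenarios to represent a functionally
    abolished glymphatic drive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvariantError, ParameterError
from .params import ModelParams

COMPLIANCE_LAWS = ("inverse", "linear_floor", "flow_off")


@dataclass(frozen=True, slots=True)
class StiffnessProfile:
    """Exponential vessel-stiffening ramp: S(0)=1 up to S(duration)=fold_change."""

    fold_change: float = 2.0
    duration: float = 18250.0  # days
    shape: str = "exponential"
    compliance_law: str = "inverse"

    def __post_init__(self) -> None:
        if self.fold_change < 1.0:
            raise ParameterError("fold_change must be >= 1")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.shape != "exponential":
            raise ParameterError(f"unknown stiffness shape {self.shape!r}")
        if self.compliance_law not in COMPLIANCE_LAWS:
            raise ParameterError(
                f"unknown compliance law {self.compliance_law!r}; "
                f"expected one of {COMPLIANCE_LAWS}"
            )


@dataclass(frozen=True, slots=True)
class Physiology:
    """Heart rate, vessel stiffening and ApoE allele for one simulation arm."""

    heart_rate: float = 60.0   # beats/min
    hr_ref: float = 60.0       # reference heart rate, beats/min
    stiffness: StiffnessProfile | None = None
    apoe: str = "E3"

    def __post_init__(self) -> None:
        if not 30.0 <= self.heart_rate <= 200.0:
            raise ParameterError(
                f"heart_rate {self.heart_rate} outside the physiological "
                "range [30, 200] beats/min"
            )
        if self.hr_ref <= 0:
            raise ParameterError("hr_ref must be > 0")


def stiffness_at(t: float, profile: StiffnessProfile | None) -> float:
    """Wall stiffness multiple S(t): exponential ramp from 1 to fold_change
    over the profile duration, constant thereafter.  No profile means S=1."""
    if t < 0:
        raise ParameterError("t must be >= 0")
    if profile is None:
        return 1.0
    frac = min(t, profile.duration) / profile.duration
    return math.exp(math.log(profile.fold_change) * frac)


def compliance_factor(S: float, law: str, fold_change: float) -> float:
    """Fraction of the pulsatile drive transmitted at stiffness S, in [0, 1]."""
    if S < 1.0:
        raise ParameterError(f"stiffness S must be >= 1, got {S}")
    if law == "inverse":
        return 1.0 / S
    if law == "linear_floor":
        if fold_change <= 1.0:
            return 1.0
        return max(0.0, (fold_change - S) / (fold_change - 1.0))
    if law == "flow_off":
        return 0.0
    raise ParameterError(f"unknown compliance law {law!r}")


def isf_velocity(t: float, phys: Physiology, params: ModelParams) -> float:
    """Bulk ISF velocity (mm/day) at day t: linear in heart rate, attenuated
    by the stiffness profile's compliance law."""
    if t < 0:
        raise ParameterError("t must be >= 0")
    factor = 1.0
    if phys.stiffness is not None:
        S = stiffness_at(t, phys.stiffness)
        factor = compliance_factor(
            S, phys.stiffness.compliance_law, phys.stiffness.fold_change
        )
    return params.v0 * (phys.heart_rate / phys.hr_ref) * factor


def lrp_fraction(LRP: float, LRP0: float) -> float:
    """Surviving fraction of the LRP-1 receptor pool, in [0, 1]."""
    if LRP0 <= 0:
        raise ParameterError("LRP0 must be > 0")
    if LRP < 0:
        raise InvariantError("LRP pool is negative")
    if LRP > LRP0 * (1.0 + 1e-12):
        raise InvariantError(f"LRP pool {LRP} exceeds LRP0 {LRP0}")
    return min(LRP / LRP0, 1.0)
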