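"""Decision factor, global hypoxemic risk, and the correction procedures.

The global hypoxemic risk couples the two concurrent inferences as

    RG(RT, RE) = RT * f(RT, RE) / 10,   RT, RE in [10, 100], RG capped at 100

where the *decision factor* f weights the expert judgment by the technical
evidence. The surface is piecewise in RT:

* exponential zone (RT <= 50):  f = f1(RT)^(RE - f2(RT)) + 10, so that a
  reassuring technical picture demands a fast-growing expert contribution
  before the global risk rises;
* logarithmic zone (RT > 50):   f = f3(RT) * ln(RE) + f4(RT), so that an
  alarming technical picture produces high global risk already at moderate
  expert risk.

The coefficient functions f1..f4 are fixed fitted constants of the model:

    f1(RT) = -0.0015 RT + 1.1391
    f2(RT) = -0.0085 RT^2 + 0.5092 RT + 57.247
    f3(RT) = 215.3 RT^-1.005
    f4(RT) = -0.0048 RT + 0.7849

Three expert corrections are supported: a linear-growth override of the
exponential zone, a security (confidence) division in the logarithmic zone,
and a ramp that replaces the surface between two technical-risk bounds by a
linear interpolation across the zone boundary. When several risk values are
available the highest prevails.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .risk import RISK_CEIL, RISK_FLOOR, RiskPair

logger = logging.getLogger(__name__)

__all__ = [
    "DomainError",
    "ZoneError",
    "SpecificationError",
    "DecisionFactor",
    "ExponentialCorrectionSpec",
    "SecurityCorrectionSpec",
    "RampCorrectionSpec",
    "GlobalRiskResult",
    "coefficient_f1",
    "coefficient_f2",
    "coefficient_f3",
    "coefficient_f4",
    "decision_factor",
    "global_risk",
    "correct_exponential",
    "correct_security",
    "correct_ramp",
    "finalize",
    "assess",
    "export_surface",
]

#: RT value at and below which the exponential branch applies.
ZONE_BOUNDARY = 50.0

#: Maximum global risk, whatever the decision factor.
RG_CAP = 100.0


class DomainError(ValueError):
    """A risk argument lies outside [10, 100]."""


class ZoneError(ValueError):
    """A correction was requested outside the zone it is defined on."""


class SpecificationError(ValueError):
    """A correction specification violates its stated constraints."""


def _check_domain(value: float, name: str) -> float:
    value = float(value)
    if not (RISK_FLOOR <= value <= RISK_CEIL) or not math.isfinite(value):
        raise DomainError(f"{name} = {value} outside [{RISK_FLOOR}, {RISK_CEIL}]")
    return value


def coefficient_f1(rt: float) -> float:
    """Base of the exponential branch; > 1 throughout the exponential zone."""
    rt = _check_domain(rt, "RT")
    return -0.0015 * rt + 1.1391


def coefficient_f2(rt: float) -> float:
    """Expert-risk offset of the exponential branch."""
    rt = _check_domain(rt, "RT")
    return -0.0085 * rt**2 + 0.5092 * rt + 57.247


def coefficient_f3(rt: float) -> float:
    """Amplitude of the logarithmic branch (power law in RT)."""
    rt = _check_domain(rt, "RT")
    return 215.3 * rt**-1.005


def coefficient_f4(rt: float) -> float:
    """Intercept of the logarithmic branch."""
    rt = _check_domain(rt, "RT")
    return -0.0048 * rt + 0.7849


Zone = Literal["exponential", "logarithmic"]


@dataclass(frozen=True)
class DecisionFactor:
    """A decision-factor value, its zone, and any correction applied."""

    value: float
    zone: Zone
    corrected: bool = False
    correction_kind: Literal["linear_growth", "security"] | None = None

    def __post_init__(self) -> None:
        if self.value <= 0.0:
            raise SpecificationError(f"decision factor must be positive, got {self.value}")


def decision_factor(rt: float, re: float) -> DecisionFactor:
    """Evaluate f(RT, RE) on the branch owned by RT (boundary at RT = 50)."""
    rt = _check_domain(rt, "RT")
    re = _check_domain(re, "RE")
    if rt <= ZONE_BOUNDARY:
        value = coefficient_f1(rt) ** (re - coefficient_f2(rt)) + 10.0
        return DecisionFactor(value=value, zone="exponential")
    value = coefficient_f3(rt) * math.log(re) + coefficient_f4(rt)
    return DecisionFactor(value=value, zone="logarithmic")


def _rg_from_factor(rt: float, f_value: float) -> float:
    return min(RG_CAP, rt * f_value / 10.0)


@dataclass(frozen=True)
class GlobalRiskResult:
    """Outcome of a global-risk assessment, corrected or not.

    ``rg_final`` is the maximum of the uncorrected value and every corrected
    value computed, capped at 100 — when corrections disagree the highest
    risk prevails.
    """

    risk_pair: RiskPair
    factor: DecisionFactor
    rg_uncorrected: float
    rg_corrected: dict[str, float] = field(default_factory=dict)
    corrections_applied: tuple[str, ...] = ()

    @property
    def rg_final(self) -> float:
        return min(RG_CAP, max([self.rg_uncorrected, *self.rg_corrected.values()]))


def global_risk(rt: float, re: float) -> GlobalRiskResult:
    """Uncorrected RG = RT * f(RT, RE) / 10, capped at 100.

    At RT = 10 the global risk equals the decision factor exactly: the
    objective data do not determine a decision and the expert side carries
    the assessment alone.
    """
    factor = decision_factor(rt, re)
    return GlobalRiskResult(
        risk_pair=RiskPair(technical=rt, expert=re),
        factor=factor,
        rg_uncorrected=_rg_from_factor(rt, factor.value),
    )


# -- corrections ----------------------------------------------------------


@dataclass(frozen=True)
class ExponentialCorrectionSpec:
    """Linear-growth override of the exponential zone.

    From ``re_anchor`` upward the factor follows a straight line of slope
    ``rate`` instead of the exponential. The legal slope bracket at a given
    RT is ``[f(RT, anchor+1) - f(RT, anchor),
    (f(RT, 100) - f(RT, anchor)) / (100 - anchor)]`` — from the exponential's
    own initial unit-step growth up to the chord to RE = 100. ``rate`` may
    be the string ``"max"`` or ``"min"`` to select a bracket endpoint.
    """

    re_anchor: float = 30.0
    rate: float | Literal["max", "min"] = "max"

    def __post_init__(self) -> None:
        if not (RISK_FLOOR <= self.re_anchor < RISK_CEIL):
            raise SpecificationError(
                f"anchor {self.re_anchor} outside [10, 100)"
            )
        if isinstance(self.rate, str) and self.rate not in ("max", "min"):
            raise SpecificationError(f"rate must be numeric, 'max' or 'min'")

    def rate_bracket(self, rt: float) -> tuple[float, float]:
        a = self.re_anchor
        f_a = decision_factor(rt, a).value
        lo = decision_factor(rt, min(a + 1.0, RISK_CEIL)).value - f_a
        hi = (decision_factor(rt, RISK_CEIL).value - f_a) / (RISK_CEIL - a)
        return lo, hi

    def resolve_rate(self, rt: float) -> float:
        lo, hi = self.rate_bracket(rt)
        if self.rate == "max":
            return hi
        if self.rate == "min":
            return lo
        rate = float(self.rate)
        if not (lo - 1e-9 <= rate <= hi + 1e-9):
            raise SpecificationError(
                f"rate {rate} outside legal bracket [{lo:.6g}, {hi:.6g}] at RT={rt}"
            )
        return rate


def correct_exponential(
    rt: float, re: float, spec: ExponentialCorrectionSpec
) -> DecisionFactor:
    """First-level correction: f_corrected = f(RT, anchor) + rate * (RE - anchor)."""
    rt = _check_domain(rt, "RT")
    re = _check_domain(re, "RE")
    if rt > ZONE_BOUNDARY:
        raise ZoneError(f"exponential correction undefined for RT = {rt} > 50")
    if re < spec.re_anchor:
        raise DomainError(
            f"RE = {re} below correction anchor {spec.re_anchor}"
        )
    rate = spec.resolve_rate(rt)
    f_a = decision_factor(rt, spec.re_anchor).value
    return DecisionFactor(
        value=f_a + rate * (re - spec.re_anchor),
        zone="exponential",
        corrected=True,
        correction_kind="linear_growth",
    )


@dataclass(frozen=True)
class SecurityCorrectionSpec:
    """Confidence correction for the logarithmic zone.

    When the global risk falls below the technical risk by more than
    ``trigger_threshold`` percent, the expert is asked how sure she is; the
    factor is divided by the stated security fraction, so full confidence
    (100 %) leaves it unchanged and lower confidence raises the global risk
    back toward the technical alert.
    """

    security: float = 100.0
    trigger_threshold: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 < self.security <= 100.0):
            raise SpecificationError(f"security {self.security}% outside (0, 100]")
        if self.trigger_threshold <= 0.0:
            raise SpecificationError("trigger threshold must be positive")


def correct_security(
    rt: float, re: float, spec: SecurityCorrectionSpec
) -> DecisionFactor:
    """Apply the security correction; returns the uncorrected factor untriggered."""
    rt = _check_domain(rt, "RT")
    re = _check_domain(re, "RE")
    if rt <= ZONE_BOUNDARY:
        raise ZoneError(f"security correction undefined for RT = {rt} <= 50")
    factor = decision_factor(rt, re)
    rg = _rg_from_factor(rt, factor.value)
    variation = 100.0 * (rt - rg) / rt
    if variation <= spec.trigger_threshold:
        return factor
    return DecisionFactor(
        value=factor.value / (spec.security / 100.0),
        zone="logarithmic",
        corrected=True,
        correction_kind="security",
    )


@dataclass(frozen=True)
class RampCorrectionSpec:
    """Second-level ramp across the exponential-logarithmic transition.

    Between ``rt1`` and ``rt2`` (which must straddle the RT = 50 boundary
    and stay within [25, 75]) the surface is replaced by the linear
    interpolation, at fixed RE, between its values at the interval ends.
    """

    rt1: float = 40.0
    rt2: float = 70.0

    def __post_init__(self) -> None:
        if not (25.0 <= self.rt1 < ZONE_BOUNDARY < self.rt2 <= 75.0):
            raise SpecificationError(
                f"ramp interval [{self.rt1}, {self.rt2}] must satisfy "
                "25 <= rt1 < 50 < rt2 <= 75"
            )


def correct_ramp(rt: float, re: float, spec: RampCorrectionSpec) -> float:
    """Ramp-corrected RG for RT inside [rt1, rt2] at fixed RE."""
    rt = _check_domain(rt, "RT")
    re = _check_domain(re, "RE")
    if not (spec.rt1 <= rt <= spec.rt2):
        raise ZoneError(
            f"RT = {rt} outside ramp interval [{spec.rt1}, {spec.rt2}]"
        )
    rg1 = global_risk(spec.rt1, re).rg_uncorrected
    rg2 = global_risk(spec.rt2, re).rg_uncorrected
    return min(
        RG_CAP, rg1 + (rg2 - rg1) / (spec.rt2 - spec.rt1) * (rt - spec.rt1)
    )


def finalize(values: Iterable[float]) -> float:
    """Highest of the available global-risk values, capped at 100."""
    values = list(values)
    if not values:
        raise ValueError("no global-risk values to finalize")
    return min(RG_CAP, max(values))


def assess(
    rt: float,
    re: float,
    *,
    exponential: ExponentialCorrectionSpec | None = None,
    security: SecurityCorrectionSpec | None = None,
    ramp: RampCorrectionSpec | None = None,
) -> GlobalRiskResult:
    """Full assessment of one (RT, RE) pair with optional corrections.

    Each correction is applied only inside its zone of validity; every
    applied correction is logged (the corrections are an expert override and
    leave an audit trail). The final risk is the maximum over all values.
    """
    base = global_risk(rt, re)
    corrected: dict[str, float] = {}
    applied: list[str] = []
    factor = base.factor

    if exponential is not None and rt <= ZONE_BOUNDARY and re >= exponential.re_anchor:
        fc = correct_exponential(rt, re, exponential)
        corrected["linear_growth"] = _rg_from_factor(rt, fc.value)
        applied.append("linear_growth")
        factor = fc
        logger.info(
            "linear-growth correction at (RT=%.2f, RE=%.2f): f %.4f -> %.4f, RG %.2f",
            rt, re, base.factor.value, fc.value, corrected["linear_growth"],
        )
    if security is not None and rt > ZONE_BOUNDARY:
        fc = correct_security(rt, re, security)
        if fc.corrected:
            corrected["security"] = _rg_from_factor(rt, fc.value)
            applied.append("security")
            factor = fc
            logger.info(
                "security correction at (RT=%.2f, RE=%.2f): f %.4f -> %.4f, RG %.2f",
                rt, re, base.factor.value, fc.value, corrected["security"],
            )
    if ramp is not None and ramp.rt1 <= rt <= ramp.rt2:
        corrected["ramp"] = correct_ramp(rt, re, ramp)
        applied.append("ramp")
        logger.info(
            "ramp correction at (RT=%.2f, RE=%.2f): RG %.2f -> %.2f",
            rt, re, base.rg_uncorrected, corrected["ramp"],
        )

    return GlobalRiskResult(
        risk_pair=base.risk_pair,
        factor=factor,
        rg_uncorrected=base.rg_uncorrected,
        rg_corrected=corrected,
        corrections_applied=tuple(applied),
    )


def export_surface(
    rt_grid: Sequence[float],
    re_grid: Sequence[float],
    ramp: RampCorrectionSpec | None = None,
) -> np.ndarray:
    """RG evaluated on the outer grid (RT rows x RE columns), capped at 100.

    With a ramp specification the surface is the corrected one inside
    [rt1, rt2] and untouched outside.
    """
    rt_grid = np.asarray(rt_grid, dtype=float)
    re_grid = np.asarray(re_grid, dtype=float)
    out = np.empty((rt_grid.size, re_grid.size))
    for i, rt in enumerate(rt_grid):
        for j, re in enumerate(re_grid):
            if ramp is not None and ramp.rt1 <= rt <= ramp.rt2:
                out[i, j] = correct_ramp(rt, re, ramp)
            else:
                out[i, j] = global_risk(rt, re).rg_uncorrected
    return out
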