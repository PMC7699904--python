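"""Three-state alert classification and the binary emergency indicator.

Global risk maps to Wait / Warning / Emergency through two thresholds
(defaults 60 and 80). Intervals are half-open on the right — Wait on
[0, 60), Warning on [60, 80), Emergency on [80, 100] — consistent with the
evaluation convention that an emergency is declared for risk greater than
or equal to the limit. For the diagnostic evaluation the warning state
counts as part of the (binary) emergency class, i.e. the default binary
limit equals the Wait upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class AlertLevel(str, Enum):
    WAIT = "Wait"
    WARNING = "Warning"
    EMERGENCY = "Emergency"


@dataclass(frozen=True)
class AlertThresholds:
    """Upper bounds (risk units) of the Wait and Warning bands."""

    wait_upper: float = 60.0
    warning_upper: float = 80.0

    def __post_init__(self) -> None:
        if not (0.0 < self.wait_upper < self.warning_upper <= 100.0):
            raise ValueError(
                f"thresholds must satisfy 0 < wait_upper < warning_upper <= 100, "
                f"got ({self.wait_upper}, {self.warning_upper})"
            )


DEFAULT_THRESHOLDS = AlertThresholds()


def classify_alert(
    rg: float, thresholds: AlertThresholds = DEFAULT_THRESHOLDS
) -> AlertLevel:
    """Map a global risk value in [0, 100] to its alert level."""
    if not (0.0 <= rg <= 100.0):
        raise ValueError(f"global risk {rg} outside [0, 100]")
    if rg < thresholds.wait_upper:
        return AlertLevel.WAIT
    if rg < thresholds.warning_upper:
        return AlertLevel.WARNING
    return AlertLevel.EMERGENCY


def binarize_emergency(rg: float, limit: float = 60.0) -> bool:
    """True iff ``rg >= limit``: the binary emergency indicator."""
    if not (0.0 <= rg <= 100.0):
        raise ValueError(f"global risk {rg} outside [0, 100]")
    if not (0.0 < limit <= 100.0):
        raise ValueError(f"limit {limit} outside (0, 100]")
    return rg >= limit
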