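"""Diagnostic-accuracy evaluation of recommended versus actual states.

The positive class is the (binary) emergency state. From the confusion
counts the standard ratios are computed on the percent scale —

    accuracy    = (tp + tn) / total
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    P(false negative) = 1 - sensitivity
    P(false positive) = 1 - specificity

together with the Youden index (sensitivity + specificity - 1, fraction
scale) and Cohen's kappa ((po - pc) / (1 - pc), with the chance agreement pc
taken from the marginal products). A metric whose denominator vanishes is
surfaced as an explicit undefined signal, never silently reported as zero.

``sweep`` re-binarizes a cohort's global-risk values over a grid of
emergency limits (default 1..100, unit step) and reports the per-limit
metrics and where they are maximal. Because re-binarization only changes at
observed risk values, maxima typically occur on plateaus of limits; the
full maximizing set is reported alongside a scalar argmax tie-broken toward
the lowest limit (earlier alerts are safer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alerts import binarize_emergency

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "EvaluationReport",
    "SweepCurve",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "false_fractions",
    "youden",
    "cohen_kappa",
    "evaluate_cohort",
    "sweep",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is empty (no members of the required class)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    recommended: Sequence[bool], actual: Sequence[bool]
) -> ConfusionCounts:
    """Count the four outcomes; positive class = emergency."""
    if len(recommended) != len(actual):
        raise ValueError(
            f"length mismatch: {len(recommended)} recommended vs {len(actual)} actual"
        )
    if not len(recommended):
        raise ValueError("empty cohort")
    rec = np.asarray(recommended, dtype=bool)
    act = np.asarray(actual, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(rec & act)),
        tn=int(np.sum(~rec & ~act)),
        fp=int(np.sum(rec & ~act)),
        fn=int(np.sum(~rec & act)),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """Fraction of correctly classified cases, in percent."""
    return 100.0 * (counts.tp + counts.tn) / counts.total


def sensitivity(counts: ConfusionCounts) -> float:
    """Detection rate of the emergency class, in percent."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("no actual-positive cases; sensitivity undefined")
    return 100.0 * counts.tp / (counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    """Detection rate of the non-emergency class, in percent."""
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("no actual-negative cases; specificity undefined")
    return 100.0 * counts.tn / (counts.tn + counts.fp)


def false_fractions(counts: ConfusionCounts) -> tuple[float, float]:
    """(P(false negative), P(false positive)) in percent."""
    return 100.0 - sensitivity(counts), 100.0 - specificity(counts)


def youden(counts: ConfusionCounts) -> float:
    """Youden index, sensitivity + specificity - 1 on the fraction scale."""
    return sensitivity(counts) / 100.0 + specificity(counts) / 100.0 - 1.0


def cohen_kappa(
    recommended: Sequence[bool], actual: Sequence[bool]
) -> float:
    """Chance-corrected agreement between recommendation and actual state."""
    counts = confusion(recommended, actual)
    n = counts.total
    po = (counts.tp + counts.tn) / n
    pc = (
        (counts.tp + counts.fp) * (counts.tp + counts.fn)
        + (counts.fn + counts.tn) * (counts.fp + counts.tn)
    ) / n**2
    if pc == 1.0:
        raise UndefinedMetricError(
            "both raters constant and equal; kappa undefined"
        )
    return (po - pc) / (1.0 - pc)


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and all scalar metrics at one emergency limit."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    p_false_neg: float
    p_false_pos: float
    youden: float
    kappa: float
    limit: float

    def to_dict(self) -> dict:
        return {
            "limit": self.limit,
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "p_false_negative_pct": self.p_false_neg,
            "p_false_positive_pct": self.p_false_pos,
            "youden": self.youden,
            "kappa": self.kappa,
        }


def evaluate_cohort(
    rg_values: Sequence[float],
    actual: Sequence[bool],
    limit: float = 60.0,
) -> EvaluationReport:
    """Binarize the cohort's global risks at ``limit`` and compute all metrics."""
    recommended = [binarize_emergency(rg, limit) for rg in rg_values]
    counts = confusion(recommended, actual)
    pfn, pfp = false_fractions(counts)
    return EvaluationReport(
        counts=counts,
        accuracy=accuracy(counts),
        sensitivity=sensitivity(counts),
        specificity=specificity(counts),
        p_false_neg=pfn,
        p_false_pos=pfp,
        youden=youden(counts),
        kappa=cohen_kappa(recommended, actual),
        limit=limit,
    )


@dataclass(frozen=True)
class SweepCurve:
    """Per-limit metrics over an ascending grid of emergency limits.

    Undefined points are NaN. ``youden_argmax_set`` / ``kappa_argmax_set``
    are the full sets of limits achieving the maximum; the scalar
    ``youden_argmax`` / ``kappa_argmax`` tie-break toward the lowest limit.
    """

    limits: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden: np.ndarray
    kappa: np.ndarray
    youden_argmax_set: tuple[float, ...] = field(default=())
    kappa_argmax_set: tuple[float, ...] = field(default=())

    @property
    def youden_argmax(self) -> float:
        return self.youden_argmax_set[0]

    @property
    def kappa_argmax(self) -> float:
        return self.kappa_argmax_set[0]

    def at(self, limit: float) -> dict[str, float]:
        idx = int(np.argmin(np.abs(self.limits - limit)))
        if not math.isclose(self.limits[idx], limit):
            raise KeyError(f"limit {limit} not on the sweep grid")
        return {
            "limit": float(self.limits[idx]),
            "sensitivity_pct": float(self.sensitivity[idx]),
            "specificity_pct": float(self.specificity[idx]),
            "youden": float(self.youden[idx]),
            "kappa": float(self.kappa[idx]),
        }


def _argmax_plateau(limits: np.ndarray, values: np.ndarray) -> tuple[float, ...]:
    if np.all(np.isnan(values)):
        return ()
    best = np.nanmax(values)
    mask = np.isclose(values, best, rtol=0.0, atol=1e-12)
    return tuple(float(x) for x in limits[mask])


def sweep(
    rg_values: Sequence[float],
    actual: Sequence[bool],
    limits: Sequence[float] | None = None,
) -> SweepCurve:
    """Metrics versus emergency limit over an ascending grid of limits."""
    if limits is None:
        limits = np.arange(1.0, 101.0)
    limits = np.asarray(limits, dtype=float)
    if limits.size == 0 or np.any(np.diff(limits) <= 0):
        raise ValueError("limits must be non-empty and strictly ascending")
    if np.any(limits <= 0.0) or np.any(limits > 100.0):
        raise ValueError("limits must lie in (0, 100]")

    sens = np.full(limits.shape, np.nan)
    spec = np.full(limits.shape, np.nan)
    you = np.full(limits.shape, np.nan)
    kap = np.full(limits.shape, np.nan)
    for i, limit in enumerate(limits):
        recommended = [binarize_emergency(rg, limit) for rg in rg_values]
        counts = confusion(recommended, actual)
        try:
            sens[i] = sensitivity(counts)
            spec[i] = specificity(counts)
            you[i] = sens[i] / 100.0 + spec[i] / 100.0 - 1.0
        except UndefinedMetricError:
            pass
        try:
            kap[i] = cohen_kappa(recommended, actual)
        except UndefinedMetricError:
            pass
    return SweepCurve(
        limits=limits,
        sensitivity=sens,
        specificity=spec,
        youden=you,
        kappa=kap,
        youden_argmax_set=_argmax_plateau(limits, you),
        kappa_argmax_set=_argmax_plateau(limits, kap),
    )
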