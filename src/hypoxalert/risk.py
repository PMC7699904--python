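"""Technical- and expert-risk computations and configuration validation.

The technical risk RT is inferred from a pulse-oximeter/vitals reading
(SpO2 %, heart rate bpm, temperature degC); the expert risk RE from three
0-10 assessments issued by the healthcare team (sensor-measurement
assessment, history assessment, other-factors assessment). Both are crisp
outputs of Mamdani systems, clamped to the operational risk scale [10, 100]:
an RT of 10 means the objective data do not determine a decision and the
global risk reduces to the expert side alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from . import defaults
from .fuzzy import (
    ConfigurationError,
    FuzzyVariable,
    InferenceSystemConfig,
    TrapezoidLabel,
    infer,
    load_config,
)

__all__ = [
    "RISK_FLOOR",
    "RISK_CEIL",
    "SensorReading",
    "ExpertAssessment",
    "RiskPair",
    "Finding",
    "technical_risk",
    "expert_risk",
    "validate_config",
    "default_technical_config",
    "default_expert_config",
]

#: Operational range of both risks ("actual range is 10-100").
RISK_FLOOR = 10.0
RISK_CEIL = 100.0

_SENSOR_RANGES = {
    "spo2": (70.0, 100.0),
    "heart_rate": (15.0, 180.0),
    "temperature": (33.0, 41.0),
}


@dataclass(frozen=True)
class SensorReading:
    """One vitals sample: SpO2 in %, heart rate in bpm, temperature in degC."""

    spo2: float
    heart_rate: float
    temperature: float
    timestamp: str | None = None

    def __post_init__(self) -> None:
        for name in ("spo2", "heart_rate", "temperature"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    def out_of_range(self) -> list[str]:
        """Names of fields outside the modelled sensor ranges.

        Out-of-range values are legal (a pulse-oximeter is only reliable in
        70-100 % but can read below); they are flagged here and clamped by
        the inference engine downstream.
        """
        flags = []
        for name, (lo, hi) in _SENSOR_RANGES.items():
            v = getattr(self, name)
            if v < lo or v > hi:
                flags.append(name)
        return flags

    def as_inputs(self) -> dict[str, float]:
        return {
            "spo2": self.spo2,
            "heart_rate": self.heart_rate,
            "temperature": self.temperature,
        }


@dataclass(frozen=True)
class ExpertAssessment:
    """Three 0-10 expert scores: measurements, history, other risk factors."""

    sensors_score: float
    history_score: float
    other_factors_score: float

    def __post_init__(self) -> None:
        for name in ("sensors_score", "history_score", "other_factors_score"):
            v = getattr(self, name)
            if not (0.0 <= v <= 10.0):
                raise ValueError(f"{name} must be in [0, 10], got {v}")

    def as_inputs(self) -> dict[str, float]:
        return {
            "sensors_score": self.sensors_score,
            "history_score": self.history_score,
            "other_factors_score": self.other_factors_score,
        }


@dataclass(frozen=True)
class RiskPair:
    """The (technical, expert) risk duple, both on [10, 100]."""

    technical: float
    expert: float

    def __post_init__(self) -> None:
        for name in ("technical", "expert"):
            v = getattr(self, name)
            if not (RISK_FLOOR <= v <= RISK_CEIL):
                raise ValueError(f"{name} risk {v} outside [10, 100]")


def _clamp_risk(value: float) -> float:
    return min(max(value, RISK_FLOOR), RISK_CEIL)


def default_technical_config() -> InferenceSystemConfig:
    """The calibrated technical-risk system shipped with the package."""
    return _load_packaged("technical_fis.json")


def default_expert_config() -> InferenceSystemConfig:
    """The calibrated expert-risk system shipped with the package."""
    return _load_packaged("expert_fis.json")


def _load_packaged(filename: str) -> InferenceSystemConfig:
    ref = resources.files("hypoxalert.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return load_config(Path(path))


def technical_risk(
    reading: SensorReading, config: InferenceSystemConfig | None = None
) -> float:
    """Infer RT from a sensor reading, clamped to [10, 100]."""
    cfg = config if config is not None else default_technical_config()
    return _clamp_risk(infer(reading.as_inputs(), cfg))


def expert_risk(
    assessment: ExpertAssessment, config: InferenceSystemConfig | None = None
) -> float:
    """Infer RE from the three expert scores, clamped to [10, 100]."""
    cfg = config if config is not None else default_expert_config()
    return _clamp_risk(infer(assessment.as_inputs(), cfg))


# -- configuration validation ---------------------------------------------


@dataclass(frozen=True)
class Finding:
    """One validation finding: a category and a human-readable message."""

    kind: str
    message: str


def validate_config(
    config: InferenceSystemConfig | Mapping,
    fidelity: str | None = None,
) -> list[Finding]:
    """Collect structural problems in a configuration without raising.

    Checks knot ordering, universe coverage, dangling labels/variables, and
    — when ``fidelity`` is ``"technical"`` or ``"expert"`` — that the
    published rule subset is present or implied by the rule base.
    """
    findings: list[Finding] = []
    if isinstance(config, InferenceSystemConfig):
        cfg = config
    else:
        cfg = _structural_findings(config, findings)
        if cfg is None:
            return findings

    if fidelity is not None:
        printed = {
            "technical": defaults.TECHNICAL_PRINTED_RULES,
            "expert": defaults.EXPERT_PRINTED_RULES,
        }.get(fidelity)
        if printed is None:
            raise ValueError(f"unknown fidelity target {fidelity!r}")
        findings.extend(_fidelity_findings(cfg, printed))
    return findings


def _structural_findings(
    payload: Mapping, findings: list[Finding]
) -> InferenceSystemConfig | None:
    """Validate a raw config dict piecewise, accumulating findings.

    Returns the parsed config when it is fully constructible, else None.
    """
    try:
        input_payloads = list(payload["inputs"])
        var_payloads = input_payloads + [payload["output"]]
    except (KeyError, TypeError):
        findings.append(Finding("structure", "missing 'inputs' or 'output' section"))
        return None

    label_map: dict[str, set[str]] = {}
    for var in var_payloads:
        vname = var.get("name", "<unnamed>")
        label_map[vname] = set()
        lo, hi = var.get("range", (None, None))
        for lab in var.get("labels", []):
            try:
                TrapezoidLabel(lab["name"], tuple(float(k) for k in lab["knots"]))
                label_map[vname].add(lab["name"])
            except (ConfigurationError, KeyError, TypeError, ValueError) as exc:
                findings.append(
                    Finding("knots", f"variable {vname!r}: {exc}")
                )
        if lo is not None and label_map[vname]:
            try:
                parsed = FuzzyVariable(
                    vname,
                    (float(lo), float(hi)),
                    tuple(
                        TrapezoidLabel(
                            lab["name"], tuple(float(k) for k in lab["knots"])
                        )
                        for lab in var["labels"]
                        if lab["name"] in label_map[vname]
                    ),
                )
                if var in input_payloads:  # coverage required for inputs only
                    parsed.check_coverage()
            except ConfigurationError as exc:
                findings.append(Finding("coverage", str(exc)))

    input_names = [v.get("name") for v in payload.get("inputs", [])]
    for i, rule in enumerate(payload.get("rules", [])):
        clause = rule.get("if", {})
        then = rule.get("then")
        out_name = payload["output"].get("name", "<unnamed>")
        if then not in label_map.get(out_name, set()):
            findings.append(
                Finding("dangling", f"rule {i}: consequent {then!r} not an output label")
            )
        for var, spec in clause.items():
            if var not in input_names:
                findings.append(
                    Finding("dangling", f"rule {i}: unknown variable {var!r}")
                )
                continue
            if spec == "*":
                continue
            label = spec[1:] if isinstance(spec, str) and spec.startswith("!") else spec
            if label not in label_map.get(var, set()):
                findings.append(
                    Finding("dangling", f"rule {i}: unknown label {label!r} on {var!r}")
                )

    if findings:
        return None
    try:
        return InferenceSystemConfig.from_dict(payload)
    except ConfigurationError as exc:
        findings.append(Finding("structure", str(exc)))
        return None


def _fidelity_findings(
    cfg: InferenceSystemConfig, printed: list[tuple[dict[str, str], str]]
) -> list[Finding]:
    # Map of fully-specified IS-combinations -> consequent, used to decide
    # whether a printed pattern rule is implied by the explicit rule base.
    combos: dict[tuple[tuple[str, str], ...], str] = {}
    stored: set[tuple[tuple[tuple[str, str, str], ...], str]] = set()
    for rule in cfg.rules:
        key = tuple(
            sorted((a.variable, a.mode, a.label or "") for a in rule.antecedents)
        )
        stored.add((key, rule.consequent_label))
        if all(a.mode == "is" for a in rule.antecedents) and len(
            rule.antecedents
        ) == len(cfg.inputs):
            combo = tuple(sorted((a.variable, a.label) for a in rule.antecedents))
            combos[combo] = rule.consequent_label

    findings = []
    for clause, consequent in printed:
        literal_key = []
        for var in cfg.inputs:
            spec = clause.get(var.name, "*")
            if spec == "*":
                literal_key.append((var.name, "any", ""))
            elif spec.startswith("!"):
                literal_key.append((var.name, "is_not", spec[1:]))
            else:
                literal_key.append((var.name, "is", spec))
        if (tuple(sorted(literal_key)), consequent) in stored:
            continue
        if _pattern_implied(cfg, clause, consequent, combos):
            continue
        findings.append(
            Finding(
                "fidelity",
                f"published rule IF {clause} THEN {consequent} neither present "
                "nor implied by the rule base",
            )
        )
    return findings


def _pattern_implied(
    cfg: InferenceSystemConfig,
    clause: dict[str, str],
    consequent: str,
    combos: dict[tuple[tuple[str, str], ...], str],
) -> bool:
    from itertools import product as _product

    choices = []
    for var in cfg.inputs:
        spec = clause.get(var.name, "*")
        if spec == "*":
            choices.append([(var.name, lab) for lab in var.label_names()])
        elif spec.startswith("!"):
            excluded = spec[1:]
            choices.append(
                [(var.name, lab) for lab in var.label_names() if lab != excluded]
            )
        else:
            choices.append([(var.name, spec)])
    for assignment in _product(*choices):
        if combos.get(tuple(sorted(assignment))) != consequent:
            return False
    return True
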