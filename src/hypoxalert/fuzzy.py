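"""Generic Mamdani fuzzy inference with trapezoidal membership functions.

The engine implements the classical Mamdani pipeline: crisp inputs are
fuzzified through trapezoidal membership functions, rule antecedents are
combined with the AND (minimum) operator — with ``is not`` antecedents using
the standard complement ``1 - membership`` — each rule's consequent set is
truncated at the rule activation (MIN implication), truncated consequents are
aggregated pointwise with the maximum operator, and the aggregated set is
defuzzified by the centroid method on a uniform sample of the output
universe.

Only trapezoidal (including degenerate triangular) membership shapes and
centroid defuzzification are supported; that is the configuration the risk
systems in this package are built on.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "InputError",
    "DegenerateInferenceError",
    "TrapezoidLabel",
    "FuzzyVariable",
    "RuleAntecedent",
    "FuzzyRule",
    "InferenceSystemConfig",
    "evaluate_rule",
    "aggregate_and_defuzzify",
    "infer",
    "load_config",
]


class ConfigurationError(ValueError):
    """An inference-system configuration is malformed or inconsistent."""


class InputError(ValueError):
    """A crisp input required by the rule base is missing or invalid."""


class DegenerateInferenceError(RuntimeError):
    """No rule fired: the aggregated output set is identically zero.

    Returning an arbitrary default risk would be unsafe, so the condition is
    raised instead; well-formed configurations satisfy universe coverage and
    cannot reach this state for in-universe inputs.
    """


@dataclass(frozen=True)
class TrapezoidLabel:
    """One linguistic label with a trapezoidal membership function.

    The four knots ``(a, b, c, d)`` must be ascending; membership is 0
    outside ``[a, d]``, 1 on the plateau ``[b, c]`` and linear on the ramps.
    ``b == c`` degenerates to a triangle.
    """

    name: str
    knots: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.knots) != 4:
            raise ConfigurationError(
                f"label {self.name!r}: expected 4 knots, got {len(self.knots)}"
            )
        a, b, c, d = self.knots
        if not (a <= b <= c <= d):
            raise ConfigurationError(
                f"label {self.name!r}: knots {self.knots} are not ascending"
            )
        if not all(math.isfinite(k) for k in self.knots):
            raise ConfigurationError(f"label {self.name!r}: non-finite knots")

    def membership(self, x: float | np.ndarray) -> float | np.ndarray:
        """Membership degree of ``x``, piecewise linear in ``[0, 1]``."""
        a, b, c, d = self.knots
        x_arr = np.asarray(x, dtype=float)
        y = np.zeros_like(x_arr)
        if b > a:
            rising = (x_arr > a) & (x_arr < b)
            y[rising] = (x_arr[rising] - a) / (b - a)
        plateau = (x_arr >= b) & (x_arr <= c)
        y[plateau] = 1.0
        if d > c:
            falling = (x_arr > c) & (x_arr < d)
            y[falling] = (d - x_arr[falling]) / (d - c)
        return float(y) if np.isscalar(x) or x_arr.ndim == 0 else y


def membership_degree(x: float, label: TrapezoidLabel) -> float:
    """Functional alias for :meth:`TrapezoidLabel.membership`."""
    return label.membership(x)


@dataclass(frozen=True)
class FuzzyVariable:
    """A named variable on a closed universe with an ordered set of labels.

    Input variables must additionally satisfy *coverage* — positive
    membership in at least one label at every universe point, so that
    inference cannot silently dead-end; that is checked when a variable is
    used as an input of an :class:`InferenceSystemConfig` (output variables
    may legitimately leave gaps between consequent sets).
    """

    name: str
    universe: tuple[float, float]
    labels: tuple[TrapezoidLabel, ...]

    _COVERAGE_SAMPLES = 2001

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ConfigurationError(
                f"variable {self.name!r}: empty universe [{lo}, {hi}]"
            )
        if not self.labels:
            raise ConfigurationError(f"variable {self.name!r}: no labels")
        names = [lab.name for lab in self.labels]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"variable {self.name!r}: duplicate labels")
        for lab in self.labels:
            if lab.knots[0] < lo or lab.knots[3] > hi:
                raise ConfigurationError(
                    f"variable {self.name!r}: label {lab.name!r} knots "
                    f"{lab.knots} outside universe [{lo}, {hi}]"
                )

    def check_coverage(self) -> None:
        """Raise unless every universe point has positive membership."""
        lo, hi = self.universe
        grid = np.linspace(lo, hi, self._COVERAGE_SAMPLES)
        cover = np.zeros_like(grid)
        for lab in self.labels:
            cover = np.maximum(cover, lab.membership(grid))
        if np.any(cover <= 0.0):
            gap = grid[cover <= 0.0]
            raise ConfigurationError(
                f"variable {self.name!r}: universe not covered near "
                f"{gap[0]:.4g}..{gap[-1]:.4g}"
            )

    def label(self, name: str) -> TrapezoidLabel:
        for lab in self.labels:
            if lab.name == name:
                return lab
        raise ConfigurationError(
            f"variable {self.name!r}: unknown label {name!r}"
        )

    def label_names(self) -> list[str]:
        return [lab.name for lab in self.labels]


AntecedentMode = Literal["is", "is_not", "any"]


@dataclass(frozen=True)
class RuleAntecedent:
    """One clause of a rule: ``variable IS label``, ``IS NOT``, or don't-care."""

    variable: str
    mode: AntecedentMode = "is"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("is", "is_not", "any"):
            raise ConfigurationError(f"unknown antecedent mode {self.mode!r}")
        if self.mode == "any":
            if self.label is not None:
                raise ConfigurationError("don't-care antecedent carries a label")
        elif self.label is None:
            raise ConfigurationError(
                f"antecedent on {self.variable!r} needs a label"
            )

    def degree(self, x: float, variable: FuzzyVariable) -> float:
        if self.mode == "any":
            return 1.0
        mu = variable.label(self.label).membership(x)
        return 1.0 - mu if self.mode == "is_not" else mu


@dataclass(frozen=True)
class FuzzyRule:
    """Conjunction of antecedents implying one output label."""

    antecedents: tuple[RuleAntecedent, ...]
    consequent_label: str

    def __post_init__(self) -> None:
        if all(a.mode == "any" for a in self.antecedents):
            raise ConfigurationError("rule with only don't-care antecedents")
        variables = [a.variable for a in self.antecedents]
        if len(set(variables)) != len(variables):
            raise ConfigurationError(
                f"rule references a variable twice: {variables}"
            )


@dataclass(frozen=True)
class InferenceSystemConfig:
    """Complete specification of one Mamdani system.

    ``resolution`` is the number of uniformly spaced sample points (endpoints
    inclusive) on the output universe used for centroid defuzzification;
    1001 is ample for the 0.05-unit agreement this package targets.
    """

    inputs: tuple[FuzzyVariable, ...]
    output: FuzzyVariable
    rules: tuple[FuzzyRule, ...]
    resolution: int = 1001
    name: str = ""

    def __post_init__(self) -> None:
        if self.resolution < 101:
            raise ConfigurationError(
                f"resolution {self.resolution} < 101 is too coarse"
            )
        if not self.rules:
            raise ConfigurationError("empty rule base")
        by_name = {v.name: v for v in self.inputs}
        if len(by_name) != len(self.inputs):
            raise ConfigurationError("duplicate input variable names")
        for var in self.inputs:
            var.check_coverage()
        out_labels = set(self.output.label_names())
        for rule in self.rules:
            if rule.consequent_label not in out_labels:
                raise ConfigurationError(
                    f"rule consequent {rule.consequent_label!r} not an output label"
                )
            for ant in rule.antecedents:
                var = by_name.get(ant.variable)
                if var is None:
                    raise ConfigurationError(
                        f"rule references unknown variable {ant.variable!r}"
                    )
                if ant.mode != "any" and ant.label not in var.label_names():
                    raise ConfigurationError(
                        f"rule references unknown label {ant.label!r} "
                        f"on variable {ant.variable!r}"
                    )

    def input(self, name: str) -> FuzzyVariable:
        for var in self.inputs:
            if var.name == name:
                return var
        raise ConfigurationError(f"unknown input variable {name!r}")

    def output_grid(self) -> np.ndarray:
        lo, hi = self.output.universe
        return np.linspace(lo, hi, self.resolution)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def var_dict(v: FuzzyVariable) -> dict:
            return {
                "name": v.name,
                "range": list(v.universe),
                "labels": [
                    {"name": lab.name, "knots": list(lab.knots)}
                    for lab in v.labels
                ],
            }

        def rule_dict(r: FuzzyRule) -> dict:
            clause: dict[str, str] = {}
            for ant in r.antecedents:
                if ant.mode == "any":
                    clause[ant.variable] = "*"
                elif ant.mode == "is_not":
                    clause[ant.variable] = "!" + ant.label
                else:
                    clause[ant.variable] = ant.label
            return {"if": clause, "then": r.consequent_label}

        return {
            "name": self.name,
            "inputs": [var_dict(v) for v in self.inputs],
            "output": var_dict(self.output),
            "rules": [rule_dict(r) for r in self.rules],
            "resolution": self.resolution,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "InferenceSystemConfig":
        try:
            inputs = tuple(_parse_variable(v) for v in payload["inputs"])
            output = _parse_variable(payload["output"])
            rules = tuple(
                _parse_rule(r, [v.name for v in inputs]) for r in payload["rules"]
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed config payload: {exc}") from exc
        return cls(
            inputs=inputs,
            output=output,
            rules=rules,
            resolution=int(payload.get("resolution", 1001)),
            name=str(payload.get("name", "")),
        )


def _parse_variable(payload: Mapping) -> FuzzyVariable:
    labels = tuple(
        TrapezoidLabel(name=lab["name"], knots=tuple(float(k) for k in lab["knots"]))
        for lab in payload["labels"]
    )
    lo, hi = payload["range"]
    return FuzzyVariable(name=payload["name"], universe=(float(lo), float(hi)), labels=labels)


def _parse_rule(payload: Mapping, variable_order: Sequence[str]) -> FuzzyRule:
    clause = payload["if"]
    antecedents = []
    for var in variable_order:
        spec = clause.get(var, "*")
        if spec == "*":
            antecedents.append(RuleAntecedent(variable=var, mode="any"))
        elif isinstance(spec, str) and spec.startswith("!"):
            antecedents.append(
                RuleAntecedent(variable=var, mode="is_not", label=spec[1:])
            )
        else:
            antecedents.append(RuleAntecedent(variable=var, mode="is", label=spec))
    return FuzzyRule(antecedents=tuple(antecedents), consequent_label=payload["then"])


def load_config(path: str | Path) -> InferenceSystemConfig:
    """Load a system configuration from a JSON (or YAML) file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return InferenceSystemConfig.from_dict(payload)


# -- inference ------------------------------------------------------------


def evaluate_rule(
    crisp_inputs: Mapping[str, float],
    rule: FuzzyRule,
    config: InferenceSystemConfig,
) -> float:
    """Activation of ``rule``: min over its non-don't-care antecedent degrees."""
    degrees = []
    for ant in rule.antecedents:
        if ant.mode == "any":
            continue
        if ant.variable not in crisp_inputs:
            raise InputError(f"missing input {ant.variable!r}")
        var = config.input(ant.variable)
        degrees.append(ant.degree(float(crisp_inputs[ant.variable]), var))
    return min(degrees)


def aggregate_and_defuzzify(
    activations: Mapping[FuzzyRule, float] | Iterable[tuple[FuzzyRule, float]],
    config: InferenceSystemConfig,
) -> float:
    """MIN-implication, MAX-aggregation and centroid defuzzification.

    The aggregated set is ``g(y) = max_r min(activation_r, mu_consequent_r(y))``
    sampled on the uniform output grid; the crisp value is
    ``sum(y * g) / sum(g)``. Raises :class:`DegenerateInferenceError` when no
    rule fired.
    """
    pairs = activations.items() if isinstance(activations, Mapping) else activations
    grid = config.output_grid()
    aggregated = np.zeros_like(grid)
    fired = False
    for rule, act in pairs:
        if act <= 0.0:
            continue
        fired = True
        mu = config.output.label(rule.consequent_label).membership(grid)
        aggregated = np.maximum(aggregated, np.minimum(act, mu))
    if not fired or not np.any(aggregated > 0.0):
        raise DegenerateInferenceError("no rule fired; aggregated set is empty")
    return float(np.dot(grid, aggregated) / aggregated.sum())


def infer(
    crisp_inputs: Mapping[str, float],
    config: InferenceSystemConfig,
) -> float:
    """Run the full Mamdani pipeline on one crisp input vector.

    Inputs outside the declared universe are clamped to the nearest bound
    (sensors can read outside the modelled range) with a logged warning.
    """
    clamped: dict[str, float] = {}
    for var in config.inputs:
        if var.name not in crisp_inputs:
            raise InputError(f"missing input {var.name!r}")
        x = float(crisp_inputs[var.name])
        if not math.isfinite(x):
            raise InputError(f"non-finite input {var.name!r} = {x}")
        lo, hi = var.universe
        if x < lo or x > hi:
            logger.warning(
                "input %s=%g outside universe [%g, %g]; clamped", var.name, x, lo, hi
            )
            x = min(max(x, lo), hi)
        clamped[var.name] = x
    activations = [(rule, evaluate_rule(clamped, rule, config)) for rule in config.rules]
    return aggregate_and_defuzzify(activations, config)
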