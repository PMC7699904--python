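"""Builders for the default technical- and expert-risk inference systems.

The published description of the two systems fixes their structure (Mamdani,
trapezoidal labels, MIN/MAX, centroid, the input universes, the rule counts
and a printed subset of rules) but not the membership-function knots. The
defaults here anchor the knots to the clinical reference points available:
SpO2 97-99 % is normal, readings below ~90 % may require supplementary
oxygen and below 75-80 % the pulse-oximeter itself becomes unreliable; a
resting heart rate of roughly 60-100 bpm and a core temperature plateau
around 36-36.5 degC are unremarkable. The free ramp edges of the
temperature labels are then calibrated (see ``scripts/calibrate_fis.py``)
so the systems reproduce the reference worked-example outputs RT = 43.33
for (92 %, 80 bpm, 37 degC) and RE = 90 for assessments (3, 7, 10).

Rule bases are the full combination tables — 3x3x5 = 45 rules for the
technical system and 3x3x3 = 27 combinations plus the two reference rules
verbatim (29 in total) for the expert one. Consequents follow a
max-of-severities completion, overridden where the printed rules dictate
otherwise (any non-Very_Low SpO2 with normal temperature and normal-or-high
heart rate maps to R1; a Medium sensor assessment with Low history and Low
other-factors maps to R1).
"""

from __future__ import annotations

from itertools import product

from .fuzzy import (
    FuzzyRule,
    FuzzyVariable,
    InferenceSystemConfig,
    RuleAntecedent,
    TrapezoidLabel,
)

__all__ = [
    "build_technical_config",
    "build_expert_config",
    "TECHNICAL_PRINTED_RULES",
    "EXPERT_PRINTED_RULES",
]

# Printed rule subsets, in the config-file clause syntax ("!" = is-not).
# Any configuration claiming fidelity to the published systems must contain
# or imply these.
TECHNICAL_PRINTED_RULES: list[tuple[dict[str, str], str]] = [
    ({"spo2": "Very_Low", "heart_rate": "Normal"}, "R5"),
    ({"spo2": "!Very_Low", "temperature": "Normal", "heart_rate": "Normal"}, "R1"),
    ({"spo2": "!Very_Low", "temperature": "Normal", "heart_rate": "High"}, "R1"),
]

EXPERT_PRINTED_RULES: list[tuple[dict[str, str], str]] = [
    (
        {
            "sensors_score": "Medium",
            "history_score": "Low",
            "other_factors_score": "Low",
        },
        "R1",
    ),
    (
        {
            "sensors_score": "Low",
            "history_score": "High",
            "other_factors_score": "High",
        },
        "R5",
    ),
]


def _risk_output(name: str) -> FuzzyVariable:
    # Five ranks centred at 10, 30, 50, 70, 90. The boundary labels are
    # rectangular and the interior ones symmetric, so MIN-implication
    # truncation never shifts a label's own centroid: a saturated R1 (R5)
    # inference defuzzifies to exactly 10 (90) at any activation, and
    # mixed inferences interpolate monotonically between rank centres.
    return FuzzyVariable(
        name=name,
        universe=(0.0, 100.0),
        labels=(
            TrapezoidLabel("R1", (0.0, 0.0, 20.0, 20.0)),
            TrapezoidLabel("R2", (18.0, 27.0, 33.0, 42.0)),
            TrapezoidLabel("R3", (38.0, 47.0, 53.0, 62.0)),
            TrapezoidLabel("R4", (58.0, 67.0, 73.0, 82.0)),
            TrapezoidLabel("R5", (80.0, 80.0, 100.0, 100.0)),
        ),
    )


def build_technical_config(
    *,
    t_normal_edge: float = 36.5,
    t_normal_zero: float = 37.41,
    t_high_start: float = 36.5,
    t_high_full: float = 38.06,
    resolution: int = 1001,
) -> InferenceSystemConfig:
    """Technical-risk system: SpO2, temperature, heart rate -> risk rank.

    The keyword knots are the calibration degrees of freedom: where the
    temperature Normal membership decays to zero and where High saturates.
    They set how much a borderline 37.0 degC reading contributes, which is
    what positions the reference worked-example output; both memberships
    stay below 0.5 at 37.0 degC so that label-crossover dips of the other
    inputs can never modulate them.
    """
    spo2 = FuzzyVariable(
        "spo2",
        (70.0, 100.0),
        (
            TrapezoidLabel("Very_Low", (70.0, 70.0, 75.0, 80.0)),
            TrapezoidLabel("Low", (75.0, 80.0, 90.0, 97.0)),
            TrapezoidLabel("Normal", (90.0, 97.0, 100.0, 100.0)),
        ),
    )
    temperature = FuzzyVariable(
        "temperature",
        (33.0, 41.0),
        (
            TrapezoidLabel("Low", (33.0, 33.0, 35.0, 36.2)),
            TrapezoidLabel("Normal", (35.0, 36.0, t_normal_edge, t_normal_zero)),
            TrapezoidLabel("High", (t_high_start, t_high_full, 41.0, 41.0)),
        ),
    )
    heart_rate = FuzzyVariable(
        "heart_rate",
        (15.0, 180.0),
        (
            TrapezoidLabel("Very_Low", (15.0, 15.0, 35.0, 45.0)),
            TrapezoidLabel("Low", (35.0, 45.0, 55.0, 65.0)),
            TrapezoidLabel("Normal", (55.0, 65.0, 95.0, 110.0)),
            TrapezoidLabel("High", (95.0, 110.0, 130.0, 150.0)),
            TrapezoidLabel("Very_High", (130.0, 150.0, 180.0, 180.0)),
        ),
    )
    output = _risk_output("technical_risk")

    spo2_sev = {"Low": 2, "Normal": 1}
    temp_sev = {"Low": 3, "Normal": 1, "High": 5}
    # Extreme bradycardia (< ~35 bpm) and tachycardia (> ~150 bpm) are
    # peri-arrest signs and escalate to the top rank outright.
    hr_sev = {"Very_Low": 5, "Low": 3, "Normal": 1, "High": 2, "Very_High": 5}

    rules = []
    for s, t, h in product(
        spo2.label_names(), temperature.label_names(), heart_rate.label_names()
    ):
        if s == "Very_Low":
            rank = 5  # oximeter floor: unreadably low saturation dominates
        elif t == "Normal" and h in ("Normal", "High"):
            rank = 1  # printed reference rules 2 and 3
        else:
            rank = max(spo2_sev[s], temp_sev[t], hr_sev[h])
        rules.append(
            FuzzyRule(
                antecedents=(
                    RuleAntecedent("spo2", "is", s),
                    RuleAntecedent("temperature", "is", t),
                    RuleAntecedent("heart_rate", "is", h),
                ),
                consequent_label=f"R{rank}",
            )
        )
    return InferenceSystemConfig(
        inputs=(spo2, temperature, heart_rate),
        output=output,
        rules=tuple(rules),
        resolution=resolution,
        name="technical_risk_default",
    )


def build_expert_config(
    *,
    resolution: int = 1001,
) -> InferenceSystemConfig:
    """Expert-risk system: three 0-10 assessment scores -> risk rank."""

    def score_var(name: str) -> FuzzyVariable:
        return FuzzyVariable(
            name,
            (0.0, 10.0),
            (
                TrapezoidLabel("Low", (0.0, 0.0, 3.0, 5.0)),
                TrapezoidLabel("Medium", (3.0, 4.5, 5.5, 7.0)),
                TrapezoidLabel("High", (5.0, 7.0, 10.0, 10.0)),
            ),
        )

    inputs = (
        score_var("sensors_score"),
        score_var("history_score"),
        score_var("other_factors_score"),
    )
    output = _risk_output("expert_risk")

    sev = {"Low": 1, "Medium": 3, "High": 5}
    overrides = {("Medium", "Low", "Low"): 1}  # printed reference rule 1

    def combo_rule(s: str, h: str, o: str, rank: int) -> FuzzyRule:
        return FuzzyRule(
            antecedents=(
                RuleAntecedent("sensors_score", "is", s),
                RuleAntecedent("history_score", "is", h),
                RuleAntecedent("other_factors_score", "is", o),
            ),
            consequent_label=f"R{rank}",
        )

    rules = []
    names = ("Low", "Medium", "High")
    for s, h, o in product(names, names, names):
        rank = overrides.get((s, h, o), max(sev[s], sev[h], sev[o]))
        rules.append(combo_rule(s, h, o, rank))
    # The two printed rules are kept verbatim as well (they duplicate
    # combinations above), giving the published count of 29 rules.
    rules.append(combo_rule("Medium", "Low", "Low", 1))
    rules.append(combo_rule("Low", "High", "High", 5))

    return InferenceSystemConfig(
        inputs=inputs,
        output=output,
        rules=tuple(rules),
        resolution=resolution,
        name="expert_risk_default",
    )
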