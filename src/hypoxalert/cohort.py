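"""Cohort data model, packaged case-study fixtures, and a synthetic generator.

The packaged fixtures are the published 30-patient case study: the raw
patient table (vitals plus the free-text notes assessed by the expert team)
and the simulation results table (technical, expert and global risk with the
recommended and actual states). Files are UTF-8 CSV with '.' decimals and
'#' comment headers.

The synthetic generator draws cohorts that emulate the case-study
conditions: SpO2 as a two-component mixture of a healthy mode (truncated
normal on 94-100 %) and a hypoxemic tail (truncated normal below 90 %),
heart rate and temperature as truncated normals around resting values, and
the three 0-10 expert scores as a stated monotone map of vitals severity
plus noise. It is first-class, seeded, and reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .risk import ExpertAssessment, SensorReading

__all__ = [
    "FormatError",
    "PatientRecord",
    "CohortResultRow",
    "CohortParams",
    "EXCLUDED_REGRESSION_ROWS",
    "load_cohort",
    "write_cohort",
    "load_results",
    "write_results",
    "packaged_cohort_path",
    "packaged_results_path",
    "synthesize_cohort",
]

#: Result-table rows whose printed global risk is not reproduced by the
#: surface formulas within +-0.05: row 11 prints RG identical to RE, row 26
#: prints 87.74 where the formulas give ~80.74, and row 24 prints 97.70
#: against the ~97.90 of the other identical (90, 90) rows.
EXCLUDED_REGRESSION_ROWS = frozenset({11, 24, 26})

_COHORT_COLUMNS = ["patient_id", "spo2", "heart_rate", "temperature"]
_RESULT_COLUMNS = [
    "patient_id",
    "technical_risk",
    "expert_risk",
    "global_risk",
    "recommended_state",
    "actual_state",
]
_STATES = {"Emergency", "Non-emergency"}
_SCORE_COLUMNS = ["sensors_score", "history_score", "other_factors_score"]


class FormatError(ValueError):
    """A cohort or results file is missing columns or has unparseable rows."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: identifier, vitals, optional expert scores and notes."""

    id: str
    reading: SensorReading
    assessment: ExpertAssessment | None = None
    history_note: str = ""
    other_factors_note: str = ""
    demographics: dict = field(default_factory=dict)
    questionnaire: dict = field(default_factory=dict)

    @property
    def out_of_range(self) -> list[str]:
        return self.reading.out_of_range()


@dataclass(frozen=True)
class CohortResultRow:
    """One simulation-results row: risks plus recommended/actual state."""

    id: str
    technical_risk: float
    expert_risk: float
    global_risk: float
    recommended_state: str
    actual_state: str

    def __post_init__(self) -> None:
        for name in ("recommended_state", "actual_state"):
            v = getattr(self, name)
            if v not in _STATES:
                raise FormatError(f"{name} must be one of {_STATES}, got {v!r}")

    @property
    def actual_emergency(self) -> bool:
        return self.actual_state == "Emergency"

    @property
    def recommended_emergency(self) -> bool:
        return self.recommended_state == "Emergency"


def _read_csv(path: str | Path, mandatory: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    if frame.empty:
        raise FormatError(f"{path}: no data rows")
    return frame


def load_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a patient cohort CSV; bad rows are reported with line numbers.

    Mandatory columns: patient_id, spo2, heart_rate, temperature. Optional:
    the three expert-score columns, history and other_factors notes.
    """
    frame = _read_csv(path, _COHORT_COLUMNS)
    has_scores = all(c in frame.columns for c in _SCORE_COLUMNS)
    records: list[PatientRecord] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        lineno = idx + 2  # header line + 1-based
        try:
            reading = SensorReading(
                spo2=float(row["spo2"]),
                heart_rate=float(row["heart_rate"]),
                temperature=float(row["temperature"]),
            )
            assessment = None
            if has_scores and not row[_SCORE_COLUMNS].isna().any():
                assessment = ExpertAssessment(
                    *(float(row[c]) for c in _SCORE_COLUMNS)
                )
            records.append(
                PatientRecord(
                    id=str(row["patient_id"]),
                    reading=reading,
                    assessment=assessment,
                    history_note=str(row.get("history", "") or ""),
                    other_factors_note=str(row.get("other_factors", "") or ""),
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise FormatError(f"{path}: unparseable rows:\n" + "\n".join(errors))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate patient_id values")
    return records


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort to CSV in the load_cohort layout (round-trip safe)."""
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.id,
            "spo2": rec.reading.spo2,
            "heart_rate": rec.reading.heart_rate,
            "temperature": rec.reading.temperature,
            "history": rec.history_note,
            "other_factors": rec.other_factors_note,
        }
        if rec.assessment is not None:
            row.update(
                sensors_score=rec.assessment.sensors_score,
                history_score=rec.assessment.history_score,
                other_factors_score=rec.assessment.other_factors_score,
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.2f")


def load_results(path: str | Path) -> list[CohortResultRow]:
    """Read a simulation-results CSV (case-study results layout)."""
    frame = _read_csv(path, _RESULT_COLUMNS)
    rows: list[CohortResultRow] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        try:
            rows.append(
                CohortResultRow(
                    id=str(row["patient_id"]),
                    technical_risk=float(row["technical_risk"]),
                    expert_risk=float(row["expert_risk"]),
                    global_risk=float(row["global_risk"]),
                    recommended_state=str(row["recommended_state"]),
                    actual_state=str(row["actual_state"]),
                )
            )
        except (TypeError, ValueError, FormatError) as exc:
            errors.append(f"line {idx + 2}: {exc}")
    if errors:
        raise FormatError(f"{path}: unparseable rows:\n" + "\n".join(errors))
    return rows


def write_results(rows: Sequence[CohortResultRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.id,
                "technical_risk": r.technical_risk,
                "expert_risk": r.expert_risk,
                "global_risk": r.global_risk,
                "recommended_state": r.recommended_state,
                "actual_state": r.actual_state,
            }
            for r in rows
        ]
    ).to_csv(path, index=False, float_format="%.2f")


def packaged_cohort_path() -> Path:
    """Path of the packaged 30-patient cohort fixture."""
    with resources.as_file(
        resources.files("hypoxalert.data").joinpath("table5_patients.csv")
    ) as path:
        return Path(path)


def packaged_results_path() -> Path:
    """Path of the packaged simulation-results fixture."""
    with resources.as_file(
        resources.files("hypoxalert.data").joinpath("table6_results.csv")
    ) as path:
        return Path(path)


# -- synthetic cohorts ----------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Distribution settings for the synthetic-cohort generator.

    The defaults emulate the case-study mix: about half the cohort carries
    a hypoxemic saturation (the published cohort has 17/30 actual
    emergencies), the healthy mode sits in the 96-99 % band, heart rate and
    temperature centre on resting values, and hypoxemic patients run
    slightly febrile. Scores are a monotone map of vitals severity (weights
    0.6 SpO2 deficit, 0.25 temperature deviation, 0.15 heart-rate
    deviation) plus unit-scale noise.
    """

    hypoxemic_weight: float = 0.5
    healthy_spo2: tuple[float, float] = (97.5, 1.2)  # mean, sd on [94, 100]
    hypoxemic_spo2: tuple[float, float] = (84.0, 5.0)  # mean, sd on [70, 89.5]
    heart_rate: tuple[float, float] = (75.0, 15.0)  # mean, sd on [40, 150]
    temperature: tuple[float, float] = (36.7, 0.5)  # mean, sd on [35, 40]
    fever_shift: float = 0.8  # added to hypoxemic temperatures, degC
    score_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hypoxemic_weight <= 1.0):
            raise ValueError(
                f"hypoxemic_weight must be in [0, 1], got {self.hypoxemic_weight}"
            )
        for name in ("healthy_spo2", "hypoxemic_spo2", "heart_rate", "temperature"):
            mean, sd = getattr(self, name)
            if sd <= 0:
                raise ValueError(f"{name}: sd must be positive")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be non-negative")


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def severity_score(spo2: float, heart_rate: float, temperature: float) -> float:
    """Monotone vitals-severity map onto [0, 1] used to seed expert scores.

    Severity rises as saturation falls below 97 %, as temperature departs
    from 36.5 degC and as heart rate departs from 80 bpm.
    """
    spo2_deficit = np.clip((97.0 - spo2) / 27.0, 0.0, 1.0)
    temp_dev = np.clip(abs(temperature - 36.5) / 3.5, 0.0, 1.0)
    hr_dev = np.clip(abs(heart_rate - 80.0) / 70.0, 0.0, 1.0)
    return float(0.6 * spo2_deficit + 0.25 * temp_dev + 0.15 * hr_dev)


def synthesize_cohort(
    n: int,
    seed: int,
    params: CohortParams = CohortParams(),
) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort of ``n`` patients."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    hypox = rng.random(n) < params.hypoxemic_weight

    spo2 = np.where(
        hypox,
        _truncnorm(rng, *params.hypoxemic_spo2, 70.0, 89.5, n),
        _truncnorm(rng, *params.healthy_spo2, 94.0, 100.0, n),
    )
    heart_rate = _truncnorm(rng, *params.heart_rate, 40.0, 150.0, n)
    temperature = _truncnorm(rng, *params.temperature, 35.0, 40.0, n)
    temperature = np.where(
        hypox, np.minimum(temperature + params.fever_shift, 40.0), temperature
    )

    records = []
    for i in range(n):
        sev = severity_score(spo2[i], heart_rate[i], temperature[i])
        noise = rng.normal(0.0, params.score_noise_sd, size=3)
        scores = np.clip(10.0 * sev + noise, 0.0, 10.0)
        records.append(
            PatientRecord(
                id=f"S{i + 1:03d}",
                reading=SensorReading(
                    spo2=round(float(spo2[i]), 1),
                    heart_rate=round(float(heart_rate[i]), 0),
                    temperature=round(float(temperature[i]), 1),
                ),
                assessment=ExpertAssessment(
                    sensors_score=round(float(scores[0]), 1),
                    history_score=round(float(scores[1]), 1),
                    other_factors_score=round(float(scores[2]), 1),
                ),
                history_note="synthetic record",
                other_factors_note="",
            )
        )
    return records
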