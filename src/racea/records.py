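"""Patient-level record types shared by the cohort, matching and efficacy modules.

A patient is described by demographics plus the rheumatoid-arthritis core set
of disease-activity measures (28-joint counts, morning stiffness, pain VAS,
HAQ disability index, ESR, CRP, rheumatoid factor and the composite DAS28),
recorded at baseline and, once treatment response has been simulated or
observed, at month 6.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError

ARMS = ("TOF", "ADA")

#: Core-set measures used as auxiliary criteria for ACR response assessment.
AUX_MEASURES = ("vas", "haq", "esr", "crp")


class ACRLevel(enum.IntEnum):
    """Best ACR response level achieved (cumulative semantics: 70 ⊃ 50 ⊃ 20)."""

    NONE = 0
    ACR20 = 20
    ACR50 = 50
    ACR70 = 70


@dataclass(frozen=True)
class CoreSet:
    """One visit's core-set measurements.

    ``das28`` is stored explicitly so that a record round-trips through CSV
    without recomputation; consistency with its components is enforced by
    :func:`racea.efficacy.das28_esr` at validation time.
    """

    sjc28: int
    tjc28: int
    stiffness_min: float
    vas: float
    haq: float
    esr: float
    crp: float
    rf: float
    das28: Optional[float] = None

    def validate(self) -> None:
        if not (0 <= self.sjc28 <= 28):
            raise ConfigurationError(f"sjc28 out of [0, 28]: {self.sjc28}")
        if not (0 <= self.tjc28 <= 28):
            raise ConfigurationError(f"tjc28 out of [0, 28]: {self.tjc28}")
        if self.stiffness_min < 0:
            raise ConfigurationError(f"negative stiffness: {self.stiffness_min}")
        if not (0.0 <= self.vas <= 10.0):
            raise ConfigurationError(f"vas out of [0, 10]: {self.vas}")
        if not (0.0 <= self.haq <= 3.0):
            raise ConfigurationError(f"haq out of [0, 3]: {self.haq}")
        if self.esr < 1.0:
            raise ConfigurationError(f"esr below 1 mm/h: {self.esr}")
        if self.crp < 0.0:
            raise ConfigurationError(f"negative crp: {self.crp}")
        if self.rf < 0.0:
            raise ConfigurationError(f"negative rf: {self.rf}")


@dataclass
class PatientRecord:
    """One patient: treatment arm, demographics, and visit core sets."""

    id: str
    arm: str
    age: float
    female: bool
    bmi: float
    duration: float
    baseline: CoreSet
    month6: Optional[CoreSet] = None
    #: best ACR response category drawn during simulation, if any
    response: Optional[ACRLevel] = None

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise ConfigurationError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.age <= 0:
            raise ConfigurationError(f"non-positive age: {self.age}")
        self.baseline.validate()
        if self.month6 is not None:
            self.month6.validate()


_CORESET_FIELDS = [f.name for f in fields(CoreSet)]
_DEMO_FIELDS = ["id", "arm", "age", "female", "bmi", "duration"]


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into one row per patient.

    Baseline columns are prefixed ``bl_``, month-6 columns ``m6_``; month-6
    columns are NaN for patients whose response has not been simulated.
    """
    rows = []
    for r in records:
        row = {k: getattr(r, k) for k in _DEMO_FIELDS}
        for k in _CORESET_FIELDS:
            row[f"bl_{k}"] = getattr(r.baseline, k)
        for k in _CORESET_FIELDS:
            row[f"m6_{k}"] = getattr(r.month6, k) if r.month6 is not None else math.nan
        row["response"] = r.response.name if r.response is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


def _coreset_from_row(row: pd.Series, prefix: str) -> Optional[CoreSet]:
    vals = {k: row[f"{prefix}{k}"] for k in _CORESET_FIELDS}
    if any(pd.isna(v) for k, v in vals.items() if k != "das28"):
        return None
    vals["sjc28"] = int(vals["sjc28"])
    vals["tjc28"] = int(vals["tjc28"])
    if pd.isna(vals["das28"]):
        vals["das28"] = None
    return CoreSet(**vals)


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`cohort_to_frame`."""
    records = []
    for _, row in frame.iterrows():
        rec = PatientRecord(
            id=str(row["id"]),
            arm=str(row["arm"]),
            age=float(row["age"]),
            female=bool(row["female"]),
            bmi=float(row["bmi"]),
            duration=float(row["duration"]),
            baseline=_coreset_from_row(row, "bl_"),
            month6=_coreset_from_row(row, "m6_"),
        )
        resp = row.get("response", "")
        if isinstance(resp, str) and resp:
            rec.response = ACRLevel[resp]
        records.append(rec)
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    # %.17g round-trips doubles exactly through text
    cohort_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path) -> list[PatientRecord]:
    frame = pd.read_csv(path, keep_default_na=True, na_values=[""],
                        float_precision="round_trip")
    return frame_to_cohort(frame)
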