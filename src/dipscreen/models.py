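"""Domain types for EMR-based screening of drug-induced interstitial pneumonia.

The screen operates on three record streams from a hospital data warehouse:
free-text radiology reports (chest CT and chest X-ray, each with separate
findings and diagnosis fields), drug order records, and serum biomarker
results (KL-6, SP-D). All dates are day-granularity calendar dates.
"""

from __future__ import annotations

import datetime as dt
import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class Modality(str, enum.Enum):
    CT = "CT"
    XRAY = "XRAY"


class Analyte(str, enum.Enum):
    KL6 = "KL6"
    SPD = "SPD"


class Status(str, enum.Enum):
    """IP status of one observation period."""

    POS = "POS"
    NEG = "NEG"
    NA = "NA"


class Source(str, enum.Enum):
    """Evidence modality that determined a period's IP status."""

    CT = "CT"
    XRAY = "XRAY"
    KL6 = "KL6"
    SPD = "SPD"
    NONE = "NONE"


class Grade(str, enum.Enum):
    """Confidence grade of drug-induced IP for one patient and drug."""

    DEFINITIVE = "DEFINITIVE"
    STRONGLY_SUSPECTED = "STRONGLY_SUSPECTED"
    WEAKLY_SUSPECTED = "WEAKLY_SUSPECTED"
    NEGATIVE = "NEGATIVE"
    NOT_DETERMINED = "NOT_DETERMINED"


#: Ordering used to pick the most confident grade across drug episodes.
GRADE_CONFIDENCE: dict[Grade, int] = {
    Grade.DEFINITIVE: 4,
    Grade.STRONGLY_SUSPECTED: 3,
    Grade.WEAKLY_SUSPECTED: 2,
    Grade.NEGATIVE: 1,
    Grade.NOT_DETERMINED: 0,
}


class AdjudicationLabel(str, enum.Enum):
    """Chart-review outcome assigned by a physician."""

    DIP = "DIP"
    NON_DIP = "NON_DIP"
    NOT_DETERMINED = "NOT_DETERMINED"


class RadiologyReport(BaseModel):
    """One imaging exam: metadata plus the two free-text fields.

    Findings and diagnosis fields are assessed independently; ``gold_ip`` is
    an optional radiologist label used for lexicon training and evaluation.
    """

    model_config = ConfigDict(frozen=True)

    report_id: str
    patient_id: str
    exam_date: dt.date
    modality: Modality
    findings_text: str = ""
    diagnosis_text: str = ""
    gold_ip: Optional[bool] = None


class DrugOrder(BaseModel):
    """One raw drug order covering a closed date interval."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    drug_code: str
    start_date: dt.date
    end_date: dt.date

    @model_validator(mode="after")
    def _dates_ordered(self) -> "DrugOrder":
        if self.start_date > self.end_date:
            raise ValueError(
                f"order start_date {self.start_date} after end_date {self.end_date}"
            )
        return self


class LabResult(BaseModel):
    """One serum biomarker measurement (KL-6 in U/mL, SP-D in ng/mL)."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: dt.date
    analyte: Analyte
    value: float

    @field_validator("value")
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"lab value must be >= 0, got {v}")
        return v


class PeriodStatus(BaseModel):
    """IP status of one period with evidence provenance."""

    status: Status
    source: Source = Source.NONE
    evidence_ids: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _na_iff_none(self) -> "PeriodStatus":
        if (self.status is Status.NA) != (self.source is Source.NONE):
            raise ValueError("status NA exactly when source NONE")
        return self


class PeriodPattern(BaseModel):
    """The (pre, during, post) triple indexing the decision table."""

    pre: PeriodStatus
    during: PeriodStatus
    post: PeriodStatus

    def as_tuple(self) -> tuple[Status, Status, Status]:
        return (self.pre.status, self.during.status, self.post.status)


class DipJudgment(BaseModel):
    """Screening verdict for one patient and drug."""

    patient_id: str
    drug_code: str
    pattern: PeriodPattern
    grade: Grade
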