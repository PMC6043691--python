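"""Synthetic EMR generation with planted ground truth.

Real hospital report corpora cannot be redistributed, so every part of the
screen is exercised against generated data: report corpora with planted
keyword presence probabilities (plus negation phrases and other-organ
confounders placed inside the matching windows), drug order streams with
configurable gaps, period-structured CT exams and biomarker series that
realize a planted (pre, during, post) IP pattern per patient, and fixture
tables mirroring published screening-accuracy cross-tabs.

Report text is template-based English; the planted lexicon's surface forms
are whatever the templates embed, which is all the matcher requires.
Generators are deterministic given their seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .lexicon import KeywordEntry, KeywordLexicon
from .models import (
    Analyte,
    DrugOrder,
    Grade,
    LabResult,
    Modality,
    RadiologyReport,
    Status,
)

# ---------------------------------------------------------------------------
# Planted lexicon shared by the cohort generator and its consumers

_NEGATION_TERMS = ("not confirmed", "not accepted", "not identified")
_ORGAN_TERMS = ("liver", "aortic", "kidney", "spleen")
_IP_DIAGNOSIS_TERMS = (
    "interstitial pneumonia",
    "UIP",
    "AIP",
)
_EXCLUSION_DIAGNOSIS_TERMS = (
    "lymphocytic interstitial pneumonia",
    "RB-ILD",
    "edema of the lungs",
    "viral pneumonia",
)

_PLANTED_KEYWORDS = (
    ("ground glass", ("ground glass", "frosted glass"), 25.0, 0.30),
    ("honeycombing", ("honeycombing",), 18.0, 0.50),
    ("reticular shadow", ("reticular shadow",), 12.0, 0.60),
)


def synthetic_lexicon(modality: Modality = Modality.CT) -> KeywordLexicon:
    """Fixed keyword lexicon used when generating cohorts: scoring positive
    template text with it yields a score far above 1, negative text far
    below, so cutoff 1.0 separates the classes deterministically."""
    entries = tuple(
        KeywordEntry(
            canonical=c, variants=v, n_ip=0, n_nonip=0, lr_pos=lp, lr_neg=ln
        )
        for c, v, lp, ln in _PLANTED_KEYWORDS
    )
    return KeywordLexicon(
        modality=modality,
        entries=entries,
        negation_terms=_NEGATION_TERMS,
        organ_terms=_ORGAN_TERMS,
        ip_diagnosis_terms=_IP_DIAGNOSIS_TERMS,
        exclusion_diagnosis_terms=_EXCLUSION_DIAGNOSIS_TERMS,
        n_ip_total=0,
        n_nonip_total=0,
    )


SYNTHETIC_CUTOFF = 1.0

_POSITIVE_FINDINGS = (
    "Ground glass opacity in both lower lobes. "
    "Honeycombing along the subpleural regions. "
    "Reticular shadow is seen bilaterally."
)
_NEGATIVE_FINDINGS = "Heart size within normal limits. Lung fields are clear."


# ---------------------------------------------------------------------------
# Labeled report corpora


class KeywordSpec(BaseModel):
    """One keyword to plant: canonical form plus Bernoulli presence
    probabilities in IP and non-IP reports."""

    canonical: str
    p_ip: float
    p_nonip: float

    @model_validator(mode="after")
    def _probs(self) -> "KeywordSpec":
        for p in (self.p_ip, self.p_nonip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("presence probabilities must be in [0, 1]")
        return self


class CorpusSpec(BaseModel):
    """Specification of a labeled synthetic report corpus."""

    n_ip: int
    n_nonip: int
    keywords: tuple[KeywordSpec, ...]
    negation_rate: float = 0.0
    organ_confound_rate: float = 0.0
    modality: Modality = Modality.CT
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CorpusSpec":
        if self.n_ip < 0 or self.n_nonip < 0:
            raise ValueError("report counts must be >= 0")
        if not 0 <= self.negation_rate <= 1 or not 0 <= self.organ_confound_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.negation_rate + self.organ_confound_rate > 1:
            raise ValueError("negation_rate + organ_confound_rate must be <= 1")
        return self


def generate_corpus(spec: CorpusSpec) -> list[RadiologyReport]:
    """Generate a labeled corpus with planted keyword presence.

    Each planted keyword occurrence is rendered in one of three template
    sentences: plainly affirmed, negated (a negation phrase within the
    15-character window after the keyword), or attributed to another organ
    (an organ name directly before the keyword), drawn per the configured
    rates. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    reports: list[RadiologyReport] = []
    base = dt.date(2010, 1, 4)
    for i in range(spec.n_ip + spec.n_nonip):
        is_ip = i < spec.n_ip
        sentences = ["Routine chest examination."]
        for kw in spec.keywords:
            p = kw.p_ip if is_ip else kw.p_nonip
            if rng.random() >= p:
                continue
            u = rng.random()
            if u < spec.negation_rate:
                sentences.append(f"{kw.canonical} is not confirmed.")
            elif u < spec.negation_rate + spec.organ_confound_rate:
                sentences.append(f"liver {kw.canonical} is seen.")
            else:
                sentences.append(f"{kw.canonical} is seen in the lung fields.")
        reports.append(
            RadiologyReport(
                report_id=f"SR{i:06d}",
                patient_id=f"SP{i:06d}",
                exam_date=base + dt.timedelta(days=i % 365),
                modality=spec.modality,
                findings_text=" ".join(sentences),
                diagnosis_text="",
                gold_ip=is_ip,
            )
        )
    return reports


def corpus_synonym_map(spec: CorpusSpec) -> dict[str, tuple[str, ...]]:
    """Identity synonym map over the spec's planted canonicals."""
    return {kw.canonical: (kw.canonical,) for kw in spec.keywords}


# ---------------------------------------------------------------------------
# Cohorts with planted period patterns

#: representative (pre, during, post) pattern realizing each grade
GRADE_PATTERNS: dict[Grade, tuple[Status, Status, Status]] = {
    Grade.DEFINITIVE: (Status.NEG, Status.POS, Status.NEG),
    Grade.STRONGLY_SUSPECTED: (Status.NEG, Status.POS, Status.NA),
    Grade.WEAKLY_SUSPECTED: (Status.NA, Status.POS, Status.NA),
    Grade.NEGATIVE: (Status.NEG, Status.NEG, Status.NEG),
    Grade.NOT_DETERMINED: (Status.NA, Status.NA, Status.NA),
}


class CohortSpec(BaseModel):
    """Specification of a synthetic exposed cohort.

    ``grade_probs`` is the planted distribution of DIP grades; each patient
    draws a grade, and exams are placed so the screen's period logic must
    reproduce it. ``order_split_gap_days`` optionally splits every
    patient's order into two orders separated by that many
    non-administration days, to exercise episode merging.
    """

    n_patients: int
    drug_code: str = "TS-1"
    grade_probs: dict[Grade, float] = Field(
        default_factory=lambda: {
            Grade.DEFINITIVE: 0.02,
            Grade.STRONGLY_SUSPECTED: 0.02,
            Grade.WEAKLY_SUSPECTED: 0.02,
            Grade.NEGATIVE: 0.64,
            Grade.NOT_DETERMINED: 0.30,
        }
    )
    lab_density: float = 0.5
    kl6_normal_mean: float = 250.0
    kl6_abnormal_mean: float = 900.0
    spd_normal_mean: float = 60.0
    spd_abnormal_mean: float = 220.0
    lab_sigma: float = 0.2
    order_split_gap_days: Optional[int] = None
    episode_days: int = 60
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        total = sum(self.grade_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"grade probabilities must sum to 1, got {total}")
        if self.order_split_gap_days is not None and (
            self.order_split_gap_days < 1
            or self.order_split_gap_days > self.episode_days - 10
        ):
            raise ValueError("order_split_gap_days infeasible for episode length")
        return self


@dataclass
class SyntheticCohort:
    """Generated cohort with its ground truth and planted scoring assets."""

    reports: list[RadiologyReport]
    orders: list[DrugOrder]
    labs: list[LabResult]
    truth: pd.DataFrame  # patient_id, drug_code, pre, during, post, grade
    lexicons: dict[Modality, KeywordLexicon]
    cutoffs: dict[Modality, float]
    censor_date: dt.date


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate orders, CT reports, and labs realizing planted patterns.

    Every non-NA period of a patient contains one CT exam whose findings
    text scores above (POS) or below (NEG) the planted cutoff; NA periods
    contain no examinations. Biomarker values are drawn log-normally around
    period-appropriate means and never override CT. The censor date leaves
    every patient a non-empty post period, so a planted NA there reflects
    absent examinations, not censoring.
    """
    rng = np.random.default_rng(spec.seed)
    start = dt.date(2012, 3, 1)
    end = start + dt.timedelta(days=spec.episode_days)
    during_end = end + dt.timedelta(days=30)
    censor = during_end + dt.timedelta(days=120)
    exam_offsets = {
        "pre": start - dt.timedelta(days=45),
        "during": start + dt.timedelta(days=20),
        "post": during_end + dt.timedelta(days=40),
    }

    grades = list(spec.grade_probs)
    probs = np.array([spec.grade_probs[g] for g in grades], dtype=float)
    reports: list[RadiologyReport] = []
    orders: list[DrugOrder] = []
    labs: list[LabResult] = []
    truth_rows = []
    for i in range(spec.n_patients):
        pid = f"PT{i:05d}"
        grade = grades[int(rng.choice(len(grades), p=probs))]
        pattern = GRADE_PATTERNS[grade]

        if spec.order_split_gap_days is None:
            orders.append(
                DrugOrder(
                    patient_id=pid, drug_code=spec.drug_code,
                    start_date=start, end_date=end,
                )
            )
        else:
            gap = spec.order_split_gap_days
            mid = start + dt.timedelta(days=(spec.episode_days - gap) // 2)
            orders.append(
                DrugOrder(
                    patient_id=pid, drug_code=spec.drug_code,
                    start_date=start, end_date=mid,
                )
            )
            orders.append(
                DrugOrder(
                    patient_id=pid, drug_code=spec.drug_code,
                    start_date=mid + dt.timedelta(days=gap + 1), end_date=end,
                )
            )

        for period, status in zip(("pre", "during", "post"), pattern):
            if status is Status.NA:
                continue
            reports.append(
                RadiologyReport(
                    report_id=f"CT-{pid}-{period}",
                    patient_id=pid,
                    exam_date=exam_offsets[period],
                    modality=Modality.CT,
                    findings_text=(
                        _POSITIVE_FINDINGS if status is Status.POS
                        else _NEGATIVE_FINDINGS
                    ),
                    diagnosis_text="",
                )
            )
            if rng.random() < spec.lab_density:
                for analyte, mean_n, mean_a in (
                    (Analyte.KL6, spec.kl6_normal_mean, spec.kl6_abnormal_mean),
                    (Analyte.SPD, spec.spd_normal_mean, spec.spd_abnormal_mean),
                ):
                    mean = mean_a if status is Status.POS else mean_n
                    value = float(
                        np.exp(rng.normal(np.log(mean), spec.lab_sigma))
                    )
                    labs.append(
                        LabResult(
                            patient_id=pid,
                            date=exam_offsets[period],
                            analyte=analyte,
                            value=round(value, 1),
                        )
                    )
        truth_rows.append(
            {
                "patient_id": pid,
                "drug_code": spec.drug_code,
                "pre": pattern[0].value,
                "during": pattern[1].value,
                "post": pattern[2].value,
                "grade": grade.value,
            }
        )

    lexicon = synthetic_lexicon(Modality.CT)
    return SyntheticCohort(
        reports=reports,
        orders=orders,
        labs=labs,
        truth=pd.DataFrame(
            truth_rows,
            columns=["patient_id", "drug_code", "pre", "during", "post", "grade"],
        ),
        lexicons={Modality.CT: lexicon, Modality.XRAY: synthetic_lexicon(Modality.XRAY)},
        cutoffs={Modality.CT: SYNTHETIC_CUTOFF, Modality.XRAY: SYNTHETIC_CUTOFF},
        censor_date=censor,
    )


# ---------------------------------------------------------------------------
# Fixtures reproducing published screening-accuracy tables


def confusion_vectors(
    tp: int, fp: int, fn: int, tn: int
) -> tuple[list[bool], list[bool]]:
    """(predicted, gold) boolean vectors whose cross-tab equals the counts."""
    pred = [True] * tp + [True] * fp + [False] * fn + [False] * tn
    gold = [True] * tp + [False] * fp + [True] * fn + [False] * tn
    return pred, gold


@dataclass(frozen=True)
class PaperFixtures:
    """Printed-table fixtures for evaluation arithmetic.

    ``report_accuracy`` holds (predicted, gold) vectors per evaluation
    block; ``grade_counts`` the per-drug screening grade tallies (the
    source table distinguishes six grade rows); ``chart_review`` the
    per-drug chart-review outcome tables for flagged patients.
    """

    report_accuracy: dict[str, tuple[list[bool], list[bool]]]
    grade_counts: pd.DataFrame
    chart_review: dict[str, pd.DataFrame]


GRADE_ROWS = (
    "Definitive",
    "Strongly suspected",
    "Weakly suspected",
    "Negatively suspected",
    "Negative",
    "Not determined",
)

FLAGGED_ROWS = GRADE_ROWS[:3]

DRUGS = ("Gefitinib", "MTX", "TS-1", "UFT")


def build_paper_fixtures() -> PaperFixtures:
    """Fixture bundle whose cross-tabs equal the published screening
    results cell-for-cell (report-level accuracy on two test sets, grade
    tallies for four anticancer drugs, and chart-review outcomes)."""
    report_accuracy = {
        "ct_test1": confusion_vectors(tp=92, fp=3, fn=8, tn=97),
        "xray_test1": confusion_vectors(tp=25, fp=0, fn=5, tn=43),
        "ct_test2": confusion_vectors(tp=8, fp=1, fn=1, tn=90),
        "xray_test2": confusion_vectors(tp=2, fp=1, fn=1, tn=31),
    }
    grade_counts = pd.DataFrame(
        {
            "Gefitinib": [3, 10, 0, 27, 149, 28],
            "MTX": [0, 2, 7, 170, 84, 127],
            "TS-1": [13, 10, 6, 873, 846, 340],
            "UFT": [2, 4, 3, 170, 430, 724],
        },
        index=list(GRADE_ROWS),
    )
    chart_cols = ["total", "dip", "non_dip", "not_determined"]
    chart_review = {
        "Gefitinib": pd.DataFrame(
            [[3, 1, 2, 0], [10, 8, 2, 0], [0, 0, 0, 0]],
            index=list(FLAGGED_ROWS), columns=chart_cols,
        ),
        "MTX": pd.DataFrame(
            [[0, 0, 0, 0], [2, 0, 2, 0], [7, 4, 3, 0]],
            index=list(FLAGGED_ROWS), columns=chart_cols,
        ),
        "TS-1": pd.DataFrame(
            [[13, 8, 5, 0], [10, 7, 3, 0], [6, 2, 4, 0]],
            index=list(FLAGGED_ROWS), columns=chart_cols,
        ),
        "UFT": pd.DataFrame(
            [[2, 1, 0, 1], [4, 3, 1, 0], [3, 3, 0, 0]],
            index=list(FLAGGED_ROWS), columns=chart_cols,
        ),
    }
    return PaperFixtures(
        report_accuracy=report_accuracy,
        grade_counts=grade_counts,
        chart_review=chart_review,
    )
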