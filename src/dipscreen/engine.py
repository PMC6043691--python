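"""Temporal DIP grading: per-period IP status, the decision table, and
cohort-level summaries.

Each exposure's three observation periods receive an IP status POS / NEG /
NA. CT reports are authoritative: if any CT exists in a period, the period
is POS when at least one CT calls IP and NEG otherwise. In CT-less periods
the screen may fall back on chest X-ray, then KL-6, then SP-D — but only
when that examination has demonstrated agreement with CT in some period of
the same exposure AND shows a change across periods (an examination whose
result never changes carries no temporal signal). The (pre, during, post)
status triple is then graded by an exhaustive 27-row decision table built
around dechallenge logic: IP appearing during administration and absent
afterwards is the strongest drug-causality evidence.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .config import ScreenConfig
from .exposure import DrugExposure, build_exposures
from .lexicon import KeywordLexicon
from .models import (
    AdjudicationLabel,
    Analyte,
    DipJudgment,
    DrugOrder,
    GRADE_CONFIDENCE,
    Grade,
    Grade as G,
    LabResult,
    Modality,
    PeriodPattern,
    PeriodStatus,
    RadiologyReport,
    Source,
    Status,
    Status as S,
)
from .scorer import classify_report

PERIODS = ("pre", "during", "post")

#: the full decision table over (pre, during, post) IP status
DECISION_TABLE: dict[tuple[Status, Status, Status], Grade] = {
    (S.NEG, S.NEG, S.NEG): G.NEGATIVE,
    (S.NEG, S.NEG, S.POS): G.NEGATIVE,
    (S.NEG, S.POS, S.NEG): G.DEFINITIVE,
    (S.NEG, S.POS, S.POS): G.STRONGLY_SUSPECTED,
    (S.POS, S.NEG, S.NEG): G.NEGATIVE,
    (S.POS, S.NEG, S.POS): G.NEGATIVE,
    (S.POS, S.POS, S.NEG): G.NEGATIVE,
    (S.POS, S.POS, S.POS): G.NEGATIVE,
    (S.NA, S.NEG, S.NEG): G.NEGATIVE,
    (S.NA, S.NEG, S.POS): G.NEGATIVE,
    (S.NA, S.POS, S.NEG): G.STRONGLY_SUSPECTED,
    (S.NA, S.POS, S.POS): G.NOT_DETERMINED,
    (S.NEG, S.NA, S.NEG): G.NOT_DETERMINED,
    (S.NEG, S.NA, S.POS): G.NOT_DETERMINED,
    (S.POS, S.NA, S.NEG): G.NEGATIVE,
    (S.POS, S.NA, S.POS): G.NEGATIVE,
    (S.NEG, S.NEG, S.NA): G.NEGATIVE,
    (S.NEG, S.POS, S.NA): G.STRONGLY_SUSPECTED,
    (S.POS, S.NEG, S.NA): G.NEGATIVE,
    (S.POS, S.POS, S.NA): G.NEGATIVE,
    (S.NA, S.NA, S.POS): G.NOT_DETERMINED,
    (S.NA, S.NA, S.NEG): G.NOT_DETERMINED,
    (S.NA, S.POS, S.NA): G.WEAKLY_SUSPECTED,
    (S.NA, S.NEG, S.NA): G.NEGATIVE,
    (S.POS, S.NA, S.NA): G.NEGATIVE,
    (S.NEG, S.NA, S.NA): G.NOT_DETERMINED,
    (S.NA, S.NA, S.NA): G.NOT_DETERMINED,
}

#: grades counted as a DIP flag at cohort level
FLAGGED_GRADES = (G.DEFINITIVE, G.STRONGLY_SUSPECTED, G.WEAKLY_SUSPECTED)

#: fallback evidence precedence in CT-less periods
FALLBACK_ORDER = (Source.XRAY, Source.KL6, Source.SPD)


def binarize_lab(lab: LabResult, config: ScreenConfig | None = None) -> Status:
    """POS iff the value strictly exceeds the analyte's upper limit of normal."""
    config = config or ScreenConfig()
    if lab.analyte is Analyte.KL6:
        limit = config.kl6_upper_limit
    elif lab.analyte is Analyte.SPD:
        limit = config.spd_upper_limit
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown analyte {lab.analyte}")
    return S.POS if lab.value > limit else S.NEG


def classify_dip(pattern: PeriodPattern | tuple[Status, Status, Status]) -> Grade:
    """Grade one exposure's (pre, during, post) IP-status pattern."""
    key = pattern.as_tuple() if isinstance(pattern, PeriodPattern) else tuple(pattern)
    return DECISION_TABLE[key]


@dataclass(frozen=True)
class ImagingCall:
    """One classified imaging exam, ready for period assignment."""

    report_id: str
    patient_id: str
    modality: Modality
    exam_date: dt.date
    ip_call: bool


#: per period, per evidence source: (status or None when unexamined, evidence ids)
PeriodEvidence = dict[str, dict[Source, tuple[Optional[Status], tuple[str, ...]]]]


def collect_evidence(
    exposure: DrugExposure,
    calls: Sequence[ImagingCall],
    labs: Sequence[LabResult],
    config: ScreenConfig | None = None,
) -> PeriodEvidence:
    """Aggregate evidence into (period, source) cells.

    Within one cell, any positive item makes the cell POS; items must
    belong to the exposure's patient.
    """
    config = config or ScreenConfig()
    cells: dict[tuple[str, Source], list[tuple[str, Status]]] = {}
    for c in calls:
        if c.patient_id != exposure.patient_id:
            continue
        period = exposure.assign_period(c.exam_date)
        if period is None:
            continue
        src = Source.CT if c.modality is Modality.CT else Source.XRAY
        cells.setdefault((period, src), []).append(
            (c.report_id, S.POS if c.ip_call else S.NEG)
        )
    for lab in labs:
        if lab.patient_id != exposure.patient_id:
            continue
        period = exposure.assign_period(lab.date)
        if period is None:
            continue
        src = Source.KL6 if lab.analyte is Analyte.KL6 else Source.SPD
        lab_id = f"{lab.analyte.value}:{lab.date.isoformat()}"
        cells.setdefault((period, src), []).append((lab_id, binarize_lab(lab, config)))

    evidence: PeriodEvidence = {p: {} for p in PERIODS}
    for p in PERIODS:
        for src in (Source.CT, Source.XRAY, Source.KL6, Source.SPD):
            items = cells.get((p, src), [])
            if not items:
                evidence[p][src] = (None, ())
            else:
                status = S.POS if any(st is S.POS for _, st in items) else S.NEG
                evidence[p][src] = (status, tuple(i for i, _ in items))
    return evidence


def _fallback_qualifies(
    period: str, src: Source, result: Status, evidence: PeriodEvidence
) -> bool:
    """Concordance rule for non-CT evidence in a CT-less period.

    The examination must (a) agree with CT in some period where both were
    performed, and (b) show a different result in at least one other
    period — i.e. it discriminates between periods.
    """
    agrees = any(
        evidence[q][src][0] is not None
        and evidence[q][Source.CT][0] is not None
        and evidence[q][src][0] is evidence[q][Source.CT][0]
        for q in PERIODS
    )
    varies = any(
        q != period
        and evidence[q][src][0] is not None
        and evidence[q][src][0] is not result
        for q in PERIODS
    )
    return agrees and varies


def assess_period(
    period: str,
    evidence: PeriodEvidence,
    config: ScreenConfig | None = None,
) -> PeriodStatus:
    """IP status of one period from its evidence and cross-period context."""
    config = config or ScreenConfig()
    ct_status, ct_ids = evidence[period][Source.CT]
    if ct_status is not None:
        return PeriodStatus(status=ct_status, source=Source.CT, evidence_ids=ct_ids)
    for src in FALLBACK_ORDER:
        status, ids = evidence[period][src]
        if status is None:
            continue
        if not config.concordance_check or _fallback_qualifies(
            period, src, status, evidence
        ):
            return PeriodStatus(status=status, source=src, evidence_ids=ids)
    return PeriodStatus(status=S.NA, source=Source.NONE)


def judge_exposure(
    exposure: DrugExposure,
    calls: Sequence[ImagingCall],
    labs: Sequence[LabResult],
    config: ScreenConfig | None = None,
) -> tuple[PeriodPattern, Grade]:
    """Assess all three periods of one exposure and grade the pattern."""
    evidence = collect_evidence(exposure, calls, labs, config)
    pattern = PeriodPattern(
        pre=assess_period("pre", evidence, config),
        during=assess_period("during", evidence, config),
        post=assess_period("post", evidence, config),
    )
    return pattern, classify_dip(pattern)


def adjudicate_majority(votes: Sequence[AdjudicationLabel]) -> AdjudicationLabel:
    """Overall chart-review label from three independent physician votes:
    any label chosen by >= 2 doctors wins; three-way splits are
    NOT_DETERMINED."""
    if len(votes) != 3:
        raise ValueError(f"expected exactly 3 votes, got {len(votes)}")
    counts = Counter(votes)
    label, n = counts.most_common(1)[0]
    return label if n >= 2 else AdjudicationLabel.NOT_DETERMINED


def screen_cohort(
    reports: Sequence[RadiologyReport],
    orders: Sequence[DrugOrder],
    labs: Sequence[LabResult],
    lexicons: Mapping[Modality, KeywordLexicon],
    cutoffs: Mapping[Modality, float],
    censor_date: dt.date,
    config: ScreenConfig | None = None,
    drug_codes: Sequence[str] | None = None,
) -> list[DipJudgment]:
    """Run the full screen: classify reports, build exposures, grade.

    Returns one judgment per patient x drug; a patient with several
    separated episodes of a drug receives the most confident grade across
    episodes (with that episode's pattern).
    """
    config = config or ScreenConfig()
    calls = []
    for r in reports:
        if r.modality not in lexicons:
            continue
        j = classify_report(r, lexicons[r.modality], cutoffs[r.modality], config)
        calls.append(
            ImagingCall(
                report_id=r.report_id,
                patient_id=r.patient_id,
                modality=r.modality,
                exam_date=r.exam_date,
                ip_call=j.ip_call,
            )
        )
    if drug_codes is not None:
        orders = [o for o in orders if o.drug_code in set(drug_codes)]
    exposures = build_exposures(
        orders, config.order_merge_gap_days, config.washout_days, censor_date
    )
    calls_by_pid: dict[str, list[ImagingCall]] = {}
    for c in calls:
        calls_by_pid.setdefault(c.patient_id, []).append(c)
    labs_by_pid: dict[str, list[LabResult]] = {}
    for lab in labs:
        labs_by_pid.setdefault(lab.patient_id, []).append(lab)

    best: dict[tuple[str, str], DipJudgment] = {}
    for exp in exposures:
        pattern, grade = judge_exposure(
            exp,
            calls_by_pid.get(exp.patient_id, ()),
            labs_by_pid.get(exp.patient_id, ()),
            config,
        )
        key = (exp.patient_id, exp.drug_code)
        cand = DipJudgment(
            patient_id=exp.patient_id,
            drug_code=exp.drug_code,
            pattern=pattern,
            grade=grade,
        )
        if key not in best or GRADE_CONFIDENCE[grade] > GRADE_CONFIDENCE[best[key].grade]:
            best[key] = cand
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# Cohort summaries


def occurrence_rate_pct(
    n_definitive: int, n_strongly: int, n_weakly: int, n_total: int
) -> float:
    """Screen-flagged DIP occurrence rate in percent (unrounded)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * (n_definitive + n_strongly + n_weakly) / n_total


def ppv_pct(n_adjudicated_dip: int, n_flagged: int) -> Optional[float]:
    """Chart-review positive predictive value in percent; None when no
    patient was flagged (undefined, not 0)."""
    if n_flagged == 0:
        return None
    return 100.0 * n_adjudicated_dip / n_flagged


class DrugSummary:
    """Per-drug screening summary with optional chart-review columns."""

    def __init__(
        self,
        drug_code: str,
        grade_counts: Mapping[Grade, int],
        adjudicated_dip: Optional[int] = None,
    ) -> None:
        self.drug_code = drug_code
        self.grade_counts = {g: int(grade_counts.get(g, 0)) for g in Grade}
        self.n_total = sum(self.grade_counts.values())
        self.n_flagged = sum(self.grade_counts[g] for g in FLAGGED_GRADES)
        self.adjudicated_dip = adjudicated_dip

    @property
    def occurrence_rate(self) -> float:
        return occurrence_rate_pct(
            self.grade_counts[G.DEFINITIVE],
            self.grade_counts[G.STRONGLY_SUSPECTED],
            self.grade_counts[G.WEAKLY_SUSPECTED],
            self.n_total,
        )

    @property
    def ppv(self) -> Optional[float]:
        if self.adjudicated_dip is None:
            return None
        return ppv_pct(self.adjudicated_dip, self.n_flagged)

    @property
    def adjudicated_rate(self) -> Optional[float]:
        """Occurrence rate in percent after chart review."""
        if self.adjudicated_dip is None:
            return None
        return 100.0 * self.adjudicated_dip / self.n_total


class CohortSummary:
    """Cohort-level screen results across drugs.

    Relative risks are ratios of unrounded occurrence rates against the
    reference drug; rounding to one decimal happens only at presentation.
    """

    def __init__(
        self, drugs: Mapping[str, DrugSummary], reference_drug: Optional[str] = None
    ) -> None:
        if reference_drug is not None and reference_drug not in drugs:
            raise ValueError(f"reference drug {reference_drug!r} not in summary")
        self.drugs = dict(drugs)
        self.reference_drug = reference_drug

    def relative_risk(self, drug_code: str, adjudicated: bool = False) -> Optional[float]:
        if self.reference_drug is None:
            return None
        ref = self.drugs[self.reference_drug]
        num = self.drugs[drug_code]
        if adjudicated:
            if num.adjudicated_rate is None or ref.adjudicated_rate is None:
                return None
            return num.adjudicated_rate / ref.adjudicated_rate
        return num.occurrence_rate / ref.occurrence_rate

    def to_frame(self) -> pd.DataFrame:
        """Presentation table: percents and ratios rounded to one decimal."""
        rows = []
        for code, d in sorted(self.drugs.items()):
            rr = self.relative_risk(code)
            rr_adj = self.relative_risk(code, adjudicated=True)
            rows.append(
                {
                    "drug_code": code,
                    **{g.value.lower(): d.grade_counts[g] for g in Grade},
                    "n_total": d.n_total,
                    "n_flagged": d.n_flagged,
                    "occurrence_rate_pct": round(d.occurrence_rate, 1),
                    "adjudicated_rate_pct": (
                        None if d.adjudicated_rate is None else round(d.adjudicated_rate, 1)
                    ),
                    "ppv_pct": None if d.ppv is None else round(d.ppv, 1),
                    "relative_risk": None if rr is None else round(rr, 1),
                    "relative_risk_adjudicated": (
                        None if rr_adj is None else round(rr_adj, 1)
                    ),
                }
            )
        return pd.DataFrame(rows)


def summarize_cohort(
    judgments: Sequence[DipJudgment],
    adjudications: Optional[Mapping[tuple[str, str], AdjudicationLabel]] = None,
    reference_drug: Optional[str] = None,
) -> CohortSummary:
    """Summarize one-judgment-per-patient-per-drug screen output.

    ``adjudications`` maps (patient_id, drug_code) to chart-review labels
    for flagged patients; NOT_DETERMINED reviews stay in the PPV
    denominator (every flagged patient counts).
    """
    seen = Counter((j.patient_id, j.drug_code) for j in judgments)
    dup = [k for k, n in seen.items() if n > 1]
    if dup:
        raise ValueError(f"multiple judgments for patient x drug: {dup[:3]}")
    drugs: dict[str, DrugSummary] = {}
    for code in sorted({j.drug_code for j in judgments}):
        drug_js = [j for j in judgments if j.drug_code == code]
        counts = Counter(j.grade for j in drug_js)
        adj_dip: Optional[int] = None
        if adjudications is not None:
            adj_dip = sum(
                1
                for j in drug_js
                if j.grade in FLAGGED_GRADES
                and adjudications.get((j.patient_id, j.drug_code))
                is AdjudicationLabel.DIP
            )
        drugs[code] = DrugSummary(code, counts, adjudicated_dip=adj_dip)
    return CohortSummary(drugs, reference_drug=reference_drug)
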