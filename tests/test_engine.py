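import datetime as dt
from itertools import product

import pytest

from dipscreen import (
    AdjudicationLabel,
    Analyte,
    DipJudgment,
    DrugOrder,
    Grade,
    ImagingCall,
    LabResult,
    Modality,
    PeriodPattern,
    PeriodStatus,
    ScreenConfig,
    Source,
    Status,
    adjudicate_majority,
    assess_period,
    binarize_lab,
    classify_dip,
    collect_evidence,
    screen_cohort,
    summarize_cohort,
    synthetic_lexicon,
)
from dipscreen.engine import DECISION_TABLE, ppv_pct
from dipscreen.exposure import Episode, build_periods

# The published decision table, re-keyed independently from its printed
# rows ("-" negative, "+" positive, NA not available).
PRINTED_ROWS = [
    ("-", "-", "-", Grade.NEGATIVE),
    ("-", "-", "+", Grade.NEGATIVE),
    ("-", "+", "-", Grade.DEFINITIVE),
    ("-", "+", "+", Grade.STRONGLY_SUSPECTED),
    ("+", "-", "-", Grade.NEGATIVE),
    ("+", "-", "+", Grade.NEGATIVE),
    ("+", "+", "-", Grade.NEGATIVE),
    ("+", "+", "+", Grade.NEGATIVE),
    ("NA", "-", "-", Grade.NEGATIVE),
    ("NA", "-", "+", Grade.NEGATIVE),
    ("NA", "+", "-", Grade.STRONGLY_SUSPECTED),
    ("NA", "+", "+", Grade.NOT_DETERMINED),
    ("-", "NA", "-", Grade.NOT_DETERMINED),
    ("-", "NA", "+", Grade.NOT_DETERMINED),
    ("+", "NA", "-", Grade.NEGATIVE),
    ("+", "NA", "+", Grade.NEGATIVE),
    ("-", "-", "NA", Grade.NEGATIVE),
    ("-", "+", "NA", Grade.STRONGLY_SUSPECTED),
    ("+", "-", "NA", Grade.NEGATIVE),
    ("+", "+", "NA", Grade.NEGATIVE),
    ("NA", "NA", "+", Grade.NOT_DETERMINED),
    ("NA", "NA", "-", Grade.NOT_DETERMINED),
    ("NA", "+", "NA", Grade.WEAKLY_SUSPECTED),
    ("NA", "-", "NA", Grade.NEGATIVE),
    ("+", "NA", "NA", Grade.NEGATIVE),
    ("-", "NA", "NA", Grade.NOT_DETERMINED),
    ("NA", "NA", "NA", Grade.NOT_DETERMINED),
]

SYMBOL = {"-": Status.NEG, "+": Status.POS, "NA": Status.NA}


def status(code, source=Source.CT):
    st = SYMBOL[code]
    return PeriodStatus(
        status=st, source=Source.NONE if st is Status.NA else source
    )


class TestClassifyDip:
    def test_matches_published_table_row_for_row(self):
        assert len(PRINTED_ROWS) == 27
        for pre, during, post, grade in PRINTED_ROWS:
            assert classify_dip((SYMBOL[pre], SYMBOL[during], SYMBOL[post])) is grade

    def test_total_over_all_patterns(self):
        patterns = set(product(Status, repeat=3))
        assert set(DECISION_TABLE) == patterns
        for p in patterns:
            assert classify_dip(p) in Grade

    def test_negative_during_period_never_suspected(self):
        for pre, post in product(Status, repeat=2):
            assert classify_dip((pre, Status.NEG, post)) is Grade.NEGATIVE

    def test_accepts_period_pattern_objects(self):
        pattern = PeriodPattern(
            pre=status("-"), during=status("+"), post=status("-")
        )
        assert classify_dip(pattern) is Grade.DEFINITIVE


class TestBinarizeLab:
    def lab(self, analyte, value):
        return LabResult(
            patient_id="P1", date=dt.date(2012, 1, 1), analyte=analyte, value=value
        )

    def test_above_limit_positive(self, config):
        assert binarize_lab(self.lab(Analyte.KL6, 500.1), config) is Status.POS

    def test_exactly_at_limit_negative(self, config):
        assert binarize_lab(self.lab(Analyte.KL6, 500.0), config) is Status.NEG

    def test_below_limit_negative(self, config):
        assert binarize_lab(self.lab(Analyte.SPD, 80.0), config) is Status.NEG

    def test_limits_are_configurable(self):
        cfg = ScreenConfig(spd_upper_limit=50.0)
        assert binarize_lab(self.lab(Analyte.SPD, 80.0), cfg) is Status.POS


def _evidence(**cells):
    """Evidence grid from period -> {source: status} shorthand."""
    grid = {
        p: {s: (None, ()) for s in (Source.CT, Source.XRAY, Source.KL6, Source.SPD)}
        for p in ("pre", "during", "post")
    }
    for period, sources in cells.items():
        for src, st in sources.items():
            grid[period][src] = (st, (f"{src.value}-{period}",))
    return grid


class TestAssessPeriod:
    def test_any_positive_ct_dominates(self, config):
        ev = _evidence(during={Source.CT: Status.POS, Source.XRAY: Status.NEG})
        ps = assess_period("during", ev, config)
        assert (ps.status, ps.source) == (Status.POS, Source.CT)

    def test_no_evidence_is_not_available(self, config):
        ps = assess_period("pre", _evidence(), config)
        assert (ps.status, ps.source) == (Status.NA, Source.NONE)
        assert ps.evidence_ids == ()

    def test_concordant_varying_xray_adopted(self, config):
        # X-ray agrees with CT in "during" and changes in "post":
        # the CT-less "pre" period adopts the X-ray result
        ev = _evidence(
            pre={Source.XRAY: Status.NEG},
            during={Source.CT: Status.NEG, Source.XRAY: Status.NEG},
            post={Source.XRAY: Status.POS},
        )
        ps = assess_period("pre", ev, config)
        assert (ps.status, ps.source) == (Status.NEG, Source.XRAY)

    def test_never_varying_examination_not_adopted(self, config):
        ev = _evidence(
            pre={Source.XRAY: Status.NEG},
            during={Source.CT: Status.NEG, Source.XRAY: Status.NEG},
            post={Source.XRAY: Status.NEG},
        )
        assert assess_period("pre", ev, config).status is Status.NA

    def test_discordant_examination_not_adopted(self, config):
        ev = _evidence(
            pre={Source.XRAY: Status.NEG},
            during={Source.CT: Status.POS, Source.XRAY: Status.NEG},
            post={Source.XRAY: Status.POS},
        )
        assert assess_period("pre", ev, config).status is Status.NA

    def test_concordance_gate_can_be_disabled(self):
        cfg = ScreenConfig(concordance_check=False)
        ev = _evidence(pre={Source.XRAY: Status.NEG})
        ps = assess_period("pre", ev, cfg)
        assert (ps.status, ps.source) == (Status.NEG, Source.XRAY)

    def test_fallback_precedence_xray_before_labs(self):
        cfg = ScreenConfig(concordance_check=False)
        ev = _evidence(
            pre={Source.XRAY: Status.NEG, Source.KL6: Status.POS,
                 Source.SPD: Status.POS},
        )
        assert assess_period("pre", ev, cfg).source is Source.XRAY

    def test_lab_fallback_when_no_imaging(self):
        cfg = ScreenConfig(concordance_check=False)
        ev = _evidence(pre={Source.SPD: Status.POS})
        ps = assess_period("pre", ev, cfg)
        assert (ps.status, ps.source) == (Status.POS, Source.SPD)


class TestCollectEvidence:
    def test_bins_calls_and_labs_by_period_and_source(self, config):
        exposure = build_periods(
            Episode(patient_id="P1", drug_code="TS-1",
                    start=dt.date(2012, 3, 1), end=dt.date(2012, 4, 30)),
            30,
            dt.date(2012, 12, 31),
        )
        calls = [
            ImagingCall("R1", "P1", Modality.CT, dt.date(2012, 1, 10), False),
            ImagingCall("R2", "P1", Modality.CT, dt.date(2012, 3, 20), True),
            ImagingCall("R3", "P1", Modality.CT, dt.date(2012, 3, 25), False),
            ImagingCall("R4", "P1", Modality.XRAY, dt.date(2012, 8, 1), False),
            ImagingCall("R5", "P2", Modality.CT, dt.date(2012, 3, 20), True),
        ]
        labs = [
            LabResult(patient_id="P1", date=dt.date(2012, 8, 2),
                      analyte=Analyte.KL6, value=700.0),
        ]
        ev = collect_evidence(exposure, calls, labs, config)
        assert ev["pre"][Source.CT] == (Status.NEG, ("R1",))
        # any positive CT makes the during cell positive
        assert ev["during"][Source.CT] == (Status.POS, ("R2", "R3"))
        assert ev["post"][Source.XRAY] == (Status.NEG, ("R4",))
        assert ev["post"][Source.KL6][0] is Status.POS
        # other patients' evidence is ignored
        assert "R5" not in ev["during"][Source.CT][1]


class TestAdjudicateMajority:
    def test_two_of_three_wins(self):
        votes = [AdjudicationLabel.DIP, AdjudicationLabel.DIP,
                 AdjudicationLabel.NON_DIP]
        assert adjudicate_majority(votes) is AdjudicationLabel.DIP

    def test_three_way_split_not_determined(self):
        votes = [AdjudicationLabel.DIP, AdjudicationLabel.NON_DIP,
                 AdjudicationLabel.NOT_DETERMINED]
        assert adjudicate_majority(votes) is AdjudicationLabel.NOT_DETERMINED

    def test_unanimity(self):
        votes = [AdjudicationLabel.NON_DIP] * 3
        assert adjudicate_majority(votes) is AdjudicationLabel.NON_DIP

    @pytest.mark.parametrize("n", [0, 2, 4])
    def test_vote_count_enforced(self, n):
        with pytest.raises(ValueError):
            adjudicate_majority([AdjudicationLabel.DIP] * n)


def _judgment(patient, drug, grade):
    na = PeriodStatus(status=Status.NA, source=Source.NONE)
    pos = PeriodStatus(status=Status.POS, source=Source.CT)
    pattern = {
        Grade.WEAKLY_SUSPECTED: PeriodPattern(pre=na, during=pos, post=na),
        Grade.NOT_DETERMINED: PeriodPattern(pre=na, during=na, post=na),
    }.get(grade)
    if pattern is None:
        neg = PeriodStatus(status=Status.NEG, source=Source.CT)
        during = pos if grade is not Grade.NEGATIVE else neg
        pattern = PeriodPattern(pre=neg, during=during, post=neg)
        if grade is Grade.STRONGLY_SUSPECTED:
            pattern = PeriodPattern(pre=na, during=pos, post=neg)
    return DipJudgment(
        patient_id=patient, drug_code=drug, pattern=pattern, grade=grade
    )


class TestSummarizeCohort:
    def test_counts_conserved_and_rates(self):
        judgments = (
            [_judgment(f"A{i}", "GEF", Grade.DEFINITIVE) for i in range(3)]
            + [_judgment(f"B{i}", "GEF", Grade.NEGATIVE) for i in range(47)]
            + [_judgment(f"C{i}", "REF", Grade.DEFINITIVE) for i in range(1)]
            + [_judgment(f"D{i}", "REF", Grade.NEGATIVE) for i in range(99)]
        )
        summary = summarize_cohort(judgments, reference_drug="REF")
        gef = summary.drugs["GEF"]
        assert sum(gef.grade_counts.values()) == gef.n_total == 50
        assert gef.occurrence_rate == pytest.approx(6.0)
        assert summary.relative_risk("GEF") == pytest.approx(6.0)
        frame = summary.to_frame()
        assert set(frame["drug_code"]) == {"GEF", "REF"}

    def test_adjudicated_ppv(self):
        judgments = [_judgment(f"P{i}", "GEF", Grade.DEFINITIVE) for i in range(4)]
        adjudications = {
            ("P0", "GEF"): AdjudicationLabel.DIP,
            ("P1", "GEF"): AdjudicationLabel.DIP,
            ("P2", "GEF"): AdjudicationLabel.NON_DIP,
            # P3 reviewed as NOT_DETERMINED: stays in the denominator
            ("P3", "GEF"): AdjudicationLabel.NOT_DETERMINED,
        }
        summary = summarize_cohort(judgments, adjudications=adjudications)
        assert summary.drugs["GEF"].ppv == pytest.approx(50.0)

    def test_ppv_undefined_without_flagged_patients(self):
        judgments = [_judgment("P1", "GEF", Grade.NEGATIVE)]
        summary = summarize_cohort(judgments, adjudications={})
        assert summary.drugs["GEF"].ppv is None
        assert ppv_pct(0, 0) is None

    def test_duplicate_patient_drug_rejected(self):
        judgments = [_judgment("P1", "GEF", Grade.NEGATIVE)] * 2
        with pytest.raises(ValueError, match="multiple judgments"):
            summarize_cohort(judgments)

    def test_missing_reference_drug_rejected(self):
        judgments = [_judgment("P1", "GEF", Grade.NEGATIVE)]
        with pytest.raises(ValueError, match="reference"):
            summarize_cohort(judgments, reference_drug="TS-1")


class TestScreenCohortEpisodes:
    def test_most_confident_grade_across_episodes(self, config):
        lex = synthetic_lexicon(Modality.CT)
        orders = [
            DrugOrder(patient_id="P1", drug_code="TS-1",
                      start_date=dt.date(2011, 1, 1), end_date=dt.date(2011, 2, 1)),
            DrugOrder(patient_id="P1", drug_code="TS-1",
                      start_date=dt.date(2012, 1, 1), end_date=dt.date(2012, 2, 1)),
        ]
        pos = ("Ground glass opacity. Honeycombing along the septa. "
               "Reticular shadow bilaterally.")
        neg = "Lung fields are clear."

        def report(rid, date, text):
            from .conftest import make_report

            return make_report(rid, "P1", date, Modality.CT, findings=text)

        reports = [
            # episode 1: NEG / NEG / NEG -> NEGATIVE
            report("R1", dt.date(2010, 11, 1), neg),
            report("R2", dt.date(2011, 1, 15), neg),
            report("R3", dt.date(2011, 6, 1), neg),
            # episode 2: during POS, post NEG; pre period sees R3 (NEG)
            report("R4", dt.date(2012, 1, 20), pos),
            report("R5", dt.date(2012, 8, 1), neg),
        ]
        judgments = screen_cohort(
            reports,
            orders,
            [],
            {Modality.CT: lex},
            {Modality.CT: 1.0},
            censor_date=dt.date(2012, 12, 31),
            config=config,
        )
        assert len(judgments) == 1
        assert judgments[0].grade is Grade.DEFINITIVE
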