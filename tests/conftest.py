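import datetime as dt

import pytest

from dipscreen import (
    KeywordEntry,
    KeywordLexicon,
    Modality,
    RadiologyReport,
    ScreenConfig,
    build_paper_fixtures,
)


@pytest.fixture
def config():
    return ScreenConfig()


@pytest.fixture
def small_lexicon():
    """Three-keyword lexicon with known likelihood ratios."""
    return KeywordLexicon(
        modality=Modality.CT,
        entries=(
            KeywordEntry(
                canonical="ground glass",
                variants=("ground glass", "frosted glass"),
                lr_pos=10.0,
                lr_neg=0.5,
            ),
            KeywordEntry(canonical="cyst", variants=("cyst",), lr_pos=4.0, lr_neg=0.2),
            KeywordEntry(
                canonical="honeycombing", variants=("honeycombing",), lr_pos=25.0,
                lr_neg=0.6,
            ),
        ),
        negation_terms=("not accepted", "not confirmed"),
        organ_terms=("liver", "aortic"),
        ip_diagnosis_terms=("interstitial pneumonia", "UIP", "AIP"),
        exclusion_diagnosis_terms=(
            "lymphocytic interstitial pneumonia",
            "RB-ILD",
            "edema of the lungs",
            "viral pneumonia",
        ),
        n_ip_total=300,
        n_nonip_total=300,
    )


@pytest.fixture(scope="session")
def paper_fixtures():
    return build_paper_fixtures()


def make_report(
    report_id="R1",
    patient_id="P1",
    exam_date=dt.date(2012, 5, 1),
    modality=Modality.CT,
    findings="",
    diagnosis="",
    gold_ip=None,
):
    return RadiologyReport(
        report_id=report_id,
        patient_id=patient_id,
        exam_date=exam_date,
        modality=modality,
        findings_text=findings,
        diagnosis_text=diagnosis,
        gold_ip=gold_ip,
    )
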