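"""Report-level IP calling: keyword matching, the likelihood-ratio-product
score, diagnosis-field flag rules, ROC cutoff selection, and evaluation.

The findings field is scored as the product of keyword likelihood ratios
under a naive independence assumption; because prior odds are constant
across reports, the product is proportional to the posterior odds of IP
and serves as the "IP score". A keyword occurrence is discounted when a
negation phrase falls within a character window after it, or when a
non-lung organ name falls within the window on either side — both checks
confined to the keyword's sentence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import NegationDirection, ScoringMode, ScreenConfig
from .lexicon import KeywordLexicon
from .models import RadiologyReport
from .text import (
    find_occurrences,
    normalize_term,
    normalize_text,
    sentence_index,
    sentence_spans,
    span_gap,
)


@dataclass(frozen=True)
class KeywordMatch:
    """One located keyword occurrence in a findings field."""

    canonical: str
    surface: str
    span: tuple[int, int]  # 0-based, half-open offsets
    negated: bool
    other_organ: bool

    @property
    def effective_presence(self) -> bool:
        return not self.negated and not self.other_organ


@dataclass(frozen=True)
class ReportJudgment:
    """IP call for one report, with score and evidence."""

    report_id: str
    ip_score: float
    diagnosis_flag: bool
    findings_flag: bool
    matches: tuple[KeywordMatch, ...] = ()

    @property
    def ip_call(self) -> bool:
        return self.diagnosis_flag or self.findings_flag


@dataclass(frozen=True)
class RocCutoff:
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    distance_to_ideal: float


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else None

    @property
    def ppv(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    def summary(self) -> dict:
        """Presentation-rounded metrics: sens/spec to 2 decimals, PPV as
        a percent to 1 decimal."""
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity": None if self.sensitivity is None else round(self.sensitivity, 2),
            "specificity": None if self.specificity is None else round(self.specificity, 2),
            "ppv_pct": None if self.ppv is None else round(100.0 * self.ppv, 1),
        }


def _term_occurrences(norm_text: str, terms: Sequence[str]) -> list[tuple[int, int]]:
    occ: list[tuple[int, int]] = []
    for t in terms:
        occ.extend(find_occurrences(norm_text, normalize_term(t)))
    return occ


def _negated(
    kw_span: tuple[int, int],
    neg_spans: Sequence[tuple[int, int]],
    sent: tuple[int, int],
    config: ScreenConfig,
) -> bool:
    for ns in neg_spans:
        if not (sent[0] <= ns[0] < sent[1]):
            continue
        if ns[0] >= kw_span[1] and ns[0] - kw_span[1] <= config.negation_window:
            return True
        if (
            config.negation_direction is NegationDirection.BIDIRECTIONAL
            and ns[1] <= kw_span[0]
            and kw_span[0] - ns[1] <= config.negation_window
        ):
            return True
    return False


def _other_organ(
    kw_span: tuple[int, int],
    organ_spans: Sequence[tuple[int, int]],
    sent: tuple[int, int],
    config: ScreenConfig,
) -> bool:
    return any(
        sent[0] <= os_[0] < sent[1] and span_gap(kw_span, os_) <= config.organ_window
        for os_ in organ_spans
    )


def find_matches(
    findings_text: str, lexicon: KeywordLexicon, config: ScreenConfig | None = None
) -> list[KeywordMatch]:
    """Locate every lexicon variant occurrence and flag negation / other-organ
    context. A canonical is effectively present when at least one of its
    occurrences is neither negated nor organ-disqualified."""
    config = config or ScreenConfig()
    norm = normalize_text(findings_text)
    if not norm:
        return []
    sents = sentence_spans(norm)
    neg_spans = _term_occurrences(norm, lexicon.negation_terms)
    organ_spans = _term_occurrences(norm, lexicon.organ_terms)

    matches: list[KeywordMatch] = []
    for entry in lexicon.entries:
        for surface in entry.variants:
            for span in find_occurrences(norm, normalize_term(surface)):
                sent = sents[sentence_index(sents, span[0])]
                matches.append(
                    KeywordMatch(
                        canonical=entry.canonical,
                        surface=surface,
                        span=span,
                        negated=_negated(span, neg_spans, sent, config),
                        other_organ=_other_organ(span, organ_spans, sent, config),
                    )
                )
    matches.sort(key=lambda m: (m.span, m.canonical))
    return matches


def effective_presences(matches: Sequence[KeywordMatch]) -> set[str]:
    return {m.canonical for m in matches if m.effective_presence}


def score_findings(
    findings_text: str, lexicon: KeywordLexicon, config: ScreenConfig | None = None
) -> float:
    """Likelihood-ratio-product IP score of a findings field.

    PRESENCE_ABSENCE mode multiplies LR+ for effectively present keywords
    and LR- for the rest of the lexicon; PRESENT_ONLY multiplies LR+ over
    present keywords only (empty product = 1). Computed in log space.
    """
    config = config or ScreenConfig()
    present = effective_presences(find_matches(findings_text, lexicon, config))
    log_score = 0.0
    for entry in lexicon.entries:
        if entry.canonical in present:
            log_score += math.log(entry.lr_pos)
        elif config.scoring_mode is ScoringMode.PRESENCE_ABSENCE:
            log_score += math.log(entry.lr_neg)
    return math.exp(log_score)


def judge_diagnosis_field(
    diagnosis_text: str, lexicon: KeywordLexicon, config: ScreenConfig | None = None
) -> bool:
    """Diagnosis-field IP flag.

    Set when an IP diagnosis term (or synonym such as UIP/AIP) appears and
    is not negated; cleared — with precedence — when an exclusion diagnosis
    (IP mimic or non-drug-related IP subtype) appears.
    """
    config = config or ScreenConfig()
    norm = normalize_text(diagnosis_text)
    if not norm:
        return False
    for term in lexicon.exclusion_diagnosis_terms:
        if find_occurrences(norm, normalize_term(term)):
            return False
    sents = sentence_spans(norm)
    neg_spans = _term_occurrences(norm, lexicon.negation_terms)
    for term in lexicon.ip_diagnosis_terms:
        for span in find_occurrences(norm, normalize_term(term)):
            sent = sents[sentence_index(sents, span[0])]
            if not _negated(span, neg_spans, sent, config):
                return True
    return False


def classify_report(
    report: RadiologyReport,
    lexicon: KeywordLexicon,
    cutoff: float,
    config: ScreenConfig | None = None,
) -> ReportJudgment:
    """Combine both free-text fields into a report-level IP call.

    The findings flag is ``score >= cutoff`` (the same >= convention used
    when evaluating ROC candidate thresholds); IP is called when either
    field flags it.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    config = config or ScreenConfig()
    matches = tuple(find_matches(report.findings_text, lexicon, config))
    present = effective_presences(matches)
    log_score = 0.0
    for entry in lexicon.entries:
        if entry.canonical in present:
            log_score += math.log(entry.lr_pos)
        elif config.scoring_mode is ScoringMode.PRESENCE_ABSENCE:
            log_score += math.log(entry.lr_neg)
    score = math.exp(log_score)
    return ReportJudgment(
        report_id=report.report_id,
        ip_score=score,
        diagnosis_flag=judge_diagnosis_field(report.diagnosis_text, lexicon, config),
        findings_flag=score >= cutoff,
        matches=matches,
    )


def select_cutoff(scores: Sequence[float], labels: Sequence[bool]) -> RocCutoff:
    """ROC cutoff nearest to the ideal point (FPR, TPR) = (0, 1).

    Candidate thresholds are the distinct observed scores; a report is
    called positive when its score >= threshold. Ties in Euclidean distance
    to (0, 1) are broken toward higher specificity, then higher threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to select a cutoff")

    best: RocCutoff | None = None
    for t in np.unique(s):
        pred = s >= t
        sens = float((pred & y).sum()) / n_pos
        spec = float((~pred & ~y).sum()) / n_neg
        dist = math.hypot(1.0 - sens, 1.0 - spec)
        cand = RocCutoff(float(t), sens, spec, dist)
        if (
            best is None
            or cand.distance_to_ideal < best.distance_to_ideal - 1e-12
            or (
                abs(cand.distance_to_ideal - best.distance_to_ideal) <= 1e-12
                and (
                    cand.specificity_at_cutoff > best.specificity_at_cutoff + 1e-12
                    or (
                        abs(cand.specificity_at_cutoff - best.specificity_at_cutoff)
                        <= 1e-12
                        and cand.cutoff > best.cutoff
                    )
                )
            )
        ):
            best = cand
    assert best is not None
    return best


def evaluate(predicted: Sequence[bool], gold: Sequence[bool]) -> ConfusionMatrix:
    """Cross-tabulate predicted vs gold IP calls."""
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold must have equal length")
    tp = fp = fn = tn = 0
    for p, g in zip(predicted, gold):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
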