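"""Keyword lexicon training.

A lexicon is trained per imaging modality from a radiologist-labeled report
corpus. Keywords characteristic of interstitial pneumonia (IP) are selected
by their IP-report frequency; each selected keyword's positive and negative
likelihood ratios are estimated from a 2x2 report-presence contingency
table, treating the keyword as a diagnostic test for IP:

    LR+ = sensitivity / (1 - specificity)
    LR- = (1 - sensitivity) / specificity

Presence is counted once per report, after mapping synonym/abbreviation
surface forms (e.g. "frosted glass" == "ground glass", "UIP", "AIP") onto
canonical keywords. Zero contingency cells, which would make a ratio zero
or infinite, receive a Haldane-Anscombe-style continuity correction: the
configured ``smoothing`` constant is added to all four cells.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, model_validator

from .config import ScreenConfig
from .models import Modality, RadiologyReport
from .text import contains_term

logger = logging.getLogger(__name__)


class KeywordEntry(BaseModel):
    """One lexicon keyword with its estimated likelihood ratios."""

    canonical: str
    variants: tuple[str, ...]
    n_ip: int = 0
    n_nonip: int = 0
    lr_pos: float
    lr_neg: float

    @model_validator(mode="after")
    def _check(self) -> "KeywordEntry":
        if self.canonical not in self.variants:
            object.__setattr__(self, "variants", (self.canonical, *self.variants))
        if self.lr_pos <= 0 or self.lr_neg <= 0:
            raise ValueError("likelihood ratios must be strictly positive")
        if self.n_ip < 0 or self.n_nonip < 0:
            raise ValueError("presence counts must be nonnegative")
        return self


class KeywordLexicon(BaseModel):
    """Modality-specific keyword lexicon plus auxiliary term lists.

    ``negation_terms`` mark a nearby keyword as absent; ``organ_terms`` are
    non-lung organ names that disqualify a nearby keyword; the diagnosis
    term lists drive the diagnosis-field flag (IP synonyms set it, mimic /
    non-drug-related diagnoses clear it).
    """

    modality: Modality
    entries: tuple[KeywordEntry, ...] = ()
    negation_terms: tuple[str, ...] = ()
    organ_terms: tuple[str, ...] = ()
    ip_diagnosis_terms: tuple[str, ...] = ()
    exclusion_diagnosis_terms: tuple[str, ...] = ()
    n_ip_total: int = 0
    n_nonip_total: int = 0

    @model_validator(mode="after")
    def _unique_canonicals(self) -> "KeywordLexicon":
        names = [e.canonical for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("lexicon entries must have unique canonicals")
        return self

    def entry(self, canonical: str) -> KeywordEntry:
        for e in self.entries:
            if e.canonical == canonical:
                return e
        raise KeyError(canonical)


def compute_likelihood_ratios(
    n_ip_with: float,
    n_ip_total: float,
    n_nonip_with: float,
    n_nonip_total: float,
    smoothing: float = 0.5,
) -> tuple[float, float]:
    """Positive and negative likelihood ratios from report-presence counts.

    If any cell of the 2x2 table (with/without x IP/non-IP) is zero — which
    would force a zero or infinite ratio — ``smoothing`` is added to all
    four cells before computing.
    """
    if min(n_ip_with, n_nonip_with) < 0 or n_ip_total <= 0 or n_nonip_total <= 0:
        raise ValueError("counts must be nonnegative with positive totals")
    if n_ip_with > n_ip_total or n_nonip_with > n_nonip_total:
        raise ValueError("presence count exceeds group total")
    a = float(n_ip_with)           # IP, keyword present
    b = float(n_ip_total - n_ip_with)
    c = float(n_nonip_with)        # non-IP, keyword present
    d = float(n_nonip_total - n_nonip_with)
    if min(a, b, c, d) == 0:
        if smoothing <= 0:
            raise ZeroDivisionError(
                "zero contingency cell with no smoothing configured"
            )
        a, b, c, d = a + smoothing, b + smoothing, c + smoothing, d + smoothing
    sens = a / (a + b)
    spec = d / (c + d)
    return sens / (1.0 - spec), (1.0 - sens) / spec


def _presence_counts(
    reports: Sequence[RadiologyReport],
    synonym_map: Mapping[str, Iterable[str]],
) -> Counter:
    """Per-canonical count of reports whose findings contain any variant."""
    counts: Counter = Counter()
    for rep in reports:
        for canonical, variants in synonym_map.items():
            surfaces = set(variants) | {canonical}
            if any(contains_term(rep.findings_text, v) for v in surfaces):
                counts[canonical] += 1
    return counts


def select_keywords(
    corpus: Sequence[RadiologyReport],
    synonym_map: Mapping[str, Iterable[str]],
    min_ip_report_count: int = 10,
) -> list[str]:
    """Canonical keywords present in strictly more than ``min_ip_report_count``
    IP-labeled reports (report-level presence after canonicalization)."""
    ip_reports = [r for r in corpus if r.gold_ip is True]
    if not ip_reports:
        raise ValueError("corpus contains no IP-labeled reports")
    counts = _presence_counts(ip_reports, synonym_map)
    selected = [c for c, n in counts.items() if n > min_ip_report_count]
    return sorted(selected, key=lambda c: (-counts[c], c))


def train_lexicon(
    corpus: Sequence[RadiologyReport],
    synonym_map: Mapping[str, Iterable[str]],
    negation_terms: Sequence[str] = (),
    organ_terms: Sequence[str] = (),
    ip_diagnosis_terms: Sequence[str] = (),
    exclusion_diagnosis_terms: Sequence[str] = (),
    config: ScreenConfig | None = None,
) -> KeywordLexicon:
    """Train a lexicon from a labeled single-modality corpus.

    Deterministic given inputs; invariant under report order permutation.
    """
    config = config or ScreenConfig()
    modalities = {r.modality for r in corpus}
    if len(modalities) != 1:
        raise ValueError(f"corpus must be single-modality, got {modalities}")
    ip_reports = [r for r in corpus if r.gold_ip is True]
    nonip_reports = [r for r in corpus if r.gold_ip is False]
    if not ip_reports or not nonip_reports:
        raise ValueError("corpus must contain both IP and non-IP labeled reports")

    selected = select_keywords(corpus, synonym_map, config.min_ip_report_count)
    if not selected:
        logger.warning(
            "no keyword exceeded the IP-report threshold of %d",
            config.min_ip_report_count,
        )
    ip_counts = _presence_counts(ip_reports, synonym_map)
    nonip_counts = _presence_counts(nonip_reports, synonym_map)

    entries = []
    for canonical in selected:
        n_ip = ip_counts.get(canonical, 0)
        n_nonip = nonip_counts.get(canonical, 0)
        lr_pos, lr_neg = compute_likelihood_ratios(
            n_ip, len(ip_reports), n_nonip, len(nonip_reports), config.smoothing
        )
        entries.append(
            KeywordEntry(
                canonical=canonical,
                variants=tuple(sorted(set(synonym_map[canonical]) | {canonical})),
                n_ip=n_ip,
                n_nonip=n_nonip,
                lr_pos=lr_pos,
                lr_neg=lr_neg,
            )
        )
    return KeywordLexicon(
        modality=modalities.pop(),
        entries=tuple(entries),
        negation_terms=tuple(negation_terms),
        organ_terms=tuple(organ_terms),
        ip_diagnosis_terms=tuple(ip_diagnosis_terms),
        exclusion_diagnosis_terms=tuple(exclusion_diagnosis_terms),
        n_ip_total=len(ip_reports),
        n_nonip_total=len(nonip_reports),
    )
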