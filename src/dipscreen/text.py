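"""Low-level text matching: normalization, sentence spans, term occurrences.

Matching is language-agnostic substring matching of surface forms after
case/whitespace normalization. Normalization is length-preserving so that
character offsets reported by matchers refer to the original text. A
pluggable tokenizer can replace :func:`find_occurrences` for languages
where substring matching over-fires.
"""

from __future__ import annotations

import re
from typing import Callable

#: sentence terminators: ASCII and CJK full stops, question/exclamation, newlines
_SENT_BREAK = set(".!?。．\n")

TermFinder = Callable[[str, str], list[tuple[int, int]]]


def normalize_text(text: str) -> str:
    """Length-preserving normalization: lowercase, any whitespace -> space.

    Characters whose lowercase form changes length are left as-is so that
    offsets into the normalized string are valid in the original.
    """
    out = []
    for ch in text:
        if ch.isspace() and ch != "\n":
            out.append(" ")
        else:
            low = ch.lower()
            out.append(low if len(low) == 1 else ch)
    return "".join(out)


def normalize_term(term: str) -> str:
    """Lowercase and collapse internal whitespace to single spaces."""
    return re.sub(r"\s+", " ", term.strip()).lower()


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of sentences; terminators end a sentence."""
    spans = []
    start = 0
    for i, ch in enumerate(text):
        if ch in _SENT_BREAK:
            spans.append((start, i + 1))
            start = i + 1
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def sentence_index(spans: list[tuple[int, int]], pos: int) -> int:
    """Index of the sentence containing character position ``pos``."""
    for i, (s, e) in enumerate(spans):
        if s <= pos < e:
            return i
    return len(spans) - 1


def find_occurrences(norm_text: str, norm_term: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) occurrences of ``norm_term`` in ``norm_text``."""
    if not norm_term:
        return []
    out = []
    start = 0
    while True:
        i = norm_text.find(norm_term, start)
        if i < 0:
            return out
        out.append((i, i + len(norm_term)))
        start = i + 1


def span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Characters strictly between two spans (0 if they touch or overlap)."""
    if b[0] >= a[1]:
        return b[0] - a[1]
    if a[0] >= b[1]:
        return a[0] - b[1]
    return 0


def contains_term(text: str, term: str) -> bool:
    """Raw normalized substring presence (no negation/organ logic)."""
    return bool(find_occurrences(normalize_text(text), normalize_term(term)))
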