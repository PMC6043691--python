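"""Screen configuration.

All tunables of the screening algorithm live here so a run is fully
described by (input files, lexicons, config, cutoffs).
"""

from __future__ import annotations

import enum
from pathlib import Path

import yaml
from pydantic import BaseModel, field_validator


class ScoringMode(str, enum.Enum):
    #: every lexicon keyword contributes: LR+ if effectively present, LR- if not
    PRESENCE_ABSENCE = "PRESENCE_ABSENCE"
    #: only effectively present keywords contribute their LR+ (empty product = 1)
    PRESENT_ONLY = "PRESENT_ONLY"


class NegationDirection(str, enum.Enum):
    AFTER = "AFTER"
    BIDIRECTIONAL = "BIDIRECTIONAL"


class ScreenConfig(BaseModel):
    """Tunable parameters of the DIP screen.

    Windows are measured in characters; day counts in calendar days. The
    biomarker upper limits of normal are site-configurable (KL-6 in U/mL,
    SP-D in ng/mL).
    """

    negation_window: int = 15
    organ_window: int = 15
    negation_direction: NegationDirection = NegationDirection.AFTER
    order_merge_gap_days: int = 30
    washout_days: int = 30
    kl6_upper_limit: float = 500.0
    spd_upper_limit: float = 110.0
    scoring_mode: ScoringMode = ScoringMode.PRESENCE_ABSENCE
    min_ip_report_count: int = 10
    smoothing: float = 0.5
    #: require fallback evidence (X-ray / KL-6 / SP-D) to agree with CT in some
    #: period and to vary across periods before it is adopted
    concordance_check: bool = True

    @field_validator(
        "negation_window", "organ_window", "order_merge_gap_days", "washout_days"
    )
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("windows and day counts must be positive")
        return v

    @field_validator("smoothing")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("smoothing must be >= 0")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
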