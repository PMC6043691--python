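"""Drug exposure episodes and observation periods.

Raw drug orders are coalesced into administration episodes: consecutive
orders of the same drug separated by a non-administration gap of at most
``order_merge_gap_days`` (days strictly between one order's end and the
next order's start) belong to one episode. Around each episode three
observation periods are laid out:

* pre-administration:   every day up to the day before the episode start
* administration:       episode start through ``washout_days`` after the
                        episode end (new IP in this washout tail is still
                        attributed to the drug)
* post-administration:  the day after the administration period through the
                        censoring date, truncated the day before any next
                        episode of the same drug starts
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

from pydantic import BaseModel, model_validator

from .models import DrugOrder

ONE_DAY = dt.timedelta(days=1)


class Episode(BaseModel):
    """One merged administration episode."""

    model_config = {"frozen": True}

    patient_id: str
    drug_code: str
    start: dt.date
    end: dt.date


class DrugExposure(BaseModel):
    """An episode with its three observation-period boundaries.

    ``post_start``/``post_end`` are None when the post period is empty
    (censoring falls inside the administration period, or the next episode
    starts immediately).
    """

    patient_id: str
    drug_code: str
    episode_start: dt.date
    episode_end: dt.date
    during_end: dt.date
    post_start: Optional[dt.date] = None
    post_end: Optional[dt.date] = None

    @model_validator(mode="after")
    def _ordered(self) -> "DrugExposure":
        if not (self.episode_start <= self.episode_end < self.during_end):
            raise ValueError("require episode_start <= episode_end < during_end")
        if (self.post_start is None) != (self.post_end is None):
            raise ValueError("post period boundaries must both be set or both None")
        if self.post_start is not None:
            if self.post_start != self.during_end + ONE_DAY:
                raise ValueError("post period must start the day after during_end")
            if self.post_end < self.post_start:
                raise ValueError("post period end before start")
        return self

    @property
    def pre_end(self) -> dt.date:
        return self.episode_start - ONE_DAY

    def assign_period(self, date: dt.date) -> Optional[str]:
        """Period ('pre'|'during'|'post') containing a calendar day, else None."""
        if date <= self.pre_end:
            return "pre"
        if date <= self.during_end:
            return "during"
        if self.post_start is not None and self.post_start <= date <= self.post_end:
            return "post"
        return None


def merge_orders(
    orders: Sequence[DrugOrder], merge_gap_days: int = 30
) -> list[Episode]:
    """Coalesce one patient's orders of one drug into episodes.

    Orders are sorted by start date; an order whose non-administration gap
    to the running episode (days strictly between the episode end and the
    order start) is <= ``merge_gap_days`` extends it. Idempotent and
    invariant under input permutation.
    """
    if not orders:
        return []
    patients = {o.patient_id for o in orders}
    drugs = {o.drug_code for o in orders}
    if len(patients) != 1 or len(drugs) != 1:
        raise ValueError("merge_orders expects orders of one patient and one drug")
    pid, drug = patients.pop(), drugs.pop()

    ordered = sorted(orders, key=lambda o: (o.start_date, o.end_date))
    episodes: list[Episode] = []
    cur_start, cur_end = ordered[0].start_date, ordered[0].end_date
    for o in ordered[1:]:
        gap = (o.start_date - cur_end).days - 1
        if gap <= merge_gap_days:
            cur_end = max(cur_end, o.end_date)
        else:
            episodes.append(
                Episode(patient_id=pid, drug_code=drug, start=cur_start, end=cur_end)
            )
            cur_start, cur_end = o.start_date, o.end_date
    episodes.append(
        Episode(patient_id=pid, drug_code=drug, start=cur_start, end=cur_end)
    )
    return episodes


def build_periods(
    episode: Episode,
    washout_days: int = 30,
    censor_date: dt.date | None = None,
    next_episode_start: dt.date | None = None,
) -> DrugExposure:
    """Lay out pre/during/post periods around one episode.

    ``censor_date`` (required) bounds the post period; it must not precede
    the episode end. The post period is empty when the administration
    period already reaches the censor date, and is truncated the day before
    ``next_episode_start`` to keep evidence attribution unambiguous.
    """
    if censor_date is None:
        raise ValueError("censor_date is required")
    if censor_date < episode.end:
        raise ValueError(
            f"censor date {censor_date} precedes episode end {episode.end}"
        )
    during_end = episode.end + dt.timedelta(days=washout_days)
    post_start: Optional[dt.date] = during_end + ONE_DAY
    post_end: Optional[dt.date] = censor_date
    if next_episode_start is not None:
        post_end = min(post_end, next_episode_start - ONE_DAY)
    if during_end >= censor_date or post_end < post_start:
        post_start = post_end = None
    return DrugExposure(
        patient_id=episode.patient_id,
        drug_code=episode.drug_code,
        episode_start=episode.start,
        episode_end=episode.end,
        during_end=during_end,
        post_start=post_start,
        post_end=post_end,
    )


def build_exposures(
    orders: Sequence[DrugOrder],
    merge_gap_days: int = 30,
    washout_days: int = 30,
    censor_date: dt.date | None = None,
) -> list[DrugExposure]:
    """Merge a mixed order stream and build periods per patient x drug."""
    by_key: dict[tuple[str, str], list[DrugOrder]] = {}
    for o in orders:
        by_key.setdefault((o.patient_id, o.drug_code), []).append(o)
    exposures: list[DrugExposure] = []
    for key in sorted(by_key):
        episodes = merge_orders(by_key[key], merge_gap_days)
        for i, ep in enumerate(episodes):
            nxt = episodes[i + 1].start if i + 1 < len(episodes) else None
            exposures.append(
                build_periods(ep, washout_days, censor_date, next_episode_start=nxt)
            )
    return exposures
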