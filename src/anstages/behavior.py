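"""Circadian and calendar posting-pattern statistics.

The central statistic is the sleep-time tweets ratio (STTR): the day is cut
into eight fixed 3-hour slots, tweet counts ``t_i`` are accumulated per
slot, and the sums over the eight cyclically adjacent slot pairs (the first
and last slots are continuous) are formed.  The minimum pair sum, normalized
by the user's total tweet count ``T``, estimates the fraction of activity in
the user's 6-hour sleep window without knowing their timezone — STTR is
invariant under cyclic rotation of the slots.  DTTR = 1 - STTR is the awake
counterpart.  Alongside these we compute weekday/weekend ratios, ratios per
year quarter (Dec–Feb, Mar–May, Jun–Aug, Sep–Nov), the median inter-tweet
gap in seconds, and the total count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd

SECONDS_PER_SLOT = 3 * 3600
N_SLOTS = 8

#: calendar months of each named quarter, in reporting order
QUARTERS = (
    ("dec_feb", (12, 1, 2)),
    ("mar_may", (3, 4, 5)),
    ("jun_aug", (6, 7, 8)),
    ("sep_nov", (9, 10, 11)),
)
_MONTH_TO_QUARTER = {m: qi for qi, (_, months) in enumerate(QUARTERS) for m in months}


@dataclass
class SlotCounts:
    t: list[int]
    T: int

    def __post_init__(self) -> None:
        if len(self.t) != N_SLOTS:
            raise ValueError(f"t: expected {N_SLOTS} slots, got {len(self.t)}")
        if sum(self.t) != self.T:
            raise ValueError("t: slot counts do not sum to T")


def slot_counts(timestamps: Sequence[int]) -> SlotCounts:
    """Count tweets per fixed 3-hour UTC slot (slot 0 = 00:00–03:00)."""
    t = [0] * N_SLOTS
    for ts in timestamps:
        t[(int(ts) % 86400) // SECONDS_PER_SLOT] += 1
    return SlotCounts(t, len(timestamps))


def sttr(counts: SlotCounts) -> float:
    """Sleep-time tweets ratio: min over the 8 wraparound-adjacent slot-pair
    sums, divided by the total count.  Undefined (NaN) for T = 0."""
    if counts.T == 0:
        return math.nan
    t = counts.t
    min_pair = min(t[i] + t[(i + 1) % N_SLOTS] for i in range(N_SLOTS))
    return min_pair / counts.T


def dttr(counts: SlotCounts) -> float:
    """Day-time tweets ratio, the complement of :func:`sttr`."""
    s = sttr(counts)
    return math.nan if math.isnan(s) else 1.0 - s


def _utc(ts: int) -> datetime:
    return datetime.fromtimestamp(int(ts), tz=timezone.utc)


def week_ratios(timestamps: Sequence[int]) -> tuple[float, float]:
    """(weekday_ratio, weekend_ratio): Mon–Fri vs Sat–Sun share of tweets,
    day-of-week taken in UTC."""
    if not timestamps:
        return math.nan, math.nan
    weekend = sum(1 for ts in timestamps if _utc(ts).weekday() >= 5)
    T = len(timestamps)
    return (T - weekend) / T, weekend / T


def quarter_ratios(timestamps: Sequence[int]) -> tuple[float, float, float, float]:
    """Share of tweets in each named year quarter; sums to 1 for T >= 1."""
    if not timestamps:
        return (math.nan,) * 4
    counts = [0] * 4
    for ts in timestamps:
        counts[_MONTH_TO_QUARTER[_utc(ts).month]] += 1
    T = len(timestamps)
    return tuple(c / T for c in counts)  # type: ignore[return-value]


def median_gap_seconds(timestamps: Sequence[int]) -> float:
    """Median of successive differences of the sorted timestamps; requires
    at least two tweets."""
    if len(timestamps) < 2:
        return math.nan
    ts = np.sort(np.asarray(timestamps, dtype=np.int64))
    return float(np.median(np.diff(ts)))


@dataclass
class BehavioralProfile:
    sttr: float
    dttr: float
    weekday_ratio: float
    weekend_ratio: float
    quarter_ratios: tuple[float, float, float, float]
    median_gap_seconds: float
    total_tweets: int
    slot_counts: SlotCounts


def behavioral_profile(timestamps: Sequence[int]) -> BehavioralProfile:
    counts = slot_counts(timestamps)
    wk, we = week_ratios(timestamps)
    return BehavioralProfile(
        sttr=sttr(counts), dttr=dttr(counts),
        weekday_ratio=wk, weekend_ratio=we,
        quarter_ratios=quarter_ratios(timestamps),
        median_gap_seconds=median_gap_seconds(timestamps),
        total_tweets=counts.T, slot_counts=counts,
    )


def behavioral_table(cohort) -> pd.DataFrame:
    """One behavioral-feature row per user (NaN where undefined)."""
    rows = {}
    for uid, u in cohort.users.items():
        p = behavioral_profile(u.timestamps())
        row = {
            "sttr": p.sttr, "dttr": p.dttr,
            "weekday_ratio": p.weekday_ratio, "weekend_ratio": p.weekend_ratio,
            "median_gap_seconds": p.median_gap_seconds,
            "total_tweets": p.total_tweets,
        }
        for (name, _), val in zip(QUARTERS, p.quarter_ratios):
            row[f"quarter_{name}"] = val
        rows[uid] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("user_id")
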