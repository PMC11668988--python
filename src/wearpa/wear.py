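"""Sleep-window exclusion and valid-day / valid-week classification.

A valid wear day is a midnight-anchored calendar day that, after removal of
the overnight presumed-sleep window, retains at least 600 minutes bearing a
heart-rate value and at least 100 total steps.  Days are grouped into 7-day
intervals anchored on January 1 of each year; a week is valid when it holds
at least 3 valid days, and a participant is included when they have at least
one valid week.  The 1-2 day remainder after 52 such intervals belongs to no
week.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "DayRecord",
    "WeekRecord",
    "WearCalendar",
    "exclude_sleep_window",
    "classify_day",
    "assign_week",
    "week_start_date",
    "build_wear_calendar",
]

WEEKS_PER_YEAR = 52  # 52 x 7 = 364; the year-end remainder maps to no week


@dataclass(frozen=True)
class DayRecord:
    hr_minutes: int
    step_total: float
    is_valid: bool


@dataclass(frozen=True)
class WeekRecord:
    valid_day_count: int
    is_valid: bool
    valid_days: Tuple[dt.date, ...] = ()


@dataclass
class WearCalendar:
    """Per-participant map of day and week wear validity."""

    participant_id: str
    day_records: Dict[dt.date, DayRecord] = field(default_factory=dict)
    week_records: Dict[Tuple[int, int], WeekRecord] = field(default_factory=dict)

    @property
    def valid_weeks(self) -> List[Tuple[int, int]]:
        return sorted(k for k, w in self.week_records.items() if w.is_valid)

    @property
    def include(self) -> bool:
        """Participant enters the analysis iff they have >=1 valid week."""
        return any(w.is_valid for w in self.week_records.values())


def exclude_sleep_window(
    minutes: pd.DataFrame, config: PipelineConfig
) -> Tuple[pd.DataFrame, int]:
    """Drop records whose clock time falls in the overnight sleep window.

    The window is half-open [start, end): a record stamped exactly at the
    window start is removed, one stamped exactly at the end is kept.
    Returns the surviving frame and the number of removed records.
    """
    if minutes.empty:
        return minutes.copy(), 0
    minute_of_day = (
        minutes["datetime"].dt.hour * 60 + minutes["datetime"].dt.minute
    ).to_numpy()
    start = config.sleep_window_start.hour * 60 + config.sleep_window_start.minute
    end = config.sleep_window_end.hour * 60 + config.sleep_window_end.minute
    in_window = (minute_of_day >= start) | (minute_of_day < end)
    kept = minutes.loc[~in_window].reset_index(drop=True)
    return kept, int(in_window.sum())


def classify_day(
    day_minutes: pd.DataFrame, config: PipelineConfig
) -> DayRecord:
    """Summarise one midnight-anchored day (sleep window already excluded).

    Heart-rate minutes count records with a non-missing heart rate; the step
    total sums non-missing steps (a missing-step minute still contributes its
    heart rate).  Both validity thresholds are inclusive.
    """
    hr_minutes = int(day_minutes["heart_rate"].notna().sum())
    step_total = float(day_minutes["steps"].fillna(0).sum())
    is_valid = (
        hr_minutes >= config.min_hr_minutes_per_day
        and step_total >= config.min_steps_per_day
    )
    return DayRecord(hr_minutes=hr_minutes, step_total=step_total, is_valid=is_valid)


def assign_week(
    date: dt.date, config: Optional[PipelineConfig] = None
) -> Optional[Tuple[int, int]]:
    """Map a calendar day to its (year, week-index) 7-day interval.

    Intervals start on January 1 of each year; week 1 covers days 1-7 of the
    year.  Days beyond day 364 (the 1-2 day remainder) map to no week.
    """
    doy = date.timetuple().tm_yday
    week = (doy - 1) // 7 + 1
    if week > WEEKS_PER_YEAR:
        return None
    return date.year, week


def week_start_date(year: int, week: int) -> dt.date:
    """First calendar day of a (year, week-index) interval."""
    if not 1 <= week <= WEEKS_PER_YEAR:
        raise ValueError(f"week index must be in 1..{WEEKS_PER_YEAR}, got {week}")
    return dt.date(year, 1, 1) + dt.timedelta(days=7 * (week - 1))


def build_wear_calendar(
    minutes: pd.DataFrame, participant_id: str, config: PipelineConfig
) -> WearCalendar:
    """Classify every observed day and week for one participant.

    Expects the sleep window to be excluded and under-18 records dropped
    already.  Remainder days (no week assignment) still get day records but
    never contribute to any week.
    """
    calendar = WearCalendar(participant_id=participant_id)
    if minutes.empty:
        return calendar

    by_day = minutes.groupby(minutes["datetime"].dt.date, sort=True)
    week_days: Dict[Tuple[int, int], List[dt.date]] = {}
    for day, group in by_day:
        record = classify_day(group, config)
        calendar.day_records[day] = record
        week = assign_week(day, config)
        if week is not None:
            week_days.setdefault(week, [])
            if record.is_valid:
                week_days[week].append(day)

    for week, valid_days in week_days.items():
        count = len(valid_days)
        calendar.week_records[week] = WeekRecord(
            valid_day_count=count,
            is_valid=count >= config.min_valid_days_per_week,
            valid_days=tuple(sorted(valid_days)),
        )
    return calendar
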