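"""Small calendar helpers shared across modules."""

from __future__ import annotations

import datetime as dt

__all__ = ["add_years", "completed_years"]


def add_years(day: dt.date, years: int) -> dt.date:
    """Return the anniversary of ``day`` ``years`` later.

    Feb 29 anniversaries fall on Mar 1 in non-leap years, matching the common
    legal convention for birthdays.
    """
    try:
        return day.replace(year=day.year + years)
    except ValueError:  # Feb 29 -> Mar 1
        return dt.date(day.year + years, 3, 1)


def completed_years(birth_date: dt.date, on_date: dt.date) -> int:
    """Age in completed years on ``on_date``."""
    years = on_date.year - birth_date.year
    if (on_date.month, on_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years
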