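"""Calendar-date helpers shared by all pipeline stages.

All intervals in the package are closed (inclusive at both ends) unless a
function says otherwise. Ages are completed years. A Feb-29 birthday rolls to
Mar-1 in non-leap years when computing the date a given age is attained.
"""
from __future__ import annotations

import datetime as dt
import re

_DMY = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")


class DateParseError(ValueError):
    """Raised when a date string cannot be interpreted."""


def parse_date(text: str, allow_dayfirst: bool = False) -> dt.date:
    """Parse an ISO-8601 date; optionally also accept DD/MM/YYYY.

    Data files use ISO-8601 only. Study-design configs additionally accept
    the DD/MM/YYYY convention common in UK study protocols.
    """
    s = text.strip()
    try:
        return dt.date.fromisoformat(s)
    except ValueError:
        pass
    if allow_dayfirst:
        m = _DMY.match(s)
        if m:
            day, month, year = (int(g) for g in m.groups())
            try:
                return dt.date(year, month, day)
            except ValueError as exc:
                raise DateParseError(f"invalid calendar date: {text!r}") from exc
    raise DateParseError(f"unparseable date: {text!r}")


def add_years(d: dt.date, years: int) -> dt.date:
    """``d`` plus ``years`` calendar years; Feb-29 rolls to Mar-1."""
    try:
        return d.replace(year=d.year + years)
    except ValueError:  # Feb 29 in a non-leap target year
        return dt.date(d.year + years, 3, 1)


def age_in_years(birth: dt.date, on: dt.date) -> int:
    """Age in completed years on a given date (negative before birth)."""
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def attain_age_date(birth: dt.date, age_years: int) -> dt.date:
    """First date on which the person is ``age_years`` old (completed years)."""
    return add_years(birth, age_years)


def last_day_at_age(birth: dt.date, age_years: int) -> dt.date:
    """Last date on which completed age is still <= ``age_years``."""
    return add_years(birth, age_years + 1) - dt.timedelta(days=1)


def fmt(d: dt.date | None) -> str:
    return "" if d is None else d.isoformat()
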