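"""365-day (no-leap) calendar arithmetic shared by all gridded stages.

All synthetic climate series live on a fixed no-leap calendar: every year has
exactly 365 days, so array reshapes between (time,) and (year, day, step) are
exact and GCM calendar dialects never leak into index arithmetic.  Dates are
exchanged with CSV files as ISO-8601 strings using non-leap month lengths
(Feb 29 never occurs; external leap-day records map to Feb 28 upstream).
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365

_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_STARTS = np.concatenate([[0], np.cumsum(_MONTH_LENGTHS)])  # 0-based doy


def doy_to_month_day(doy: int) -> tuple[int, int]:
    """Convert day-of-year (1..365) to (month, day) in the no-leap calendar."""
    if not 1 <= doy <= DAYS_PER_YEAR:
        raise ValueError(f"day-of-year {doy} outside 1..{DAYS_PER_YEAR}")
    month = int(np.searchsorted(_MONTH_STARTS, doy, side="left")) - 1
    return month + 1, doy - int(_MONTH_STARTS[month])


def month_day_to_doy(month: int, day: int) -> int:
    if not 1 <= month <= 12 or not 1 <= day <= int(_MONTH_LENGTHS[month - 1]):
        raise ValueError(f"invalid no-leap date month={month} day={day}")
    return int(_MONTH_STARTS[month - 1]) + day


def month_of_doy(doy: np.ndarray | int) -> np.ndarray | int:
    """Vectorised month (1..12) for day-of-year (1..365)."""
    return np.searchsorted(_MONTH_STARTS, doy, side="left").astype(int)


def date_to_ordinal(year: int, doy: int) -> int:
    """Days since year 0, day 1 of the no-leap calendar (monotone over dates)."""
    return year * DAYS_PER_YEAR + (doy - 1)


def ordinal_to_date(ordinal: int) -> tuple[int, int]:
    year, rem = divmod(int(ordinal), DAYS_PER_YEAR)
    return year, rem + 1


def format_date(year: int, doy: int) -> str:
    month, day = doy_to_month_day(doy)
    return f"{year:04d}-{month:02d}-{day:02d}"


def parse_date(text: str) -> tuple[int, int]:
    """Parse an ISO-8601 date into (year, doy); Feb 29 folds to Feb 28."""
    year, month, day = (int(p) for p in text.split("-"))
    if month == 2 and day == 29:
        day = 28
    return year, month_day_to_doy(month, day)


def years_are_consecutive(years: list[int]) -> bool:
    return len(years) > 0 and list(years) == list(range(years[0], years[0] + len(years)))
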