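"""Surveillance-week arithmetic and the study calendar.

Weeks are integer indices counted from the study start week (index 0), each
covering a 7-day block aligned to the configured week convention.  The
maintenance window (system downtime) is a contiguous block of whole weeks; the
first week after it is the *disruption week* splitting the study into pre/post
periods (the downtime coincided with the end of the participation incentive,
so the two effects are analysed as a single disruption).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

WEEK_CONVENTIONS = ("sunday_start", "monday_start", "iso")


def _week_start(date: dt.date, convention: str) -> dt.date:
    """First day of the 7-day surveillance week containing ``date``."""
    if convention == "sunday_start":
        # date.weekday(): Monday=0 .. Sunday=6
        offset = (date.weekday() + 1) % 7
    elif convention in ("monday_start", "iso"):
        offset = date.weekday()
    else:
        raise ValueError(
            f"unknown week convention {convention!r}; expected one of {WEEK_CONVENTIONS}"
        )
    return date - dt.timedelta(days=offset)


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        return dt.date.fromisoformat(value)
    raise TypeError(f"cannot interpret {value!r} as a calendar date")


@dataclass(frozen=True)
class StudyCalendar:
    """Week grid for a participatory surveillance study.

    Parameters
    ----------
    study_start_date
        Any date inside week 0.  Default 2016-04-03, the first Sunday of the
        recruitment month.
    study_close_week
        Last week index with possible submissions (inclusive).  The default
        103 spans roughly 24 months: an 18-month participation commitment
        plus the 6 months the system stayed open afterwards.
    maintenance_start, maintenance_end
        First and last calendar day of the system downtime.  The defaults,
        2017-05-07 through 2017-07-15, are Sunday-to-Saturday aligned and
        span exactly 10 whole weeks under the ``sunday_start`` convention.
    week_convention
        ``sunday_start`` (epidemiological weeks, default), ``monday_start``
        or ``iso``.
    """

    study_start_date: dt.date = dt.date(2016, 4, 3)
    study_close_week: int = 103
    maintenance_start: dt.date = dt.date(2017, 5, 7)
    maintenance_end: dt.date = dt.date(2017, 7, 15)
    week_convention: str = "sunday_start"

    # derived, filled in __post_init__
    maintenance_weeks: frozenset = field(init=False)
    disruption_week: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "study_start_date", _as_date(self.study_start_date))
        object.__setattr__(self, "maintenance_start", _as_date(self.maintenance_start))
        object.__setattr__(self, "maintenance_end", _as_date(self.maintenance_end))
        if self.week_convention not in WEEK_CONVENTIONS:
            raise ValueError(
                f"unknown week convention {self.week_convention!r}; "
                f"expected one of {WEEK_CONVENTIONS}"
            )
        if self.maintenance_end < self.maintenance_start:
            raise ValueError("maintenance_end precedes maintenance_start")
        first = self.week_of(self.maintenance_start)
        last = self.week_of(self.maintenance_end)
        if first <= 0 or last >= self.study_close_week:
            raise ValueError(
                "maintenance window must lie strictly inside the study window"
            )
        object.__setattr__(self, "maintenance_weeks", frozenset(range(first, last + 1)))
        object.__setattr__(self, "disruption_week", last + 1)

    @property
    def study_start_week(self) -> int:
        return 0

    @property
    def origin(self) -> dt.date:
        """First day of week 0."""
        return _week_start(self.study_start_date, self.week_convention)

    def week_of(self, date) -> int:
        """Map a calendar date (or datetime) to its surveillance week index."""
        date = _as_date(date)
        return (_week_start(date, self.week_convention) - self.origin).days // 7

    def week_start_date(self, week: int) -> dt.date:
        """First day of the given surveillance week."""
        return self.origin + dt.timedelta(days=7 * int(week))

    def study_weeks(self) -> range:
        """All week indices in the study window, maintenance included."""
        return range(self.study_start_week, self.study_close_week + 1)

    def is_maintenance(self, week: int) -> bool:
        return week in self.maintenance_weeks


def week_of(date, calendar: StudyCalendar) -> int:
    """Functional alias for :meth:`StudyCalendar.week_of`."""
    return calendar.week_of(date)
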