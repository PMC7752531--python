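import datetime as dt
import itertools



import pandas as pd
import pytest

from flumob import StudyCalendar
from flumob.datatypes import SYMPTOM_COLUMNS


@pytest.fixture(scope="session")
def calendar():
    """Default study calendar: 104 weeks, 10-week maintenance at weeks 57-66."""
    return StudyCalendar()


@pytest.fixture(scope="session")
def small_calendar():
    """Short 21-week study with a single maintenance week (week 9)."""
    return StudyCalendar(
        study_start_date=dt.date(2016, 4, 3),
        study_close_week=20,
        maintenance_start=dt.date(2016, 6, 5),
        maintenance_end=dt.date(2016, 6, 11),
    )


_counter = itertools.count(1)


def make_cohort(n, calendar, enroll=0, followup=78, **covariates):
    """Minimal analysis-roster frame; covariates default to reference levels."""
    base = {
        "gender": "female", "age_group": "21-30", "job_category": "nursing",
        "ethnicity": "chinese", "children_in_household": False,
        "vaccinated_past_year": False, "allergy": False, "hospital": "TTSH",
        "registration_complete": True, "background_complete": True,
    }
    base.update(covariates)
    rows = []
    for _ in range(n):
        i = next(_counter)
        rows.append({
            "participant_id": f"T{i:05d}", **base,
            "enrollment_week": enroll, "study_end_week": enroll + followup,
            "enrollment_date": calendar.week_start_date(enroll),
            "study_end_date": calendar.week_start_date(enroll + followup),
        })
    return pd.DataFrame(rows)


def make_reports(entries, calendar):
    """Reports frame from (pid, week, symptoms, hour_offset) tuples.

    ``symptoms`` is an iterable of symptom names; ``hour_offset`` orders
    submissions within a week (default 12).
    """
    rows = []
    for entry in entries:
        pid, week, symptoms = entry[0], entry[1], entry[2]
        hours = entry[3] if len(entry) > 3 else 12
        row = {s: False for s in SYMPTOM_COLUMNS}
        for s in symptoms:
            row[s] = True
        row["participant_id"] = pid
        row["week"] = week
        row["submitted_at"] = pd.Timestamp(
            calendar.week_start_date(week)
        ) + pd.Timedelta(hours=hours)
        row["in_maintenance"] = week in calendar.maintenance_weeks
        rows.append(row)
    columns = ["participant_id", "submitted_at"] + list(SYMPTOM_COLUMNS) + [
        "week", "in_maintenance"]
    if not rows:
        return pd.DataFrame({c: [] for c in columns})
    return pd.DataFrame(rows)[columns]


def random_panel(rng, n_participants=5, n_weeks=12, p_report=0.7, p_ili=0.3):
    """Random deduplicated panel for oracle checks."""
    rows = []
    for i in range(n_participants):
        for w in range(n_weeks):
            if rng.random() < p_report:
                ili = rng.random() < p_ili
                rows.append({
                    "participant_id": f"R{i}", "week": w,
                    "is_ili": ili, "any_symptom": ili or rng.random() < 0.3,
                })
    if not rows:
        return pd.DataFrame(
            {"participant_id": [], "week": [], "is_ili": [], "any_symptom": []}
        )
    return pd.DataFrame(rows)


def count_runs(weeks):
    """Brute-force episode count: maximal runs of consecutive integers."""
    weeks = sorted(weeks)
    return sum(1 for i, w in enumerate(weeks) if i == 0 or w != weeks[i - 1] + 1)
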