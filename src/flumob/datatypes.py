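"""Domain types and column schemas.

The canonical in-memory containers are pandas DataFrames with the column
schemas defined here; the dataclasses provide row-level typed views with
validation, used by the CSV loaders to reject malformed rows.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, fields as dc_fields

# The 18 weekly questionnaire symptoms, in fixed order.
SYMPTOM_COLUMNS = (
    "fever",
    "chills",
    "runny_or_blocked_nose",
    "sneezing",
    "cough",
    "sore_throat",
    "shortness_of_breath",
    "muscle_or_joint_pain",
    "headache",
    "malaise",
    "loss_of_appetite",
    "colored_phlegm",
    "watery_bloodshot_eyes",
    "nausea",
    "vomiting",
    "diarrhea",
    "stomach_ache",
    "chest_pain",
)

# Strictly respiratory subset, available as an alternative retention-rule
# symptom set (the questionnaire groups gastrointestinal items under the same
# acute-respiratory heading, so the default retention set is all 18).
RESPIRATORY_SYMPTOMS = (
    "fever",
    "chills",
    "runny_or_blocked_nose",
    "sneezing",
    "cough",
    "sore_throat",
    "shortness_of_breath",
    "colored_phlegm",
    "watery_bloodshot_eyes",
    "chest_pain",
)

GENDER_LEVELS = ("female", "male")
AGE_LEVELS = ("21-30", "31-40", "41-50", ">50")
JOB_LEVELS = ("nursing", "administration_other", "ancillary", "allied_health", "medical")
ETHNICITY_LEVELS = ("chinese", "other")
HOSPITAL_LEVELS = ("TTSH", "KKH")

CATEGORICAL_LEVELS = {
    "gender": GENDER_LEVELS,
    "age_group": AGE_LEVELS,
    "job_category": JOB_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "hospital": HOSPITAL_LEVELS,
}

BOOLEAN_FIELDS = (
    "children_in_household",
    "vaccinated_past_year",
    "allergy",
    "registration_complete",
    "background_complete",
)

# Covariates entering the participation models, with their reference levels.
MODEL_COVARIATES = (
    "gender",
    "age_group",
    "job_category",
    "ethnicity",
    "children_in_household",
    "vaccinated_past_year",
    "allergy",
)
REFERENCE_LEVELS = {
    "gender": "female",
    "age_group": "21-30",
    "job_category": "nursing",
    "ethnicity": "chinese",
    "children_in_household": False,
    "vaccinated_past_year": False,
    "allergy": False,
}

ROSTER_COLUMNS = (
    "participant_id",
    "gender",
    "age_group",
    "job_category",
    "ethnicity",
    "children_in_household",
    "vaccinated_past_year",
    "allergy",
    "hospital",
    "enrollment_date",
    "study_end_date",
    "registration_complete",
    "background_complete",
)

REPORT_COLUMNS = ("participant_id", "submitted_at") + SYMPTOM_COLUMNS

REFERENCE_COLUMNS = ("week_start_date", "ili_pct")

# Default participation commitment: 18 months of weekly reports.
DEFAULT_FOLLOWUP_WEEKS = 78


@dataclass
class Participant:
    """One roster row: demographics, enrollment window, completion flags."""

    participant_id: str
    gender: str
    age_group: str
    job_category: str
    ethnicity: str
    children_in_household: bool
    vaccinated_past_year: bool
    allergy: bool
    hospital: str
    enrollment_date: dt.date
    study_end_date: dt.date
    registration_complete: bool = True
    background_complete: bool = True

    def validate(self) -> None:
        for name, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise ValueError(
                    f"{name}={value!r} is not one of the levels {levels}"
                )
        for name in BOOLEAN_FIELDS:
            if not isinstance(getattr(self, name), (bool,)):
                raise ValueError(f"{name} must be boolean")
        if self.study_end_date <= self.enrollment_date:
            raise ValueError(
                f"study_end_date {self.study_end_date} does not follow "
                f"enrollment_date {self.enrollment_date}"
            )


@dataclass
class SymptomReport:
    """One weekly submission: participant, timestamp, 18 symptom flags."""

    participant_id: str
    submitted_at: dt.datetime
    symptoms: dict

    def validate(self) -> None:
        names = tuple(self.symptoms)
        if set(names) != set(SYMPTOM_COLUMNS) or len(names) != len(SYMPTOM_COLUMNS):
            missing = sorted(set(SYMPTOM_COLUMNS) - set(names))
            extra = sorted(set(names) - set(SYMPTOM_COLUMNS))
            raise ValueError(
                f"symptom set must have exactly the 18 questionnaire symptoms; "
                f"missing={missing}, unexpected={extra}"
            )
        for key, value in self.symptoms.items():
            if not isinstance(value, bool):
                raise ValueError(f"symptom {key} must be boolean, got {value!r}")

    def __getattr__(self, name):
        if name in SYMPTOM_COLUMNS:
            return self.symptoms[name]
        raise AttributeError(name)


def roster_records(roster_df) -> list:
    """Typed row views of a roster DataFrame."""
    names = [f.name for f in dc_fields(Participant)]
    return [Participant(**{n: row[n] for n in names}) for _, row in roster_df.iterrows()]


def report_records(reports_df) -> list:
    """Typed row views of a reports DataFrame."""
    out = []
    for _, row in reports_df.iterrows():
        out.append(
            SymptomReport(
                participant_id=row["participant_id"],
                submitted_at=row["submitted_at"],
                symptoms={s: bool(row[s]) for s in SYMPTOM_COLUMNS},
            )
        )
    return out
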