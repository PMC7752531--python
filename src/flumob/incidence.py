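"""Weekly ILI incidence: within-week retention, case definition, episode
consolidation, weekly incidence and trailing moving proportions.

The incidence denominator is the number of retained reports in the week; the
numerator counts episode *onsets*: runs of ILI reports in consecutive weeks
collapse to a single onset at the run's first week, so an episode spanning
several weeks contributes once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import SYMPTOM_COLUMNS
from .studycalendar import StudyCalendar

__all__ = ["is_ili", "dedupe_within_week", "merge_episodes", "weekly_incidence",
           "moving_proportion", "reference_moving", "episode_summary"]


def is_ili(report) -> bool:
    """ILI case definition: self-reported fever (>=38.0 C) with cough or sore
    throat.  Accepts anything with fever/cough/sore_throat fields."""
    if isinstance(report, pd.DataFrame):
        return report["fever"] & (report["cough"] | report["sore_throat"])
    fever = getattr(report, "fever", None)
    if fever is None:
        fever = report["fever"]
        return bool(fever and (report["cough"] or report["sore_throat"]))
    return bool(fever and (report.cough or report.sore_throat))


def dedupe_within_week(reports: pd.DataFrame, symptom_set=None) -> pd.DataFrame:
    """Collapse multiple submissions in one (participant, week) to one row.

    Retention rule: if any submission that week reports at least one symptom
    (from ``symptom_set``, default all 18), keep the latest symptomatic one;
    otherwise keep the latest submission.  All entries are used, including
    those after a participant's study end date.
    """
    symptom_set = tuple(symptom_set) if symptom_set is not None else SYMPTOM_COLUMNS
    unknown = set(symptom_set) - set(SYMPTOM_COLUMNS)
    if unknown:
        raise ValueError(f"unknown symptoms in retention set: {sorted(unknown)}")
    panel = reports.copy()
    panel["any_symptom"] = panel[list(symptom_set)].any(axis=1)
    # stable sort puts, within each (participant, week), asymptomatic rows
    # first and symptomatic rows last, each block in submission order; the
    # final row per group is then exactly the one the rule retains
    panel = panel.sort_values(
        ["participant_id", "week", "any_symptom", "submitted_at"], kind="mergesort"
    )
    panel = panel.groupby(["participant_id", "week"], as_index=False, sort=True).tail(1)
    panel["is_ili"] = is_ili(panel)
    # a case by definition has fever, hence a symptom, under any retention set
    panel["any_symptom"] = panel["any_symptom"] | panel["is_ili"]
    return panel.sort_values(["participant_id", "week"], kind="mergesort").reset_index(
        drop=True
    )


def merge_episodes(panel: pd.DataFrame) -> pd.DataFrame:
    """Flag episode onsets on a deduplicated panel.

    Within a participant, ILI reports in weeks differing by exactly 1 belong
    to one episode; only its first week is an onset.  A gap week — missing or
    reported without ILI — starts a new episode.  Non-onset ILI rows keep
    their report (they still count in denominators).
    """
    out = panel.sort_values(["participant_id", "week"], kind="mergesort").reset_index(
        drop=True
    )
    if out.duplicated(["participant_id", "week"]).any():
        raise ValueError("panel has duplicate (participant, week) rows; dedupe first")
    same = out["participant_id"].eq(out["participant_id"].shift())
    consecutive = out["week"].diff().eq(1)
    prev_ili = out["is_ili"].shift(fill_value=False).astype(bool)
    out["onset"] = out["is_ili"] & ~(same & consecutive & prev_ili)
    return out


def weekly_incidence(panel: pd.DataFrame, calendar: StudyCalendar) -> pd.DataFrame:
    """Weekly series of retained-report counts, episode onsets and ILI%.

    Weeks with no reports (including the maintenance block) carry a missing
    ILI% — never 0/0.
    """
    if "onset" not in panel.columns:
        panel = merge_episodes(panel)
    weeks = pd.Index(calendar.study_weeks(), name="week")
    grouped = panel.groupby("week").agg(
        n_reports=("participant_id", "size"), n_ili_onsets=("onset", "sum")
    )
    out = grouped.reindex(weeks, fill_value=0).reset_index()
    out["n_ili_onsets"] = out["n_ili_onsets"].astype(int)
    out["ili_pct"] = np.where(
        out["n_reports"] > 0, 100.0 * out["n_ili_onsets"] / out["n_reports"], np.nan
    )
    out["is_maintenance"] = out["week"].isin(calendar.maintenance_weeks)
    return out


def moving_proportion(series: pd.DataFrame, width: int = 4,
                      method: str = "pooled") -> pd.DataFrame:
    """Trailing ``width``-week moving proportion of an incidence series.

    ``pooled`` (default): 100 * (sum of onsets) / (sum of reports) over the
    window — a count-weighted proportion.  ``mean``: unweighted mean of the
    weekly percentages.  Windows containing any week without reports are
    missing, as are the first ``width - 1`` weeks.
    """
    if width < 1:
        raise ValueError(f"window width must be >= 1, got {width}")
    if method not in ("pooled", "mean"):
        raise ValueError(f"unknown method {method!r}; expected 'pooled' or 'mean'")
    out = series.copy()
    valid = (out["n_reports"] > 0).astype(float)
    complete = valid.rolling(width, min_periods=width).sum().eq(width)
    if method == "pooled":
        onsets = out["n_ili_onsets"].rolling(width, min_periods=width).sum()
        reports = out["n_reports"].rolling(width, min_periods=width).sum()
        moving = 100.0 * onsets / reports
    else:
        moving = out["ili_pct"].rolling(width, min_periods=width).mean()
    out["moving_pct"] = moving.where(complete)
    return out


def reference_moving(reference: pd.DataFrame, width: int = 4) -> pd.Series:
    """Trailing moving proportion of the sentinel series (no counts are
    available, so this is the rolling mean of the weekly percentages),
    indexed by week."""
    if width < 1:
        raise ValueError(f"window width must be >= 1, got {width}")
    s = reference.set_index("week")["ili_pct"].sort_index()
    return s.rolling(width, min_periods=width).mean().rename("moving_pct")


def episode_summary(panel: pd.DataFrame, cohort: pd.DataFrame) -> dict:
    """Share of the analysis cohort reporting at least one ILI episode."""
    if "onset" not in panel.columns:
        panel = merge_episodes(panel)
    in_cohort = panel["participant_id"].isin(cohort["participant_id"])
    with_episode = panel.loc[in_cohort & panel["onset"], "participant_id"].nunique()
    n = len(cohort)
    return {
        "participants_with_any_episode": int(with_episode),
        "n_cohort": int(n),
        "pct_with_any_episode": 100.0 * with_episode / n if n else float("nan"),
    }
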