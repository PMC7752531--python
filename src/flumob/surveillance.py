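"""Surveillance power: correlation of the participatory incidence series
against the sentinel series, overall, by period, and by participant stratum.

Surveillance power is the Pearson correlation between the trailing 4-week
moving proportions of the participatory ILI% and the sentinel ILI%.  The
``before_maintenance`` period keeps only weeks strictly before the
maintenance window; because the moving windows are trailing, those windows
contain pre-disruption weeks only, and windows downstream of the gap are
already missing (the gap weeks have no reports), so no window ever pools
across the downtime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .incidence import merge_episodes, moving_proportion, reference_moving, \
    weekly_incidence
from .studycalendar import StudyCalendar

__all__ = ["SurveillanceResult", "surveillance_correlation",
           "stratified_correlations", "format_p"]

PERIODS = ("all", "before_maintenance")

MIN_WEEKS = 3


@dataclass(frozen=True)
class SurveillanceResult:
    stratum: str
    level: str
    period: str
    r: float
    p_value: float
    n_weeks: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum, "level": self.level, "period": self.period,
            "r": self.r, "p_value": self.p_value, "n_weeks": self.n_weeks,
            "degenerate": self.degenerate,
        }


def format_p(p: float) -> str:
    """Display convention: three decimals, floored at '<.001'."""
    if not np.isfinite(p):
        return ""
    return "<.001" if p < 0.001 else f"{p:.3f}"


def _correlate(x: pd.Series, y: pd.Series, stratum: str, level: str,
               period: str) -> SurveillanceResult:
    paired = pd.concat({"x": x, "y": y}, axis=1, join="inner").dropna()
    n = len(paired)
    if n < MIN_WEEKS or paired["x"].nunique() < 2 or paired["y"].nunique() < 2:
        return SurveillanceResult(stratum, level, period, float("nan"),
                                  float("nan"), n, degenerate=True)
    r, p = stats.pearsonr(paired["x"], paired["y"])
    return SurveillanceResult(stratum, level, period, float(r), float(p), n)


def surveillance_correlation(flumob: pd.DataFrame, reference: pd.DataFrame,
                             calendar: StudyCalendar, period: str = "all",
                             width: int = 4, stratum: str = "overall",
                             level: str = "overall",
                             method: str = "pooled") -> SurveillanceResult:
    """Pearson correlation between the moving proportions of a participatory
    incidence series (as from :func:`weekly_incidence`) and the sentinel
    series, with a two-sided p from the t transform on n_weeks - 2 df.

    Weeks with either side missing are dropped.  Fewer than 3 paired weeks,
    or a constant series, yields a flagged degenerate result rather than a
    numeric r.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {PERIODS}")
    moving = moving_proportion(flumob, width=width, method=method)
    x = moving.set_index("week")["moving_pct"]
    y = reference_moving(reference, width=width)
    if period == "before_maintenance":
        boundary = min(calendar.maintenance_weeks)
        x = x[x.index < boundary]
        y = y[y.index < boundary]
    return _correlate(x, y, stratum, level, period)


def stratified_correlations(panel: pd.DataFrame, cohort: pd.DataFrame,
                            reference: pd.DataFrame, calendar: StudyCalendar,
                            strata, width: int = 4,
                            periods=PERIODS) -> pd.DataFrame:
    """Re-run the incidence pipeline on the panel restricted to each covariate
    level and correlate against the same sentinel series.

    Returns one row per (covariate, level, period), plus 'overall' rows.
    Empty strata yield flagged degenerate rows.
    """
    results = []

    def run(sub_panel, stratum, level):
        if sub_panel.empty:
            for period in periods:
                results.append(SurveillanceResult(
                    stratum, level, period, float("nan"), float("nan"), 0,
                    degenerate=True,
                ))
            return
        series = weekly_incidence(merge_episodes(sub_panel), calendar)
        for period in periods:
            results.append(surveillance_correlation(
                series, reference, calendar, period=period, width=width,
                stratum=stratum, level=level,
            ))

    run(panel[panel["participant_id"].isin(cohort["participant_id"])],
        "overall", "overall")
    for cov in strata:
        for value in pd.unique(cohort[cov]):
            pids = cohort.loc[cohort[cov] == value, "participant_id"]
            sub = panel[panel["participant_id"].isin(pids)]
            label = {True: "yes", False: "no"}.get(value, value)
            run(sub, cov, str(label))
    return pd.DataFrame([r.as_dict() for r in results])
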