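"""Participation metrics and their covariate models.

Individual submission rates (share of eligible study weeks with a
submission, maintenance weeks excluded, entries after the personal study end
dropped), the week-level reporting-rate series, the committed-user
classification, the paired pre/post-disruption contrast, and three
statsmodels-backed models:

* :class:`SubmissionRateModel` — multivariable linear regression of the
  individual submission rate on participant characteristics, reporting
  adjusted rates per category level by marginal standardization;
* :class:`CommittedUserModel` — multivariable logistic regression of the
  committed-user flag, reporting adjusted odds ratios with Wald 95% CIs;
* :class:`AdherenceModel` — binomial GLM of weekly reporting on covariates
  plus the post-disruption indicator, on participant x period aggregated
  counts (likelihood-equivalent to the per-week Bernoulli model, since the
  linear predictor is constant within a participant's period).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datatypes import MODEL_COVARIATES, REFERENCE_LEVELS
from .studycalendar import StudyCalendar

__all__ = [
    "participation_summary", "cohort_summary", "weekly_reporting_rate",
    "classify_committed", "paired_pre_post_test", "PairedTestResult",
    "SubmissionRateModel", "CommittedUserModel", "AdherenceModel",
    "SeparationError",
]


class SeparationError(RuntimeError):
    """Logistic fit flagged as (quasi-)completely separated or divergent."""


def _eligible_weeks(start, stop, maintenance) -> np.ndarray:
    """Number of non-maintenance weeks in [start, stop) for paired arrays."""
    start = np.asarray(start)
    stop = np.maximum(np.asarray(stop), start)
    m = np.sort(np.fromiter(maintenance, dtype=int))
    removed = np.searchsorted(m, stop, side="left") - np.searchsorted(
        m, start, side="left"
    )
    return (stop - start) - removed


def participation_summary(reports: pd.DataFrame, cohort: pd.DataFrame,
                          calendar: StudyCalendar,
                          committed_threshold: int = 2) -> pd.DataFrame:
    """Per-participant participation summary.

    Eligible weeks are the half-open window [enrollment_week, study_end_week)
    minus maintenance weeks; a week counts as submitted if at least one report
    falls in it.  Entries after the personal study end are excluded here (they
    re-enter in the incidence pipeline).  Pre/post rates split the eligible
    weeks at the disruption week.  ``committed`` is true when at least
    ``committed_threshold`` reports (entries, not weeks) fall in weeks
    [disruption_week, study_end_week].
    """
    bad = cohort["study_end_week"] <= cohort["enrollment_week"]
    if bad.any():
        pid = cohort.loc[bad, "participant_id"].iloc[0]
        raise ValueError(f"participant {pid}: study end week precedes enrollment")
    d = calendar.disruption_week
    enroll = cohort["enrollment_week"].to_numpy()
    end = cohort["study_end_week"].to_numpy()
    out = cohort[["participant_id", "enrollment_week", "study_end_week"]].copy()
    out["n_eligible_weeks"] = _eligible_weeks(enroll, end, calendar.maintenance_weeks)
    out["n_eligible_pre"] = _eligible_weeks(
        enroll, np.minimum(end, d), calendar.maintenance_weeks
    )
    out["n_eligible_post"] = _eligible_weeks(
        np.maximum(enroll, d), end, calendar.maintenance_weeks
    )

    r = reports.merge(
        cohort[["participant_id", "enrollment_week", "study_end_week"]],
        on="participant_id", how="inner",
    )
    in_window = (
        (r["week"] >= r["enrollment_week"])
        & (r["week"] < r["study_end_week"])
        & ~r["week"].isin(calendar.maintenance_weeks)
    )
    weeks = r.loc[in_window, ["participant_id", "week"]].drop_duplicates()
    n_sub = weeks.groupby("participant_id").size()
    n_pre = weeks[weeks["week"] < d].groupby("participant_id").size()
    n_post = weeks[weeks["week"] >= d].groupby("participant_id").size()
    idx = out["participant_id"]
    out["n_submitted_weeks"] = n_sub.reindex(idx).fillna(0).astype(int).to_numpy()
    out["n_submitted_pre"] = n_pre.reindex(idx).fillna(0).astype(int).to_numpy()
    out["n_submitted_post"] = n_post.reindex(idx).fillna(0).astype(int).to_numpy()

    for label, num, den in (
        ("submission_rate", "n_submitted_weeks", "n_eligible_weeks"),
        ("submission_rate_pre", "n_submitted_pre", "n_eligible_pre"),
        ("submission_rate_post", "n_submitted_post", "n_eligible_post"),
    ):
        out[label] = np.where(
            out[den] > 0, out[num] / out[den].replace(0, 1), np.nan
        )

    # committed: report entries in [disruption_week, study_end_week] inclusive
    post_entries = r[(r["week"] >= d) & (r["week"] <= r["study_end_week"])]
    n_post_reports = post_entries.groupby("participant_id").size()
    out["n_post_reports"] = n_post_reports.reindex(idx).fillna(0).astype(int).to_numpy()
    out["committed"] = out["n_post_reports"] >= committed_threshold
    return out.reset_index(drop=True)


def classify_committed(reports: pd.DataFrame, participant_id: str,
                       study_end_week: int, calendar: StudyCalendar,
                       threshold: int = 2) -> bool:
    """True iff the participant submitted at least ``threshold`` reports in
    weeks [disruption_week, study_end_week]."""
    r = reports[reports["participant_id"] == participant_id]
    n = int(((r["week"] >= calendar.disruption_week)
             & (r["week"] <= study_end_week)).sum())
    return n >= threshold


def cohort_summary(summaries: pd.DataFrame) -> dict:
    """Cohort-level participation summary: means/SDs of the individual rates
    (the individual-level definition — mean of per-participant rates, not a
    pooled count ratio) and the share with at least one submission."""
    def stats(col):
        v = summaries[col].dropna()
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else float("nan")

    mean_all, sd_all = stats("submission_rate")
    mean_pre, sd_pre = stats("submission_rate_pre")
    mean_post, sd_post = stats("submission_rate_post")
    n = len(summaries)
    n_any = int((summaries["n_submitted_weeks"] > 0).sum())
    return {
        "n_participants": n,
        "mean_submission_rate": mean_all, "sd_submission_rate": sd_all,
        "mean_submission_rate_pre": mean_pre, "sd_submission_rate_pre": sd_pre,
        "mean_submission_rate_post": mean_post, "sd_submission_rate_post": sd_post,
        "n_any_submission": n_any,
        "pct_any_submission": 100.0 * n_any / n if n else float("nan"),
        "n_committed": int(summaries["committed"].sum()),
        "pct_committed": 100.0 * summaries["committed"].mean() if n else float("nan"),
    }


def weekly_reporting_rate(reports: pd.DataFrame, cohort: pd.DataFrame,
                          calendar: StudyCalendar) -> pd.DataFrame:
    """Week-level reporting rate: distinct reporters that week over the
    cumulative number enrolled by that week (never decremented).  Maintenance
    weeks, and weeks before anyone enrolled, carry a missing rate."""
    if cohort.empty:
        raise ValueError("cohort is empty")
    weeks = pd.Index(calendar.study_weeks(), name="week")
    enroll = np.sort(cohort["enrollment_week"].to_numpy())
    n_cum = np.searchsorted(enroll, weeks.to_numpy(), side="right")

    r = reports.merge(
        cohort[["participant_id", "study_end_week"]], on="participant_id", how="inner"
    )
    r = r[r["week"] < r["study_end_week"]]
    n_survey = (
        r.groupby("week")["participant_id"].nunique().reindex(weeks, fill_value=0)
    )
    out = pd.DataFrame({
        "week": weeks.to_numpy(),
        "n_cumulative": n_cum.astype(int),
        "n_survey": n_survey.to_numpy().astype(int),
    })
    out["is_maintenance"] = out["week"].isin(calendar.maintenance_weeks)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = out["n_survey"] / out["n_cumulative"]
    out["reporting_rate"] = rate.where((out["n_cumulative"] > 0)
                                       & ~out["is_maintenance"])
    return out


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p_value: float
    mean_difference: float
    degenerate: bool = False


def paired_pre_post_test(summaries: pd.DataFrame) -> PairedTestResult:
    """Paired t test of pre- versus post-disruption individual submission
    rates: one-sample t on the per-participant differences (pre - post)."""
    d = (summaries["submission_rate_pre"] - summaries["submission_rate_post"]).dropna()
    n = len(d)
    if n < 2:
        raise ValueError("paired test needs at least 2 participants with both rates")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.sign(mean)) * float("inf")
        p = 1.0 if mean == 0.0 else 0.0
        return PairedTestResult(t, n - 1, p, mean, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    from scipy import stats

    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), n - 1, float(p), mean)


# ---------------------------------------------------------------------------
# covariate models


def _design_frame(summaries: pd.DataFrame, cohort: pd.DataFrame,
                  covariates) -> pd.DataFrame:
    data = summaries.merge(
        cohort[["participant_id", *covariates]], on="participant_id", how="inner"
    ).copy()
    for cov in covariates:
        if data[cov].dtype == bool:
            data[cov] = np.where(data[cov], "yes", "no")
    return data


def _ref_label(cov) -> str:
    ref = REFERENCE_LEVELS.get(cov, None)
    if isinstance(ref, bool):
        return "yes" if ref else "no"
    return ref


def _rhs(covariates) -> str:
    terms = []
    for cov in covariates:
        ref = _ref_label(cov)
        if ref is None:
            terms.append(f"C({cov})")
        else:
            terms.append(f"C({cov}, Treatment({ref!r}))")
    return " + ".join(terms)


def _check_full_rank(formula: str, data: pd.DataFrame) -> None:
    X = patsy.dmatrix(formula, data, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        aliased = []
        arr = X.to_numpy()
        for j, name in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                aliased.append(name)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}"
        )


def _level_map(data: pd.DataFrame, covariates) -> list:
    """(covariate, level, is_reference) triples in model order."""
    rows = []
    for cov in covariates:
        ref = _ref_label(cov)
        levels = list(pd.unique(data[cov]))
        levels.sort(key=lambda x: (x != ref, str(x)))
        for level in levels:
            rows.append((cov, level, level == ref))
    return rows


def _param_name(cov: str, level, ref) -> str:
    if ref is None:
        return f"C({cov})[T.{level}]"
    return f"C({cov}, Treatment({ref!r}))[T.{level}]"


class SubmissionRateModel:
    """Multivariable linear regression of individual submission rates on
    participant characteristics.

    Parameters
    ----------
    summaries : DataFrame
        Output of :func:`participation_summary`.
    cohort : DataFrame
        Analysis roster carrying the covariates.
    covariates : sequence of str, optional
        Defaults to gender, age group, job category, ethnicity, children in
        household, vaccination in the past year and allergy, with the usual
        reference levels.
    outcome : str
        Column of ``summaries`` to model (default ``submission_rate``; pass
        ``submission_rate_pre`` for the pre-disruption sensitivity analysis).
    """

    def __init__(self, summaries, cohort, covariates=MODEL_COVARIATES,
                 outcome="submission_rate"):
        self.covariates = tuple(covariates)
        self.outcome = outcome
        self.data = _design_frame(summaries, cohort, self.covariates)
        self.data = self.data.dropna(subset=[outcome])
        self.formula = f"{outcome} ~ {_rhs(self.covariates)}"

    def fit(self) -> "SubmissionRateResults":
        _check_full_rank(_rhs(self.covariates), self.data)
        res = smf.ols(self.formula, data=self.data).fit()
        return SubmissionRateResults(self, res)


class SubmissionRateResults:
    """OLS results plus adjusted (marginally standardized) rates."""

    def __init__(self, model: SubmissionRateModel, results):
        self.model = model
        self._results = results
        self.params = results.params
        self.bse = results.bse
        self.pvalues = results.pvalues

    def coefficient(self, covariate: str, level) -> float:
        ref = _ref_label(covariate)
        if isinstance(level, bool):
            level = "yes" if level else "no"
        if level == ref:
            return 0.0
        return float(self.params[_param_name(covariate, level, ref)])

    def adjusted_rates(self) -> pd.DataFrame:
        """Adjusted rate per covariate level by marginal standardization:
        predict for every participant with the level substituted, average
        over the cohort."""
        rows = []
        for cov, level, is_ref in _level_map(self.model.data, self.model.covariates):
            counterfactual = self.model.data.assign(**{cov: level})
            rate = float(self._results.predict(counterfactual).mean())
            rows.append({
                "covariate": cov, "level": level, "reference": is_ref,
                "adjusted_rate": rate,
                "coefficient": np.nan if is_ref else self.coefficient(cov, level),
                "se": np.nan if is_ref else float(
                    self.bse[_param_name(cov, level, _ref_label(cov))]
                ),
                "p_value": np.nan if is_ref else float(
                    self.pvalues[_param_name(cov, level, _ref_label(cov))]
                ),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        table = self.adjusted_rates()
        lines = [
            "Multivariable linear regression of individual submission rate",
            f"n = {int(self._results.nobs)}, "
            f"R^2 = {self._results.rsquared:.3f}",
            "",
            f"{'covariate':<24}{'level':<22}{'adj. rate':>10}"
            f"{'coef (SE)':>18}{'P':>8}",
        ]
        for _, row in table.iterrows():
            if row["reference"]:
                coef = "(reference)"
                p = ""
            else:
                coef = f"{row['coefficient']:.3f} ({row['se']:.3f})"
                p = "<.001" if row["p_value"] < 0.001 else f"{row['p_value']:.3f}"
            lines.append(
                f"{row['covariate']:<24}{str(row['level']):<22}"
                f"{row['adjusted_rate']:>10.3f}{coef:>18}{p:>8}"
            )
        return "\n".join(lines)


class CommittedUserModel:
    """Multivariable logistic regression of the committed-user flag on
    participant characteristics, reporting adjusted odds ratios."""

    def __init__(self, summaries, cohort, covariates=MODEL_COVARIATES,
                 outcome="committed"):
        self.covariates = tuple(covariates)
        self.outcome = outcome
        self.data = _design_frame(summaries, cohort, self.covariates)
        self.data["_y"] = self.data[outcome].astype(int)

    def fit(self) -> "CommittedUserResults":
        y = self.data["_y"]
        if y.nunique() < 2:
            raise ValueError(
                "committed-user outcome has no variation (all "
                + ("committed" if y.iloc[0] else "non-committed") + ")"
            )
        _check_full_rank(_rhs(self.covariates), self.data)
        formula = f"_y ~ {_rhs(self.covariates)}"
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
        try:
            with warnings.catch_warnings():
                warnings.filterwarnings("error", category=PerfectSeparationWarning)
                res = smf.logit(formula, data=self.data).fit(disp=False,
                                                             maxiter=100)
        except (PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"complete separation in the committed-user outcome: {exc}"
            ) from exc
        except Exception as exc:  # older statsmodels raises an error class
            if "separation" in type(exc).__name__.lower():
                raise SeparationError(str(exc)) from exc
            raise
        if not res.mle_retvals.get("converged", True) or np.any(
            np.abs(res.params.to_numpy()) > 20
        ):
            raise SeparationError(
                "logistic fit did not converge cleanly; possible complete "
                "separation in the committed-user outcome"
            )
        return CommittedUserResults(self, res)


class CommittedUserResults:
    """Logit results: adjusted odds ratios, Wald 95% CIs, stratum counts."""

    def __init__(self, model: CommittedUserModel, results):
        self.model = model
        self._results = results
        self.params = results.params
        self.bse = results.bse
        self.pvalues = results.pvalues

    def log_odds(self, covariate: str, level) -> float:
        ref = _ref_label(covariate)
        if isinstance(level, bool):
            level = "yes" if level else "no"
        if level == ref:
            return 0.0
        return float(self.params[_param_name(covariate, level, ref)])

    def odds_ratios(self) -> pd.DataFrame:
        ci = self._results.conf_int(alpha=0.05)
        rows = []
        for cov, level, is_ref in _level_map(self.model.data, self.model.covariates):
            if is_ref:
                rows.append({
                    "covariate": cov, "level": level, "reference": True,
                    "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan,
                })
            else:
                name = _param_name(cov, level, _ref_label(cov))
                rows.append({
                    "covariate": cov, "level": level, "reference": False,
                    "odds_ratio": float(np.exp(self.params[name])),
                    "ci_low": float(np.exp(ci.loc[name, 0])),
                    "ci_high": float(np.exp(ci.loc[name, 1])),
                    "p_value": float(self.pvalues[name]),
                })
        return pd.DataFrame(rows)

    def stratum_table(self) -> pd.DataFrame:
        """Committed counts and percentages within each covariate stratum."""
        rows = []
        data = self.model.data
        for cov, level, is_ref in _level_map(data, self.model.covariates):
            stratum = data[data[cov] == level]
            n = len(stratum)
            k = int(stratum["_y"].sum())
            rows.append({
                "covariate": cov, "level": level,
                "committed_n": k, "stratum_n": n,
                "pct": 100.0 * k / n if n else np.nan,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        table = self.odds_ratios().merge(
            self.stratum_table(), on=["covariate", "level"]
        )
        lines = [
            "Multivariable logistic regression of committed users",
            f"n = {int(self._results.nobs)}, committed = "
            f"{int(self.model.data['_y'].sum())}",
            "",
            f"{'covariate':<24}{'level':<22}{'n (%)':>14}{'OR':>7}"
            f"{'95% CI':>16}{'P':>8}",
        ]
        for _, row in table.iterrows():
            npct = f"{row['committed_n']} ({row['pct']:.1f})"
            if row["reference"]:
                orr, cistr, p = "1.00", "(reference)", ""
            else:
                orr = f"{row['odds_ratio']:.2f}"
                cistr = f"{row['ci_low']:.2f}-{row['ci_high']:.2f}"
                p = "<.001" if row["p_value"] < 0.001 else f"{row['p_value']:.3f}"
            lines.append(
                f"{row['covariate']:<24}{str(row['level']):<22}{npct:>14}"
                f"{orr:>7}{cistr:>16}{p:>8}"
            )
        return "\n".join(lines)


class AdherenceModel:
    """Binomial GLM of weekly reporting on covariates and the disruption.

    Aggregates each participant's eligible weeks into pre- and
    post-disruption (submitted, missed) counts, which is likelihood-
    equivalent to the per-week Bernoulli model because the linear predictor
    is constant within a participant's period.  Used to check that the
    synthetic cohort's adherence effects are recoverable.
    """

    def __init__(self, summaries, cohort, covariates=MODEL_COVARIATES):
        self.covariates = tuple(covariates)
        data = _design_frame(summaries, cohort, self.covariates)
        rows = []
        for period, sub_col, elig_col in (
            ("pre", "n_submitted_pre", "n_eligible_pre"),
            ("post", "n_submitted_post", "n_eligible_post"),
        ):
            d = data[data[elig_col] > 0].copy()
            d["post_period"] = 1 if period == "post" else 0
            d["n_submitted"] = d[sub_col]
            d["n_missed"] = d[elig_col] - d[sub_col]
            rows.append(d[["participant_id", "post_period", "n_submitted",
                           "n_missed", *self.covariates]])
        self.data = pd.concat(rows, ignore_index=True)
        self.rhs = _rhs(self.covariates) + " + post_period"

    def fit(self) -> "AdherenceResults":
        X = patsy.dmatrix(self.rhs, self.data, return_type="dataframe")
        y = self.data[["n_submitted", "n_missed"]].to_numpy()
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return AdherenceResults(self, res)


class AdherenceResults:
    def __init__(self, model: AdherenceModel, results):
        self.model = model
        self._results = results
        self.params = results.params
        self.bse = results.bse

    def effect(self, covariate: str, level=None):
        """(estimate, ci_low, ci_high) for a covariate level's log-odds
        effect, or for 'post_period'."""
        if covariate == "post_period":
            name = "post_period"
        else:
            if isinstance(level, bool):
                level = "yes" if level else "no"
            name = _param_name(covariate, level, _ref_label(covariate))
        ci = self._results.conf_int(alpha=0.05)
        return (float(self.params[name]), float(ci.loc[name, 0]),
                float(ci.loc[name, 1]))

    def summary(self) -> str:
        return str(self._results.summary())
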