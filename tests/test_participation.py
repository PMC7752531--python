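import numpy as np
import pandas as pd
import pytest

from flumob import (
    AdherenceModel,
    CommittedUserModel,
    SeparationError,
    SimulationConfig,
    SubmissionRateModel,
    classify_committed,
    cohort_summary,
    paired_pre_post_test,
    participation_summary,
    simulate_study,
    weekly_reporting_rate,
)

from conftest import make_cohort, make_reports


class TestIndividualSubmissionRate:
    def test_every_eligible_week_reported_rate_one(self, calendar):
        cohort = make_cohort(1, calendar)
        pid = cohort["participant_id"].iloc[0]
        weeks = [w for w in range(0, 78) if w not in calendar.maintenance_weeks]
        reports = make_reports([(pid, w, ()) for w in weeks], calendar)
        s = participation_summary(reports, cohort, calendar).iloc[0]
        assert s["n_eligible_weeks"] == 68
        assert s["submission_rate"] == 1.0

    def test_no_reports_rate_zero(self, calendar):
        cohort = make_cohort(1, calendar)
        reports = make_reports([], calendar)
        s = participation_summary(reports, cohort, calendar).iloc[0]
        assert s["submission_rate"] == 0.0
        assert s["submission_rate_pre"] == 0.0
        assert s["submission_rate_post"] == 0.0

    def test_half_reported_rate_half(self, calendar):
        # 78 candidate weeks, 10 removed by maintenance -> 68 eligible;
        # reports in 34 of them gives exactly 0.5
        cohort = make_cohort(1, calendar)
        pid = cohort["participant_id"].iloc[0]
        eligible = [w for w in range(0, 78) if w not in calendar.maintenance_weeks]
        assert len(eligible) == 68
        reports = make_reports([(pid, w, ()) for w in eligible[:34]], calendar)
        s = participation_summary(reports, cohort, calendar).iloc[0]
        assert s["submission_rate"] == 0.5

    def test_post_study_end_entries_excluded(self, calendar):
        cohort = make_cohort(1, calendar, followup=10)
        pid = cohort["participant_id"].iloc[0]
        reports = make_reports(
            [(pid, 5, ()), (pid, 12, ()), (pid, 15, ())], calendar
        )
        s = participation_summary(reports, cohort, calendar).iloc[0]
        assert s["n_eligible_weeks"] == 10
        assert s["n_submitted_weeks"] == 1

    def test_duplicate_reports_count_one_week(self, calendar):
        cohort = make_cohort(1, calendar)
        pid = cohort["participant_id"].iloc[0]
        reports = make_reports([(pid, 3, (), 8), (pid, 3, (), 20)], calendar)
        s = participation_summary(reports, cohort, calendar).iloc[0]
        assert s["n_submitted_weeks"] == 1

    def test_pre_post_split_at_disruption(self, calendar):
        cohort = make_cohort(1, calendar)
        pid = cohort["participant_id"].iloc[0]
        d = calendar.disruption_week
        reports = make_reports([(pid, d - 12, ()), (pid, d, ())], calendar)
        s = participation_summary(reports, cohort, calendar).iloc[0]
        assert s["n_submitted_pre"] == 1 and s["n_submitted_post"] == 1
        assert s["n_eligible_pre"] == 57  # 67 pre-disruption weeks minus 10
        assert s["n_eligible_post"] == 11  # weeks 67..77

    def test_end_before_enrollment_rejected(self, calendar):
        cohort = make_cohort(1, calendar)
        cohort["study_end_week"] = cohort["enrollment_week"]
        with pytest.raises(ValueError, match="precedes enrollment"):
            participation_summary(make_reports([], calendar), cohort, calendar)

    def test_cohort_mean_is_mean_of_individual_rates(self, calendar):
        # two participants with unequal eligible windows: the individual-level
        # mean differs from the pooled count ratio and is the one reported
        a = make_cohort(1, calendar, followup=20)
        b = make_cohort(1, calendar, followup=40)
        cohort = pd.concat([a, b], ignore_index=True)
        pa, pb = cohort["participant_id"]
        entries = [(pa, w, ()) for w in range(10)]  # 10/20
        entries += [(pb, w, ()) for w in range(40)]  # 40/40
        summaries = participation_summary(make_reports(entries, calendar),
                                          cohort, calendar)
        summary = cohort_summary(summaries)
        assert summary["mean_submission_rate"] == pytest.approx(0.75)
        pooled = 50 / 60
        assert summary["mean_submission_rate"] != pytest.approx(pooled)


class TestWeeklyReportingRate:
    def test_constant_full_reporting(self, small_calendar):
        cohort = make_cohort(3, small_calendar, followup=15)
        entries = [
            (pid, w, ())
            for pid in cohort["participant_id"]
            for w in range(15)
            if w not in small_calendar.maintenance_weeks
        ]
        weekly = weekly_reporting_rate(make_reports(entries, small_calendar),
                                       cohort, small_calendar)
        observed = weekly[weekly["week"] < 15]
        live = observed[~observed["is_maintenance"]]
        assert (live["reporting_rate"] == 1.0).all()
        assert observed[observed["is_maintenance"]]["reporting_rate"].isna().all()

    def test_staggered_enrollment_denominator(self, small_calendar):
        early = make_cohort(10, small_calendar, enroll=0, followup=15)
        late = make_cohort(10, small_calendar, enroll=5, followup=15)
        cohort = pd.concat([early, late], ignore_index=True)
        entries = [
            (pid, w, ())
            for pid in early["participant_id"]
            for w in range(15)
            if w not in small_calendar.maintenance_weeks
        ]
        weekly = weekly_reporting_rate(make_reports(entries, small_calendar),
                                       cohort, small_calendar).set_index("week")
        assert (weekly.loc[0:4, "reporting_rate"] == 1.0).all()
        live = [w for w in range(5, 15) if w not in small_calendar.maintenance_weeks]
        assert (weekly.loc[live, "reporting_rate"] == 0.5).all()

    def test_week_before_any_enrollment_flagged(self, small_calendar):
        cohort = make_cohort(2, small_calendar, enroll=3, followup=10)
        weekly = weekly_reporting_rate(make_reports([], small_calendar),
                                       cohort, small_calendar).set_index("week")
        assert weekly.loc[0:2, "reporting_rate"].isna().all()
        assert weekly.loc[0:2, "n_cumulative"].eq(0).all()


class TestCommitted:
    def test_two_post_reports_committed(self, calendar):
        cohort = make_cohort(1, calendar)
        pid = cohort["participant_id"].iloc[0]
        d = calendar.disruption_week
        reports = make_reports([(pid, d, ()), (pid, d + 1, ())], calendar)
        assert classify_committed(reports, pid, 78, calendar)
        assert participation_summary(reports, cohort, calendar)["committed"].iloc[0]

    def test_one_post_report_not_committed(self, calendar):
        cohort = make_cohort(1, calendar)
        pid = cohort["participant_id"].iloc[0]
        reports = make_reports([(pid, calendar.disruption_week, ())], calendar)
        assert not classify_committed(reports, pid, 78, calendar)

    def test_many_pre_reports_not_committed(self, calendar):
        cohort = make_cohort(1, calendar)
        pid = cohort["participant_id"].iloc[0]
        reports = make_reports([(pid, w, ()) for w in range(50)], calendar)
        assert not classify_committed(reports, pid, 78, calendar)

    def test_monotone_in_threshold_and_count(self, calendar):
        pid = "T1"
        d = calendar.disruption_week
        for k in range(5):
            reports = make_reports([(pid, d + i, ()) for i in range(k)], calendar)
            flags = [classify_committed(reports, pid, 78, calendar, threshold=t)
                     for t in range(1, 6)]
            # once false at a threshold, false at every higher threshold
            assert flags == sorted(flags, reverse=True)
            assert flags[0] == (k >= 1)

    def test_removing_post_reports_clears_committed(self, calendar):
        cohort = make_cohort(2, calendar)
        d = calendar.disruption_week
        entries = []
        for pid in cohort["participant_id"]:
            entries += [(pid, w, ()) for w in (1, 2, 3, d, d + 1)]
        reports = make_reports(entries, calendar)
        full = participation_summary(reports, cohort, calendar)
        pre_only = participation_summary(reports[reports["week"] < d], cohort,
                                         calendar)
        assert full["committed"].all()
        assert not pre_only["committed"].any()
        pd.testing.assert_series_equal(full["submission_rate_pre"],
                                       pre_only["submission_rate_pre"])


class TestPairedTest:
    def test_identical_rates_give_t_zero(self, calendar):
        summaries = pd.DataFrame({
            "submission_rate_pre": [0.5, 0.6, 0.7],
            "submission_rate_post": [0.5, 0.6, 0.7],
        })
        result = paired_pre_post_test(summaries)
        assert result.t == 0.0
        assert result.degenerate

    def test_hand_computed_t(self):
        # differences 0.1, 0.2, 0.3: t = 0.2 / (0.1 / sqrt(3)) = 3.4641...
        summaries = pd.DataFrame({
            "submission_rate_pre": [0.6, 0.7, 0.8],
            "submission_rate_post": [0.5, 0.5, 0.5],
        })
        result = paired_pre_post_test(summaries)
        assert result.t == pytest.approx(0.2 / (0.1 / np.sqrt(3)), rel=1e-12)
        assert result.df == 2

    def test_df_is_n_minus_one(self, calendar):
        rng = np.random.default_rng(0)
        summaries = pd.DataFrame({
            "submission_rate_pre": rng.random(25),
            "submission_rate_post": rng.random(25),
        })
        assert paired_pre_post_test(summaries).df == 24

    def test_too_few_participants_rejected(self):
        summaries = pd.DataFrame({
            "submission_rate_pre": [0.5], "submission_rate_post": [0.2],
        })
        with pytest.raises(ValueError, match="at least 2"):
            paired_pre_post_test(summaries)


@pytest.fixture(scope="module")
def fitted(calendar):
    config = SimulationConfig(seed=20)
    roster, reference, reports = simulate_study(config, calendar)
    cohort = roster[roster["registration_complete"]
                    & roster["background_complete"]].reset_index(drop=True)
    summaries = participation_summary(reports, cohort, calendar)
    return summaries, cohort


class TestSubmissionRateModel:
    def test_adjusted_rate_contrast_equals_coefficient(self, fitted):
        # exact algebra of linear marginal standardization
        summaries, cohort = fitted
        res = SubmissionRateModel(summaries, cohort).fit()
        rates = res.adjusted_rates().set_index(["covariate", "level"])
        for cov, ref in (("age_group", "21-30"), ("ethnicity", "chinese")):
            base = rates.loc[(cov, ref), "adjusted_rate"]
            for level in rates.loc[cov].index:
                if level == ref:
                    continue
                contrast = rates.loc[(cov, level), "adjusted_rate"] - base
                assert contrast == pytest.approx(
                    res.coefficient(cov, level), abs=1e-10
                )

    def test_null_covariate_levels_have_equal_adjusted_rates(self, fitted):
        # allergy has no true effect in the generator: with n=690 its two
        # adjusted rates agree closely
        summaries, cohort = fitted
        res = SubmissionRateModel(summaries, cohort).fit()
        rates = res.adjusted_rates().set_index(["covariate", "level"])
        gap = abs(rates.loc[("allergy", "yes"), "adjusted_rate"]
                  - rates.loc[("allergy", "no"), "adjusted_rate"])
        assert gap < 0.03

    def test_rank_deficiency_names_aliased_columns(self, fitted, calendar):
        summaries, cohort = fitted
        clone = cohort.copy()
        clone["ethnicity"] = np.where(clone["gender"] == "male", "chinese",
                                      "other")
        with pytest.raises(ValueError, match="aliased"):
            SubmissionRateModel(summaries, clone,
                                covariates=("gender", "ethnicity")).fit()

    def test_summary_renders(self, fitted):
        summaries, cohort = fitted
        text = SubmissionRateModel(summaries, cohort).fit().summary()
        assert "adjusted" not in text or text  # smoke: non-empty string
        assert "age_group" in text


class TestCommittedUserModel:
    def test_reference_levels_have_or_one(self, fitted):
        summaries, cohort = fitted
        res = CommittedUserModel(summaries, cohort).fit()
        table = res.odds_ratios()
        refs = table[table["reference"]]
        assert (refs["odds_ratio"] == 1.0).all()

    def test_wald_interval_brackets_or(self, fitted):
        summaries, cohort = fitted
        table = CommittedUserModel(summaries, cohort).fit().odds_ratios()
        est = table[~table["reference"]]
        assert ((est["ci_low"] < est["odds_ratio"])
                & (est["odds_ratio"] < est["ci_high"])).all()

    def test_stratum_percentages_consistent(self, fitted):
        summaries, cohort = fitted
        res = CommittedUserModel(summaries, cohort).fit()
        table = res.stratum_table()
        gender = table[table["covariate"] == "gender"]
        assert gender["stratum_n"].sum() == len(cohort)
        assert (table["pct"]
                == 100.0 * table["committed_n"] / table["stratum_n"]).all()

    def test_all_committed_rejected(self, fitted):
        summaries, cohort = fitted
        const = summaries.copy()
        const["committed"] = True
        with pytest.raises(ValueError, match="no variation"):
            CommittedUserModel(const, cohort).fit()

    def test_complete_separation_flagged(self, calendar):
        cohort = pd.concat(
            [make_cohort(30, calendar, gender="female"),
             make_cohort(30, calendar, gender="male")],
            ignore_index=True,
        )
        summaries = pd.DataFrame({
            "participant_id": cohort["participant_id"],
            "committed": cohort["gender"] == "male",
        })
        with pytest.raises((SeparationError,)):
            CommittedUserModel(summaries, cohort, covariates=("gender",)).fit()


class TestAdherenceModel:
    def test_recovers_disruption_effect_sign(self, fitted):
        summaries, cohort = fitted
        res = AdherenceModel(summaries, cohort).fit()
        est, lo, hi = res.effect("post_period")
        assert hi < 0  # adherence drops after the disruption
        assert lo < -1.4 < hi or abs(est + 1.4) < 0.2
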