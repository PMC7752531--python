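# flumob

Analysis pipeline for **participatory influenza-like-illness (ILI)
surveillance**: panels of volunteers (here, hospital health-care workers)
submit a short weekly symptom questionnaire through a mobile app, and the
resulting self-reports are turned into an epidemic signal that can be
compared against official sentinel surveillance.

The package takes three inputs — a participant roster with demographics and
enrollment windows, the raw weekly symptom reports (18 binary symptoms per
submission), and a sentinel weekly ILI% series — and produces:

* **Participation metrics.** The *individual submission rate* for
  participant *j* is s_j = (weeks with ≥1 submission) / (eligible weeks),
  where eligible weeks are the half-open enrollment window minus the system
  maintenance weeks; the *weekly reporting rate* is
  N_survey(i) / N_cumulative(i). A system-downtime week splits the study
  into pre/post periods compared by a paired *t* test on s_j^pre − s_j^post.
  Covariate structure is modelled two ways: a multivariable linear model of
  s_j with **adjusted rates per category level by marginal standardization**
  (predict for every participant with the level substituted, average over
  the cohort), and a multivariable logistic model of the *committed user*
  flag (≥2 reports after the disruption) reporting adjusted odds ratios
  with Wald 95% CIs.
* **Weekly ILI incidence.** ILI is fever (≥38.0 °C) with cough or sore
  throat. Multiple submissions in one participant-week are collapsed
  (symptomatic beats asymptomatic, latest wins within each class), ILI
  reports in consecutive weeks are merged into one episode contributing a
  single onset at its first week, and incidence in week *i* is
  ILI%(i) = 100 · onsets(i) / reports(i), smoothed as a trailing 4-week
  pooled moving proportion 100 · Σ onsets / Σ reports.
* **Surveillance power.** The Pearson correlation *r* between the 4-week
  moving proportions of the participatory and sentinel series, overall, for
  the pre-disruption period only, and re-computed within every participant
  stratum (gender, age group, job category, ethnicity, children in
  household, vaccination, allergy).

Because real participatory-surveillance data are rarely shareable, a seeded
**synthetic cohort** generator reproduces the statistical structure the
analysis assumes — covariate-dependent weekly reporting adherence with a
discrete post-disruption drop, occasional within-week duplicate
submissions, and an ILI episode process whose onset hazard is coupled to
the sentinel curve through a logistic link — so the whole pipeline is
testable end to end without any external data.

## Worked example

```python
from flumob import *

calendar = StudyCalendar()                      # 104 weeks, 10-week downtime
config = SimulationConfig(seed=1)               # 690-participant synthetic study
roster, reference, reports = simulate_study(config, calendar)
cohort, log = apply_exclusions(roster)
print(f"analysis cohort: {log.n_retained} of {log.n_input} recruited")

summaries = participation_summary(reports, cohort, calendar)
overall = cohort_summary(summaries)
print(f"mean individual submission rate: {100*overall['mean_submission_rate']:.1f}% "
      f"(pre {100*overall['mean_submission_rate_pre']:.1f}%, "
      f"post {100*overall['mean_submission_rate_post']:.1f}%)")
paired = paired_pre_post_test(summaries)
print(f"paired t({paired.df}) = {paired.t:.1f}, p = {format_p(paired.p_value)}")

panel = merge_episodes(dedupe_within_week(reports))
series = weekly_incidence(panel, calendar)
print(f"mean weekly ILI incidence: {series['ili_pct'].mean():.2f}%")

res = surveillance_correlation(series, reference, calendar,
                               period="before_maintenance")
print(f"surveillance power (pre-disruption): r = {res.r:.2f}, "
      f"p = {format_p(res.p_value)}, n = {res.n_weeks} weeks")
```

Output:

```
analysis cohort: 690 of 700 recruited
mean individual submission rate: 46.5% (pre 52.1%, post 21.4%)
paired t(689) = 59.6, p = <.001
mean weekly ILI incidence: 0.98%
surveillance power (pre-disruption): r = 0.43, p = 0.001, n = 54 weeks
```

Ten of 700 recruits are dropped (8 never completed registration, 2 never
submitted the background survey). Adherence collapses after the combined
system-downtime/incentive-end disruption — the paired *t* on the
per-participant pre−post rate differences is overwhelming — and the
pre-disruption participatory series tracks the sentinel curve (*r* = 0.43
over the 54 pre-downtime weeks with complete 4-week windows), while weekly
ILI incidence sits near 1%.

Regression summaries print in tabular form:

```python
print(SubmissionRateModel(summaries, cohort).fit().summary())
print(CommittedUserModel(summaries, cohort).fit().summary())
```

## Command line

```bash
flumob simulate --seed 1 --out data/            # roster.csv, reports.csv, reference.csv
flumob participation --roster data/roster.csv --reports data/reports.csv --out out/
flumob incidence --reports data/reports.csv --out out/
flumob surveillance --roster data/roster.csv --reports data/reports.csv \
    --reference data/reference.csv --out out/table4.csv
flumob run --seed 1 --out out/                  # everything, plus figures + manifest
```

All stages share one YAML configuration (see `flumob.config.default_config`)
covering the study calendar, the committed-user threshold, the moving-window
width and the simulator parameters; `flumob run` writes a `manifest.json`
with config hash, input checksums and per-stage row counts, and a fixed seed
reproduces every output table byte for byte.

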