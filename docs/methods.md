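# Methods

## Study structure and calendar

The pipeline models a fixed-panel participatory surveillance study:
participants enroll near the study start, commit to 78 weeks (18 months) of
weekly symptom reports, and may keep submitting afterwards until the system
closes (week 103). Weeks are integer indices over 7-day blocks aligned to a
configurable convention (`sunday_start` by default — epidemiological weeks;
`monday_start` and `iso` are equivalent alignments of the same arithmetic).
A contiguous block of whole weeks (default weeks 57–66, i.e. 2017-05-07
through 2017-07-15, exactly ten Sunday-to-Saturday weeks) marks a system
downtime during which no submissions exist; the first week after it is the
*disruption week*. The downtime coincided with the end of the participation
incentive, so the two are treated as a single disruption: the package makes
no attempt to separate their effects, and the simulator folds both into one
post-disruption adherence shift rather than modelling threshold-seeking
incentive behaviour.

Two different inclusion rules coexist deliberately:

* participation metrics use only reports inside a participant's own
  enrollment window `[enrollment_week, study_end_week)` (half-open, so a
  78-week commitment yields 78 candidate weeks before maintenance removal);
* incidence uses **all** retained reports, including those submitted after
  a participant's study end, because an epidemic signal has no reason to
  discard observed person-time.

Loaders therefore keep post-study-end and maintenance-flagged rows and let
each stage decide.

## Participation metrics

The individual submission rate is a per-participant proportion; the cohort
figure is the **mean of per-participant rates**, not a pooled count ratio —
participants with short windows weigh the same as long-stayers. Pre/post
rates split each participant's eligible weeks at the disruption week, and
the disruption contrast is a one-sample *t* on the paired differences
(df = n−1, two-sided). If the differences have zero variance the result is
flagged degenerate (t = 0 when the mean difference is also zero).

A *committed user* submitted at least `threshold` (default 2) report
entries in weeks from the disruption week up to and including their study
end week. The classification is monotone in both report count and
threshold.

### Covariate models

Three statsmodels-backed model classes follow the Model → `fit()` →
Results-with-`summary()` convention:

* `SubmissionRateModel` — OLS of the submission rate on gender, age group,
  job category, ethnicity, children in household, past-year influenza
  vaccination and allergy (reference levels: female, 21-30, nursing,
  Chinese, no, no, no). The **adjusted rate** for a level is computed by
  marginal standardization: substitute the level for every participant,
  predict, and average over the cohort. For a linear model this makes
  adjusted(level) − adjusted(reference) equal the raw coefficient exactly —
  a relationship the tests assert to 1e-10 — so the adjusted-rate table and
  the coefficient table are two views of one fit. Rank-deficient designs
  are rejected with the aliased columns named.
* `CommittedUserModel` — logistic regression of the committed flag on the
  same covariates; adjusted odds ratios with Wald 95% CIs (symmetric on the
  log scale). A constant outcome is rejected up front; complete separation
  is surfaced as a dedicated `SeparationError` (statsmodels' separation
  warning is promoted to an error, and a cleanly non-converged or exploding
  fit is treated the same) rather than returning divergent estimates. The
  results also expose per-stratum committed counts and percentages, since
  those are the natural companions of the ORs.
* `AdherenceModel` — binomial GLM of weekly reporting on the covariates
  plus a post-disruption indicator, used to verify that the generator's
  adherence parameters are recoverable. Each participant's weeks are
  aggregated into pre- and post-period (submitted, missed) counts; because
  the linear predictor is constant within a participant-period, this is
  likelihood-equivalent to the per-week Bernoulli model and ~50× smaller.

Rows with missing covariates are not imputed; the exclusion step already
removes participants without a complete background survey.

## Incidence

ILI is fever (self-reported, semantically ≥38.0 °C) together with cough or
sore throat. The weekly pipeline is:

1. **Within-week retention.** If a participant submitted several reports in
   one week, keep the latest *symptomatic* one if any submission reports at
   least one symptom, else the latest. The retention symptom set defaults
   to all 18 questionnaire items (the questionnaire groups gastrointestinal
   items under its acute-respiratory heading); a strictly respiratory
   subset is available via `symptom_set=RESPIRATORY_SYMPTOMS`.
2. **Episode merging.** Per participant, maximal runs of ILI reports in
   consecutive weeks (difference exactly 1) collapse to one onset at the
   run's first week. A gap week — missing *or* reported without ILI —
   terminates the run. Non-onset ILI rows keep their report and stay in
   denominators. The operation is idempotent and invariant to input row
   order, and its onset totals are checked against a brute-force
   run-length oracle on randomized panels.
3. **Weekly incidence.** ILI%(i) = 100 · onsets(i) / reports(i); weeks with
   no reports (including the whole maintenance block) are missing, never
   0/0. Merging can only lower a week's incidence.
4. **Moving proportion.** The default 4-week trailing window **pools**
   numerators and denominators (100 · Σ onsets / Σ reports) so
   high-denominator weeks carry more weight; an unweighted mean of weekly
   percentages is available (`method="mean"`) because the two differ
   whenever denominators vary and either reading of "4-week moving
   proportion" is defensible. Windows containing any report-free week are
   missing, as are the first width−1 weeks. The sentinel series carries no
   counts, so its moving proportion is the rolling mean of its weekly
   percentages.

## Surveillance power

Surveillance power is the Pearson correlation between the two moving-
proportion series on paired non-missing weeks, with the two-sided p-value
from the t transform on n−2 df. Fewer than 3 pairs, or a constant series,
yields a flagged degenerate result with no numeric r. The
`before_maintenance` period keeps weeks strictly before the downtime;
trailing windows guarantee those windows contain only pre-disruption weeks,
and windows that would straddle the gap on the far side are already missing
because the gap weeks have no reports. Stratified results re-run the
incidence pipeline on the panel restricted to each covariate level (each
participant contributes to exactly one level per covariate, so stratum
counts sum to the overall series week by week) and correlate against the
same sentinel curve.

Dropping pairs with either side missing is a choice, not a claim about how
any particular published analysis handled alignment; it is the only rule
consistent with the degenerate-week flagging above.

## Synthetic cohort

The generator emulates a two-hospital health-care-worker panel:

* **Roster** — 690 analysable participants plus 8 registration-incomplete
  and 2 background-incomplete recruits (exercising the exclusion filter);
  independent covariates at the recruited cohort's marginal frequencies
  (84.1% female, 37.4/39.6/13.3/9.7% across age groups, 56.4% Chinese,
  18.4% with children, 81.7% vaccinated, 25.8% with allergy; the published
  job-category proportions overlap slightly and are renormalized to a
  proper marginal). Enrollment is uniform over weeks 0–3.
* **Sentinel series** — baseline 1.5% + 0.8%·sin(2πt/26) + N(0, 0.15²),
  truncated to [0, 100]: a year-round ILI level with biannual peaks, the
  regime of an equatorial city rather than a single winter season.
* **Adherence** — each eligible participant-week reports with probability
  `logistic(logit(0.42) + covariate effects + (−1.4)·1[post])`. The
  reference-level 0.42 puts the marginal pre-disruption rate near 0.52 once
  the mean covariate effect (~+0.40 log-odds: +0.35/+0.60/+0.35 for the
  older age groups, −0.40 for non-Chinese, +0.40 for vaccinated) is
  folded in, and the −1.4 post shift drops it to ~0.21 — the adherence
  regime the analysis is designed for. With probability 0.01 a reporting
  week carries a second, later submission that duplicates the first's
  symptoms with probability 0.5 and is otherwise asymptomatic, exercising
  both branches of the retention rule.
* **Illness** — a two-state episode process runs every week whether or not
  the participant reports (reports reveal illness, they do not create it):
  onset hazard `logistic(−5.35 + 0.3·sentinel(t))`, giving ~1% weekly
  observed incidence at the default sentinel level, and geometric
  persistence 0.4 per week. An active episode sets fever and cough, plus
  sore throat with probability 0.5; all 18 symptoms also fire independently
  at low background rates (upper-respiratory complaints commonest, fever
  rare at 0.003 so background ILI noise stays small).

Everything is driven by `numpy.random.default_rng` seeded from one integer
(separate deterministic streams for roster, sentinel and reports), so a
fixed seed reproduces every table byte for byte.

### What the generator does *not* emulate

Adherence is independent Bernoulli given covariates: no autocorrelation, no
per-participant frailty, no permanent dropout. That is the minimal
structure needed to exercise every analysis rule (deduplication, episode
merging, the disruption contrast, stratified correlations), and it is why
the synthetic cohort's submission-rate dispersion (SD ≈ 0.10) and
committed-user share (~79%) are far tamer than a real panel's, where many
participants quit outright after a disruption. Passing tests show the
*pipeline arithmetic and inference machinery* are right under known
structure; they say nothing about adherence dynamics, reporting biases, or
health-care-seeking behaviour in real panels. Likewise there is no
transmission or contact structure — illness is independent across
participants given the sentinel curve.

## Numerical and design choices

* Week indices are plain integers from week 0, making "consecutive weeks"
  exact integer arithmetic; dates are stored as calendar dates.
* CSV round trips are exact: floats are written with shortest round-trip
  repr and parsed with correctly-rounded conversion (pandas' fast numeric
  parser can be off by one ulp, which matters for byte-identical
  re-analysis from saved inputs).
* The weekly reporting-rate denominator is cumulative enrollment, never
  decremented after participants pass their study end.
* A participant failing both exclusion criteria is counted under incomplete
  registration (the filter applies registration first).
* p-values are floored at "<.001" in *formatted* output only; CSVs keep
  raw values.
* The null-behaviour check of the sentinel correlation (uniform p-values
  when the illness–sentinel link is switched off) is run at window width 1:
  a 4-week moving average induces serial correlation in both series, which
  makes the nominal Pearson test anticonservative even under independence,
  so uniformity is a property of the unsmoothed series. The stochastic
  checks use a reduced cohort (n = 200) for the 200-seed null sweep and the
  full n = 690 for the 20-replicate parameter-recovery sweep, sizes at
  which each sweep completes in seconds while leaving the binomial noise
  on coverage and correlation well inside the asserted margins.

## Known limitations

* No mixed-effects or survival modelling of dropout, no imputation, no
  nowcasting/backfill correction, no lead/lag cross-correlation — the
  correlation is contemporaneous only.
* The committed-user logistic model can legitimately fail on small cohorts
  (quasi-separation); the pipeline logs and skips it rather than emitting
  divergent odds ratios.
* The sentinel alignment assumes both series share the configured week
  grid; reference dates are assigned to the surveillance week containing
  them, which silently absorbs off-by-a-few-days week conventions.
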