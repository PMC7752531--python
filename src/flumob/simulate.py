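"""Seeded synthetic cohort: roster, sentinel series and weekly reports.

The generator emulates the statistical structure a participatory ILI study
assumes, so every downstream stage has a no-download test surface:

* covariates drawn at the recruited cohort's marginal frequencies;
* weekly reporting adherence that depends on covariates through a logistic
  model, with a discrete log-odds drop from the disruption week onward;
* occasional second submissions within a reporting week;
* an ILI episode process (onset hazard tied to the sentinel series through a
  logistic link, geometric persistence week to week) that runs whether or not
  the participant reports, so reports reveal rather than create illness;
* background (non-ILI) symptoms at low independent rates.

Everything is driven by one integer seed; a fixed seed reproduces the output
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import DEFAULT_FOLLOWUP_WEEKS, SYMPTOM_COLUMNS
from .studycalendar import StudyCalendar

__all__ = ["SimulationConfig", "simulate_roster", "simulate_reference",
           "simulate_reports", "simulate_study"]


def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _normalized(probs: dict) -> dict:
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


# Marginal level frequencies of the recruited cohort (analysis sample of 690).
# The published job-category percentages overlap slightly (they sum to 108.4,
# the categories apparently not being mutually exclusive for some staff), so
# they are renormalized to a proper marginal here.
DEFAULT_CATEGORY_PROBS = {
    "gender": {"female": 0.841, "male": 0.159},
    "age_group": {"21-30": 0.374, "31-40": 0.396, "41-50": 0.133, ">50": 0.097},
    "job_category": _normalized({
        "nursing": 0.413,
        "administration_other": 0.165,
        "ancillary": 0.152,
        "allied_health": 0.270,
        "medical": 0.084,
    }),
    "ethnicity": {"chinese": 0.564, "other": 0.436},
    "children_in_household": {True: 0.184, False: 0.816},
    "vaccinated_past_year": {True: 0.817, False: 0.183},
    "allergy": {True: 0.258, False: 0.742},
    "hospital": {"TTSH": 5 / 7, "KKH": 2 / 7},
}

# Adherence log-odds shifts per covariate level (reference levels at 0),
# sized to give adjusted-rate contrasts of roughly 0.08-0.15 around a
# pre-disruption reporting probability of ~0.5.
DEFAULT_ADHERENCE_EFFECTS = {
    ("age_group", "31-40"): 0.35,
    ("age_group", "41-50"): 0.60,
    ("age_group", ">50"): 0.35,
    ("ethnicity", "other"): -0.40,
    ("vaccinated_past_year", True): 0.40,
}

# Low per-week background rates for non-ILI symptoms (upper-respiratory
# complaints commonest); fever kept rare so background ILI noise stays small.
DEFAULT_BACKGROUND_SYMPTOMS = {
    "fever": 0.003,
    "chills": 0.005,
    "runny_or_blocked_nose": 0.04,
    "sneezing": 0.03,
    "cough": 0.02,
    "sore_throat": 0.02,
    "shortness_of_breath": 0.003,
    "muscle_or_joint_pain": 0.01,
    "headache": 0.03,
    "malaise": 0.008,
    "loss_of_appetite": 0.005,
    "colored_phlegm": 0.008,
    "watery_bloodshot_eyes": 0.008,
    "nausea": 0.005,
    "vomiting": 0.003,
    "diarrhea": 0.008,
    "stomach_ache": 0.008,
    "chest_pain": 0.003,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    The defaults describe a two-hospital health-care-worker panel of 690
    analysable participants followed weekly for 18 months, with a 10-week
    system downtime after which adherence drops sharply.
    """

    # cohort composition
    n_participants: int = 690
    n_incomplete_registration: int = 8
    n_incomplete_background: int = 2
    enrollment_weeks: tuple = (0, 1, 2, 3)
    followup_weeks: int = DEFAULT_FOLLOWUP_WEEKS
    category_probs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_CATEGORY_PROBS.items()
    })

    # weekly reporting adherence; p_report is the reference-level probability
    # (the average covariate effect of ~+0.40 log-odds lifts the marginal
    # pre-disruption reporting rate to roughly 0.52)
    p_report: float = 0.42
    adherence_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_ADHERENCE_EFFECTS)
    )
    post_disruption_logodds: float = -1.4
    p_multi: float = 0.01
    p_multi_duplicate: float = 0.5

    # sentinel (reference) series: baseline + seasonal sinusoid + noise, in %
    ref_baseline: float = 1.5
    ref_amplitude: float = 0.8
    ref_period: float = 26.0
    ref_noise_sd: float = 0.15

    # ILI episode process
    ili_baseline_logodds: float = -5.35
    ili_link_slope: float = 0.3
    sore_throat_prob: float = 0.5
    episode_continuation: float = 0.4
    background_symptom_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_SYMPTOMS)
    )

    seed: int = 0

    def validate(self) -> None:
        for name in ("p_report", "p_multi", "p_multi_duplicate",
                     "sore_throat_prob", "episode_continuation"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        for fieldname, probs in self.category_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"marginal probabilities for {fieldname} sum to {total}, not 1"
                )
            if any(not 0.0 <= p <= 1.0 for p in probs.values()):
                raise ValueError(f"marginal probabilities for {fieldname} outside [0,1]")
        for symptom, p in self.background_symptom_probs.items():
            if symptom not in SYMPTOM_COLUMNS:
                raise ValueError(f"unknown symptom {symptom!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"background probability for {symptom} outside [0,1]")
        if self.followup_weeks < 1:
            raise ValueError("followup_weeks must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Copy with fields replaced."""
        return replace(self, **kwargs)


def _rng(config: SimulationConfig, stream: int, seed=None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng([int(base), stream])


def simulate_roster(config: SimulationConfig, calendar: StudyCalendar,
                    seed=None) -> pd.DataFrame:
    """Draw a participant roster with independent covariates at the configured
    marginals.

    The roster includes the recruits later excluded from analysis: the first
    ``n_incomplete_registration`` rows never completed registration and the
    next ``n_incomplete_background`` completed registration but not the
    background survey.
    """
    config.validate()
    rng = _rng(config, 1, seed)
    n_total = (config.n_participants + config.n_incomplete_registration
               + config.n_incomplete_background)
    width = len(str(n_total))
    df = pd.DataFrame({
        "participant_id": [f"P{i:0{width}d}" for i in range(1, n_total + 1)]
    })
    for fieldname, probs in config.category_probs.items():
        levels = list(probs)
        p = np.array([probs[l] for l in levels], dtype=float)
        p = p / p.sum()
        draws = rng.choice(len(levels), size=n_total, p=p)
        values = [levels[i] for i in draws]
        df[fieldname] = values
    enroll = rng.choice(np.asarray(config.enrollment_weeks), size=n_total)
    df["enrollment_week"] = enroll.astype(int)
    df["study_end_week"] = df["enrollment_week"] + config.followup_weeks
    df["enrollment_date"] = [calendar.week_start_date(w) for w in df["enrollment_week"]]
    df["study_end_date"] = [calendar.week_start_date(w) for w in df["study_end_week"]]
    flags_reg = np.ones(n_total, dtype=bool)
    flags_bg = np.ones(n_total, dtype=bool)
    flags_reg[: config.n_incomplete_registration] = False
    flags_bg[config.n_incomplete_registration:
             config.n_incomplete_registration + config.n_incomplete_background] = False
    df["registration_complete"] = flags_reg
    df["background_complete"] = flags_bg
    return df


def simulate_reference(config: SimulationConfig, calendar: StudyCalendar,
                       seed=None) -> pd.DataFrame:
    """Sentinel weekly ILI% series: baseline + seasonal sinusoid + Gaussian
    noise, truncated to [0, 100]."""
    config.validate()
    rng = _rng(config, 2, seed)
    weeks = np.arange(calendar.study_start_week, calendar.study_close_week + 1)
    values = (config.ref_baseline
              + config.ref_amplitude * np.sin(2 * np.pi * weeks / config.ref_period))
    if config.ref_noise_sd > 0:
        values = values + rng.normal(0.0, config.ref_noise_sd, size=weeks.size)
    values = np.clip(values, 0.0, 100.0)
    return pd.DataFrame({"week": weeks.astype(int), "ili_pct": values})


def _adherence_logodds(roster: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    lin = np.full(len(roster), _logit(config.p_report))
    for (fieldname, level), effect in config.adherence_effects.items():
        lin = lin + effect * (roster[fieldname].to_numpy() == level)
    return lin


def simulate_reports(roster: pd.DataFrame, reference: pd.DataFrame,
                     calendar: StudyCalendar, config: SimulationConfig,
                     seed=None) -> pd.DataFrame:
    """Generate weekly symptom reports for every registered participant.

    For each week from enrollment to the study close (participants keep
    submitting past their individual study end dates), excluding maintenance
    weeks, a report is submitted with probability
    ``logistic(logit(p_report) + covariate effects + post_disruption_logodds
    * 1[week >= disruption_week])``.  A reporting week emits one report, plus
    a second with probability ``p_multi`` (duplicating the first's symptoms
    with probability ``p_multi_duplicate``, else asymptomatic).
    """
    config.validate()
    if roster.empty:
        raise ValueError("roster is empty")
    rng = _rng(config, 3, seed)
    active = roster[roster["registration_complete"]].reset_index(drop=True)
    n = len(active)
    pids = active["participant_id"].to_numpy()
    enroll = active["enrollment_week"].to_numpy()
    lin = _adherence_logodds(active, config)
    ref = reference.set_index("week")["ili_pct"]

    bg_probs = np.array(
        [config.background_symptom_probs.get(s, 0.0) for s in SYMPTOM_COLUMNS]
    )
    isym = {s: i for i, s in enumerate(SYMPTOM_COLUMNS)}

    in_episode = np.zeros(n, dtype=bool)
    rows_pid, rows_time, rows_week = [], [], []
    rows_symptoms = []

    for week in calendar.study_weeks():
        eligible = enroll <= week
        # illness evolves every week, observed or not
        onset_p = _sigmoid(config.ili_baseline_logodds
                           + config.ili_link_slope * float(ref.get(week, 0.0)))
        onset = (~in_episode) & eligible & (rng.random(n) < onset_p)
        cont = in_episode & (rng.random(n) < config.episode_continuation)
        in_episode = onset | cont

        if calendar.is_maintenance(week):
            continue
        p_rep = _sigmoid(lin + config.post_disruption_logodds
                         * (week >= calendar.disruption_week))
        reporting = eligible & (rng.random(n) < p_rep)
        idx = np.flatnonzero(reporting)
        if idx.size == 0:
            continue

        symptoms = rng.random((idx.size, len(SYMPTOM_COLUMNS))) < bg_probs
        ili = in_episode[idx]
        symptoms[ili, isym["fever"]] = True
        symptoms[ili, isym["cough"]] = True
        sore = ili & (rng.random(idx.size) < config.sore_throat_prob)
        symptoms[sore, isym["sore_throat"]] = True

        offsets = rng.integers(0, 6 * 86400, size=idx.size)
        week_start = pd.Timestamp(calendar.week_start_date(week))
        times = week_start + pd.to_timedelta(offsets, unit="s")
        rows_pid.append(pids[idx])
        rows_time.append(times)
        rows_week.append(np.full(idx.size, week))
        rows_symptoms.append(symptoms)

        # occasional second submission within the same week, always later
        second = rng.random(idx.size) < config.p_multi
        jdx = np.flatnonzero(second)
        if jdx.size:
            dup = rng.random(jdx.size) < config.p_multi_duplicate
            symptoms2 = np.zeros((jdx.size, len(SYMPTOM_COLUMNS)), dtype=bool)
            symptoms2[dup] = symptoms[jdx[dup]]
            offsets2 = offsets[jdx] + rng.integers(1, 86400, size=jdx.size)
            times2 = week_start + pd.to_timedelta(offsets2, unit="s")
            rows_pid.append(pids[idx[jdx]])
            rows_time.append(times2)
            rows_week.append(np.full(jdx.size, week))
            rows_symptoms.append(symptoms2)

    if not rows_pid:
        columns = ["participant_id", "submitted_at", "week", "in_maintenance"]
        return pd.DataFrame(
            {c: [] for c in columns[:2] + list(SYMPTOM_COLUMNS) + columns[2:]}
        )
    df = pd.DataFrame({
        "participant_id": np.concatenate(rows_pid),
        "submitted_at": pd.DatetimeIndex(np.concatenate(
            [t.to_numpy() for t in rows_time])),
    })
    symptom_matrix = np.vstack(rows_symptoms)
    for i, s in enumerate(SYMPTOM_COLUMNS):
        df[s] = symptom_matrix[:, i]
    df["week"] = np.concatenate(rows_week).astype(int)
    df["in_maintenance"] = False
    df = df.sort_values(["participant_id", "submitted_at"], kind="mergesort")
    return df.reset_index(drop=True)


def simulate_study(config: SimulationConfig, calendar: StudyCalendar | None = None,
                   seed=None):
    """Convenience: (roster, reference, reports) from one config and seed."""
    calendar = calendar or StudyCalendar()
    roster = simulate_roster(config, calendar, seed=seed)
    reference = simulate_reference(config, calendar, seed=seed)
    reports = simulate_reports(roster, reference, calendar, config, seed=seed)
    return roster, reference, reports
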