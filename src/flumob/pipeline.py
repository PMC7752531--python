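"""End-to-end orchestration: simulate -> participation -> incidence ->
surveillance, with a run manifest for reproducibility auditing."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import apply_exclusions
from .config import calendar_from_config, default_config, simulation_from_config
from .incidence import dedupe_within_week, episode_summary, merge_episodes, \
    moving_proportion, reference_moving, weekly_incidence
from .io import load_reference, load_reports, load_roster, write_reference, \
    write_reports, write_roster
from .participation import CommittedUserModel, SeparationError, \
    SubmissionRateModel, cohort_summary, paired_pre_post_test, \
    participation_summary, weekly_reporting_rate
from .simulate import simulate_reference, simulate_reports, simulate_roster
from .surveillance import stratified_correlations

logger = logging.getLogger("flumob")

ALL_STAGES = ("simulate", "participation", "incidence", "surveillance")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    version: str
    stages: list
    inputs: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    started_at: str = ""
    finished_at: str = ""
    complete: bool = False

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    canonical = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(cfg: dict | None = None, seed: int | None = None,
                 out_dir="flumob_out", stages=ALL_STAGES,
                 make_plots: bool = True) -> RunManifest:
    """Execute the requested stages in order, writing all artifact tables to
    ``out_dir`` and returning the run manifest (also written as
    ``manifest.json``).  Any stage failure aborts with the stage name."""
    cfg = cfg if cfg is not None else default_config()
    stages = tuple(s for s in ALL_STAGES if s in set(stages))
    if not stages:
        raise ValueError("no recognised stages requested")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calendar = calendar_from_config(cfg)
    manifest = RunManifest(
        config_hash=_config_hash(cfg), seed=seed, version=__version__,
        stages=list(stages),
        started_at=dt.datetime.now().isoformat(timespec="seconds"),
    )
    logger.info("maintenance window: %d weeks (%s..%s), disruption week %d",
                len(calendar.maintenance_weeks), calendar.maintenance_start,
                calendar.maintenance_end, calendar.disruption_week)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                manifest.complete = False
                manifest.write(out / "manifest.json")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    # ---- inputs -----------------------------------------------------------
    if "simulate" in stages:
        @stage("simulate")
        def _simulate():
            sim = simulation_from_config(cfg, seed=seed)
            roster = simulate_roster(sim, calendar)
            reference = simulate_reference(sim, calendar)
            reports = simulate_reports(roster, reference, calendar, sim)
            write_roster(roster, out / "roster.csv")
            write_reports(reports, out / "reports.csv")
            write_reference(reference, out / "reference.csv", calendar)
            return roster, reference, reports

        roster, reference, reports = _simulate
        for name in ("roster", "reports", "reference"):
            manifest.inputs[name] = {
                "path": str(out / f"{name}.csv"),
                "sha256": _sha256(out / f"{name}.csv"),
            }
    else:
        @stage("load-inputs")
        def _load():
            paths = cfg.get("inputs", {})
            loaded = {}
            for name, loader in (("roster", load_roster),
                                 ("reports", load_reports),
                                 ("reference", load_reference)):
                path = paths.get(name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(
                        f"required input {name!r} not found "
                        f"(configured path: {path})"
                    )
                loaded[name] = loader(path, calendar)
                manifest.inputs[name] = {"path": str(path),
                                         "sha256": _sha256(path)}
            return loaded["roster"], loaded["reference"], loaded["reports"]

        roster, reference, reports = _load

    manifest.row_counts["roster"] = len(roster)
    manifest.row_counts["reports"] = len(reports)
    manifest.row_counts["reference"] = len(reference)

    cohort, exclusions = apply_exclusions(roster)
    manifest.summaries["exclusions"] = asdict_excl(exclusions)
    manifest.row_counts["cohort"] = len(cohort)
    logger.info("exclusions: %d registration-incomplete, %d background-incomplete, "
                "%d retained of %d", exclusions.n_registration_incomplete,
                exclusions.n_background_incomplete, exclusions.n_retained,
                exclusions.n_input)

    analysis = cfg.get("analysis", {})
    width = int(analysis.get("moving_window", 4))
    threshold = int(analysis.get("committed_threshold", 2))
    strata = analysis.get("strata", [])

    summaries = None
    if "participation" in stages:
        @stage("participation")
        def _participation():
            summaries = participation_summary(reports, cohort, calendar,
                                              committed_threshold=threshold)
            weekly = weekly_reporting_rate(reports, cohort, calendar)
            summaries.to_csv(out / "participation_summary.csv", index=False)
            weekly.to_csv(out / "weekly_rates.csv", index=False)
            overall = cohort_summary(summaries)
            paired = paired_pre_post_test(summaries)
            overall.update({
                "paired_t": paired.t, "paired_df": paired.df,
                "paired_p": paired.p_value,
            })
            try:
                sub = SubmissionRateModel(summaries, cohort).fit()
                sub.adjusted_rates().to_csv(out / "model_submission.csv",
                                            index=False)
            except ValueError as exc:
                logger.warning("submission-rate model skipped: %s", exc)
            try:
                com = CommittedUserModel(summaries, cohort).fit()
                com.odds_ratios().merge(
                    com.stratum_table(), on=["covariate", "level"]
                ).to_csv(out / "model_committed.csv", index=False)
            except (ValueError, SeparationError) as exc:
                logger.warning("committed-user model skipped: %s", exc)
            if make_plots:
                from .plots import plot_weekly_reporting_rate
                plot_weekly_reporting_rate(weekly, calendar,
                                           out / "weekly_reporting_rate.png")
            return summaries, overall

        summaries, overall = _participation
        manifest.row_counts["participation_summary"] = len(summaries)
        manifest.summaries["participation"] = overall

    panel = None
    series = None
    if "incidence" in stages or "surveillance" in stages:
        @stage("incidence")
        def _incidence():
            panel = merge_episodes(dedupe_within_week(reports))
            series = weekly_incidence(panel, calendar)
            series = moving_proportion(series, width=width,
                                       method=analysis.get("moving_method",
                                                           "pooled"))
            if "incidence" in stages:
                panel_out = panel[["participant_id", "week", "submitted_at",
                                   "any_symptom", "is_ili", "onset"]]
                panel_out.to_csv(out / "panel.csv", index=False)
                series.rename(columns={"ili_pct": "ili_pct_flumob"}).to_csv(
                    out / "incidence.csv", index=False)
            return panel, series

        panel, series = _incidence
        manifest.row_counts["panel"] = len(panel)
        valid = series["ili_pct"].dropna()
        manifest.summaries["incidence"] = {
            "mean_weekly_ili_pct": float(valid.mean()) if len(valid) else None,
            **episode_summary(panel, cohort),
        }

    if "surveillance" in stages:
        @stage("surveillance")
        def _surveillance():
            table = stratified_correlations(panel, cohort, reference, calendar,
                                            strata=strata, width=width)
            table.to_csv(out / "surveillance.csv", index=False)
            if make_plots:
                from .plots import plot_incidence_vs_reference
                plot_incidence_vs_reference(series,
                                            reference_moving(reference, width),
                                            calendar,
                                            out / "incidence_vs_reference.png")
            return table

        table = _surveillance
        manifest.row_counts["surveillance"] = len(table)
        overall_rows = table[table["stratum"] == "overall"]
        manifest.summaries["surveillance"] = {
            row["period"]: {"r": row["r"], "p_value": row["p_value"],
                            "n_weeks": int(row["n_weeks"])}
            for _, row in overall_rows.iterrows()
        }

    manifest.finished_at = dt.datetime.now().isoformat(timespec="seconds")
    manifest.complete = True
    manifest.write(out / "manifest.json")
    return manifest


def asdict_excl(log) -> dict:
    return {
        "n_input": log.n_input,
        "n_registration_incomplete": log.n_registration_incomplete,
        "n_background_incomplete": log.n_background_incomplete,
        "n_retained": log.n_retained,
    }
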