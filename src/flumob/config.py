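"""YAML configuration: one document governs every pipeline stage."""

from __future__ import annotations

import copy

import yaml

from .simulate import SimulationConfig
from .studycalendar import StudyCalendar

DEFAULT_CONFIG = {
    "calendar": {
        "study_start_date": "2016-04-03",
        "study_close_week": 103,
        "maintenance_start": "2017-05-07",
        "maintenance_end": "2017-07-15",
        "week_convention": "sunday_start",
    },
    "analysis": {
        "committed_threshold": 2,
        "moving_window": 4,
        "moving_method": "pooled",
        "strata": [
            "gender", "age_group", "job_category", "ethnicity",
            "children_in_household", "vaccinated_past_year", "allergy",
        ],
    },
    "simulation": {},      # SimulationConfig field overrides
    "inputs": {},          # roster/reports/reference paths when not simulating
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path) -> dict:
    """Load a YAML config, filling unspecified sections with defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if values is None:
            continue
        if isinstance(cfg[section], dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def calendar_from_config(cfg: dict) -> StudyCalendar:
    c = cfg.get("calendar", {})
    return StudyCalendar(
        study_start_date=c.get("study_start_date", "2016-04-03"),
        study_close_week=int(c.get("study_close_week", 103)),
        maintenance_start=c.get("maintenance_start", "2017-05-07"),
        maintenance_end=c.get("maintenance_end", "2017-07-15"),
        week_convention=c.get("week_convention", "sunday_start"),
    )


def simulation_from_config(cfg: dict, seed=None) -> SimulationConfig:
    kwargs = dict(cfg.get("simulation", {}))
    if "adherence_effects" in kwargs and isinstance(kwargs["adherence_effects"], dict):
        # YAML mappings cannot key on tuples; accept "field:level" strings
        fixed = {}
        for key, value in kwargs["adherence_effects"].items():
            if isinstance(key, str) and ":" in key:
                fieldname, level = key.split(":", 1)
                if level in ("true", "True"):
                    level = True
                elif level in ("false", "False"):
                    level = False
                fixed[(fieldname, level)] = float(value)
            else:
                fixed[key] = float(value)
        kwargs["adherence_effects"] = fixed
    if "enrollment_weeks" in kwargs:
        kwargs["enrollment_weeks"] = tuple(kwargs["enrollment_weeks"])
    if seed is not None:
        kwargs["seed"] = int(seed)
    config = SimulationConfig(**kwargs)
    config.validate()
    return config
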