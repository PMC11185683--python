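"""Parameter and scenario configuration files (YAML, with JSON accepted)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model_core import PatientParams
from .simulate import (MealSchedule, InsulinProtocol, Phase, ScenarioTimeline)

__all__ = [
    "load_params",
    "save_params",
    "load_timeline",
    "timeline_to_dict",
]


def _read_mapping(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_params(path) -> PatientParams:
    """Read a flat symbol-keyed parameter mapping (SE, SI, gamma, ...)."""
    return PatientParams.from_dict(_read_mapping(path))


def save_params(params: PatientParams, path) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def _meals_from_dict(d: dict) -> MealSchedule:
    return MealSchedule(
        daily_total=float(d.get("daily_total_mg_per_dL_day", 0.0)),
        meals_per_day=int(d.get("meals_per_day", 3)),
        meal_duration=float(d.get("meal_duration_days", 1.0 / 48.0)),
        meal_times=tuple(d.get("meal_times_day_fraction",
                               MealSchedule.meal_times)),
    )


def _insulin_from_dict(d: dict) -> InsulinProtocol:
    return InsulinProtocol(
        mode=d.get("mode", "none"),
        FI=float(d.get("FI_uU_per_mL_day", 0.0)),
        target_G=float(d.get("target_G_mg_per_dL", 90.0)),
        update_interval=float(d.get("update_interval_days", 3.0)),
    )


def load_timeline(path) -> ScenarioTimeline:
    """Read a scenario timeline: a list of phases under the key ``phases``.

    Each phase is a mapping with ``duration_days`` and optional ``meals``
    and ``insulin`` sub-mappings (unit-bearing key names throughout).
    """
    data = _read_mapping(path)
    phases = data.get("phases")
    if not phases:
        raise ValueError(f"{path}: no phases defined")
    out = []
    for i, ph in enumerate(phases):
        out.append(Phase(
            duration=float(ph["duration_days"]),
            meals=_meals_from_dict(ph.get("meals", {})),
            insulin=_insulin_from_dict(ph.get("insulin", {})),
            name=str(ph.get("name", f"phase{i}")),
        ))
    return ScenarioTimeline(tuple(out))


def timeline_to_dict(timeline: ScenarioTimeline) -> dict:
    return {"phases": [
        {
            "name": ph.name,
            "duration_days": ph.duration,
            "meals": {
                "daily_total_mg_per_dL_day": ph.meals.daily_total,
                "meals_per_day": ph.meals.meals_per_day,
                "meal_duration_days": ph.meals.meal_duration,
                "meal_times_day_fraction": list(ph.meals.meal_times),
            },
            "insulin": {
                "mode": ph.insulin.mode,
                "FI_uU_per_mL_day": ph.insulin.FI,
                "target_G_mg_per_dL": ph.insulin.target_G,
                "update_interval_days": ph.insulin.update_interval,
            },
        } for ph in timeline.phases
    ]}
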