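"""Configuration and results I/O.

Run configurations are YAML or JSON with sections::

    model:    {L, a, D, A, v}
    schedule: {p, r}  or  {d_open, d_closed}
    water:    {D_w, k, I, A_w}        # optional; presence selects water runs
    sim:      {n_x, dt, t_burn, t_sample, n_realizations, seed}

Profiles are written as CSV (x, mean, se) and run summaries as JSON with all
floats at full precision; with a fixed seed a rerun produces byte-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .model import FlutterSchedule, TrachealModel, WaterModel
from .sim import EnsembleResult, SimulationGrid

__all__ = [
    "load_config",
    "write_profile_csv",
    "write_summary_json",
]

_SECTION_FIELDS = {
    "model": {"L", "a", "D", "A", "v"},
    "schedule": {"p", "r", "d_open", "d_closed"},
    "water": {"D_w", "k", "I", "A_w"},
    "sim": {"n_x", "dt", "t_burn", "t_sample", "n_realizations", "seed"},
}


def _check_fields(section: str, data: dict) -> None:
    unknown = set(data) - _SECTION_FIELDS[section]
    if unknown:
        raise ValueError(
            f"config section {section!r}: unknown field(s) {sorted(unknown)}"
        )


def load_config(path: str | Path) -> dict:
    """Parse and validate a run configuration.

    Returns a dict with keys ``model`` (:class:`TrachealModel`), ``schedule``
    (:class:`FlutterSchedule`), ``sim`` (:class:`SimulationGrid`) and, when a
    water section is present, ``water`` (:class:`WaterModel`).  Field errors
    name the section and field.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTION_FIELDS)
    if unknown:
        raise ValueError(f"config {path}: unknown section(s) {sorted(unknown)}")
    if "model" not in raw:
        raise ValueError(f"config {path}: missing required section 'model'")
    if "schedule" not in raw:
        raise ValueError(f"config {path}: missing required section 'schedule'")

    out: dict = {}
    _check_fields("model", raw["model"])
    try:
        out["model"] = TrachealModel(**raw["model"])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section 'model': {exc}") from exc

    sched = dict(raw["schedule"])
    _check_fields("schedule", sched)
    try:
        if "d_open" in sched or "d_closed" in sched:
            if set(sched) != {"d_open", "d_closed"}:
                raise ValueError(
                    "give either fields (p, r) or (d_open, d_closed), not a mix"
                )
            out["schedule"] = FlutterSchedule.from_durations(
                sched["d_open"], sched["d_closed"]
            )
        else:
            out["schedule"] = FlutterSchedule(**sched)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section 'schedule': {exc}") from exc

    if "water" in raw:
        _check_fields("water", raw["water"])
        try:
            out["water"] = WaterModel(**raw["water"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"config section 'water': {exc}") from exc

    sim = raw.get("sim", {})
    _check_fields("sim", sim)
    try:
        out["sim"] = SimulationGrid(**sim)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section 'sim': {exc}") from exc
    return out


def write_profile_csv(path: str | Path, result: EnsembleResult) -> Path:
    """Write the ensemble mean profile as CSV columns x, mean, se."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("x,mean,se\n")
        for x, m, s in zip(result.x_grid, result.mean_profile, result.profile_se):
            fh.write(f"{x!r},{m!r},{s!r}\n")
    return path


def write_summary_json(
    path: str | Path, result: EnsembleResult, settings: SimulationGrid
) -> Path:
    """Write a JSON run summary (uptake, se, realized_p, seed, settings).

    Deterministic byte-for-byte for a given seed and settings.
    """
    import math

    path = Path(path)
    payload = {
        "uptake_mean": result.uptake_mean,
        "uptake_se": result.uptake_se,
        "realized_p": result.realized_p,
        "realized_p_se": (
            None if math.isnan(result.realized_p_se) else result.realized_p_se
        ),
        "n_switches": result.n_switches,
        "seed": result.seed,
        "settings": dataclasses.asdict(settings),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
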