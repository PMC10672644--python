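"""JSON (de)serialization of the simulation configuration.

The JSON layout mirrors the configuration dataclasses; every key is
optional and falls back to the package default, so a minimal file like
``{"menopause": {"preset": "combined"}}`` is valid.  Menopause schedules
may either name a preset or spell out the κ parameters per channel.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .engine import DEFAULT_ENSEMBLE, SimulationConfig, SiteSpec
from .kinetics import BMUParams, MineralizationLaw
from .menopause import KappaParams, MenopauseSchedule, PRESETS
from .stimulus import LoadSchedule, StimulusParams
from .tissue import TissueConstants

__all__ = ["config_from_dict", "config_to_dict", "load_config", "save_config"]


def _build(cls, payload: dict | None):
    return cls(**payload) if payload else cls()


def _menopause_from_dict(payload: dict | None) -> MenopauseSchedule:
    if not payload:
        return PRESETS["none"]
    if "preset" in payload:
        return PRESETS[payload["preset"]]
    return MenopauseSchedule(
        kappa_fbio=_build(KappaParams, payload.get("kappa_fbio")),
        kappa_fbb=_build(KappaParams, payload.get("kappa_fbb")),
        scenario=payload.get("scenario", "combined"),
    )


def config_from_dict(payload: dict) -> SimulationConfig:
    kwargs: dict = {}
    if "tissue" in payload:
        kwargs["tissue"] = _build(TissueConstants, payload["tissue"])
    if "bmu" in payload:
        kwargs["bmu"] = _build(BMUParams, payload["bmu"])
    if "mineralization" in payload:
        kwargs["mineralization"] = _build(MineralizationLaw, payload["mineralization"])
    if "stimulus" in payload:
        kwargs["stimulus"] = _build(StimulusParams, payload["stimulus"])
    if "sv_coeffs" in payload:
        kwargs["sv_coeffs"] = tuple(payload["sv_coeffs"])
    if "habitual_strains" in payload:
        kwargs["habitual_strains"] = tuple(
            (e["label"], float(e["cycles_per_day"]), float(e["strain_target"]))
            for e in payload["habitual_strains"]
        )
    if "sites" in payload:
        kwargs["sites"] = tuple(
            SiteSpec(s["label"], float(s["weight"]), float(s["initial_vb"]))
            for s in payload["sites"]
        )
    if "menopause" in payload:
        kwargs["menopause"] = _menopause_from_dict(payload["menopause"])
    if "load_schedule" in payload:
        kwargs["load_schedule"] = _build(LoadSchedule, payload["load_schedule"])
    for key in (
        "t_start",
        "t_end",
        "initial_tissue_age_years",
        "coalesce_gap_days",
        "run_in_tolerance",
        "max_run_in_years",
    ):
        if key in payload:
            kwargs[key] = payload[key]
    return SimulationConfig(**kwargs)


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "tissue": dataclasses.asdict(config.tissue),
        "bmu": dataclasses.asdict(config.bmu),
        "mineralization": dataclasses.asdict(config.mineralization),
        "stimulus": dataclasses.asdict(config.stimulus),
        "sv_coeffs": list(config.sv_coeffs),
        "habitual_strains": [
            {"label": l, "cycles_per_day": n, "strain_target": e}
            for l, n, e in config.habitual_strains
        ],
        "sites": [dataclasses.asdict(s) for s in config.sites],
        "menopause": {
            "scenario": config.menopause.scenario,
            "kappa_fbio": dataclasses.asdict(config.menopause.kappa_fbio),
            "kappa_fbb": dataclasses.asdict(config.menopause.kappa_fbb),
        },
        "load_schedule": dataclasses.asdict(config.load_schedule),
        "t_start": config.t_start,
        "t_end": config.t_end,
        "initial_tissue_age_years": config.initial_tissue_age_years,
        "coalesce_gap_days": config.coalesce_gap_days,
        "run_in_tolerance": config.run_in_tolerance,
        "max_run_in_years": config.max_run_in_years,
    }


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2))
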