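"""Run configuration: defaults, validation, and file round-tripping.

A run is fully described by a nested mapping (JSON or YAML) with three
blocks — ``population``, ``model``, ``analysis`` — plus a root seed, output
directory and log level.  Unknown keys are rejected by dotted name, defaults
fill absent keys, and the effective (post-default) configuration is echoed
to the output directory so a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .model import ModelParams, NeocytolysisParams
from .population import (
    LognormSpec,
    PopulationSpecs,
    fit_lognormal_from_quantiles,
    fit_truncated_normal,
)
from .requirement import AnalysisConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "default_config_dict"]

_DEFAULTS: dict[str, Any] = {
    "seed": 1,
    "output_dir": "out",
    "log_level": "INFO",
    "population": {
        "n": 6659,
        "seed": None,  # falls back to the root seed
        "life_span": {"mean": 76.0, "sd": 21.0, "min": 33.0, "max": 137.0},
        "endogenous_epo": {"median": 15.0, "q25": 10.2, "q75": 21.1},
        "esa_half_life": {"median": 20.0, "log_sd": 0.3},
        "apoptosis_sensitivity": {"median": 30.0, "log_sd": 0.4},
        "maturation_factor": {"median": 0.5, "log_sd": 0.4},
    },
    "model": {
        "stem_influx": 1.0,
        "proliferation_rate": 0.7,
        "apoptosis_max": 0.35,
        "hill_exponent": 2.0,
        "cfu_residence": 6.0,
        "proliferation_window": 5.0,
        "maturation_delay": 3.0,
        "epo_cap": 10000.0,
        "hct_per_hb": 3.0,
        "neocytolysis": {
            "enabled": False,
            "age_cutoff": 10.0,
            "epo_threshold": 10.0,
            "extra_rate": 0.05,
        },
        "calibration": {"life_span": 120.0, "epo": 15.0, "hemoglobin": 14.0},
    },
    "analysis": {
        "hb_lo": 10.49,
        "hb_hi": 10.51,
        "lifespan_bin_width": 10.0,
        "epo_bin_start": 5.0,
        "epo_bin_width": 10.0,
        "min_cell_count": 25,
        "clamp_negative_delta": True,
    },
}


class ConfigError(ValueError):
    """Configuration parse or validation failure; the message names the key."""


def default_config_dict() -> dict[str, Any]:
    return copy.deepcopy(_DEFAULTS)


def _merge(defaults: Mapping[str, Any], given: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    """Overlay ``given`` on ``defaults``, rejecting keys absent from defaults."""
    out: dict[str, Any] = {}
    for key, default_value in defaults.items():
        dotted = f"{prefix}{key}"
        if key not in given:
            out[key] = copy.deepcopy(default_value)
        elif isinstance(default_value, Mapping):
            sub = given[key]
            if not isinstance(sub, Mapping):
                raise ConfigError(f"config key '{dotted}' must be a mapping")
            out[key] = _merge(default_value, sub, prefix=f"{dotted}.")
        else:
            out[key] = given[key]
    for key in given:
        if key not in defaults:
            raise ConfigError(f"unknown config key '{prefix}{key}'")
    return out


def _require(cond: bool, key: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"invalid config key '{key}': {message}")


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted description of one pipeline run."""

    raw: dict[str, Any]  # effective (post-default) mapping
    n: int
    seed: int
    population_seed: int
    output_dir: Path
    log_level: str
    specs: PopulationSpecs
    model: ModelParams  # uncalibrated; pipeline calibrates kappa
    calibration: dict[str, float]
    analysis: AnalysisConfig

    def echo(self, directory: Path | None = None) -> Path:
        """Write the effective config as YAML; returns the file path."""
        directory = Path(directory) if directory is not None else self.output_dir
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "effective_config.yaml"
        path.write_text(yaml.safe_dump(self.raw, sort_keys=True))
        return path


def _build(effective: dict[str, Any]) -> RunConfig:
    pop = effective["population"]
    _require(isinstance(pop["n"], int) and pop["n"] >= 1, "population.n", "must be an integer >= 1")
    ls = pop["life_span"]
    _require(ls["min"] < ls["mean"] < ls["max"], "population.life_span", "require min < mean < max")
    _require(ls["sd"] > 0, "population.life_span.sd", "must be positive")
    ee = pop["endogenous_epo"]
    _require(
        0 < ee["q25"] < ee["median"] < ee["q75"],
        "population.endogenous_epo",
        "require 0 < q25 < median < q75",
    )
    lognorm_blocks = {}
    for name in ("esa_half_life", "apoptosis_sensitivity", "maturation_factor"):
        block = pop[name]
        _require(block["median"] > 0, f"population.{name}.median", "must be positive")
        _require(block["log_sd"] > 0, f"population.{name}.log_sd", "must be positive")
        lognorm_blocks[name] = LognormSpec(math.log(block["median"]), block["log_sd"])

    specs = PopulationSpecs(
        life_span=fit_truncated_normal(ls["mean"], ls["sd"], ls["min"], ls["max"]),
        endogenous_epo=fit_lognormal_from_quantiles(ee["median"], ee["q25"], ee["q75"]),
        **lognorm_blocks,
    )

    m = effective["model"]
    try:
        model = ModelParams(
            stem_influx=m["stem_influx"],
            proliferation_rate=m["proliferation_rate"],
            apoptosis_max=m["apoptosis_max"],
            hill_exponent=m["hill_exponent"],
            cfu_residence=m["cfu_residence"],
            proliferation_window=m["proliferation_window"],
            maturation_delay=m["maturation_delay"],
            epo_cap=m["epo_cap"],
            hct_per_hb=m["hct_per_hb"],
            neocytolysis=NeocytolysisParams(**m["neocytolysis"]),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid config key under 'model': {exc}") from exc
    cal = m["calibration"]
    _require(
        min(cal["life_span"], cal["epo"], cal["hemoglobin"]) > 0,
        "model.calibration",
        "reference values must be positive",
    )

    a = effective["analysis"]
    try:
        analysis = AnalysisConfig(
            hb_lo=a["hb_lo"],
            hb_hi=a["hb_hi"],
            lifespan_bin_width=a["lifespan_bin_width"],
            epo_bin_start=a["epo_bin_start"],
            epo_bin_width=a["epo_bin_width"],
            min_cell_count=a["min_cell_count"],
            clamp_negative_delta=bool(a["clamp_negative_delta"]),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid config key under 'analysis': {exc}") from exc

    seed = effective["seed"]
    _require(isinstance(seed, int) and seed >= 0, "seed", "must be a non-negative integer")
    pop_seed = pop["seed"] if pop["seed"] is not None else seed
    _require(
        isinstance(pop_seed, int) and pop_seed >= 0,
        "population.seed",
        "must be a non-negative integer",
    )

    return RunConfig(
        raw=effective,
        n=pop["n"],
        seed=seed,
        population_seed=pop_seed,
        output_dir=Path(effective["output_dir"]),
        log_level=str(effective["log_level"]),
        specs=specs,
        model=model,
        calibration=dict(cal),
        analysis=analysis,
    )


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Load and validate a run config from a JSON/YAML file.

    ``path=None`` yields the all-defaults configuration; ``overrides`` (a
    partial nested mapping, e.g. from CLI flags) is applied on top of the
    file contents before defaulting and validation.
    """
    given: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        try:
            loaded = yaml.safe_load(text)  # YAML is a superset of JSON
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        given = dict(loaded)
    if overrides:
        given = _deep_overlay(given, overrides)
    effective = _merge(_DEFAULTS, given)
    return _build(effective)


def _deep_overlay(base: Mapping[str, Any], extra: Mapping[str, Any]) -> dict[str, Any]:
    out = {k: copy.deepcopy(v) for k, v in base.items()}
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _deep_overlay(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out
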