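"""End-to-end pipeline: generate -> calibrate -> solve -> bin -> grid.

Runs the full virtual-population requirement analysis from a validated
:class:`~erythrosim.config.RunConfig` and writes the population, per-patient
results, bin-summary and grid CSVs plus the effective config into the output
directory.  Identical config + seed produce byte-identical files; on a stage
failure, files already written for this run are removed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .model import ModelParams, calibrate_kappa
from .population import PopulationTable, sample_population
from .requirement import bin_by_lifespan, lifespan_epo_grid, solve_population

__all__ = ["PipelineError", "calibrated_model", "run_pipeline"]

logger = logging.getLogger("erythrosim")

OUTPUT_FILES = {
    "config": "effective_config.yaml",
    "population": "population.csv",
    "results": "results.csv",
    "bins": "bin_summary.csv",
    "grid": "lifespan_epo_grid.csv",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def calibrated_model(cfg: RunConfig) -> ModelParams:
    """The run's model with kappa fixed to the configured anchor."""
    cal = cfg.calibration
    return calibrate_kappa(
        cfg.model,
        reference_life_span=cal["life_span"],
        reference_epo=cal["epo"],
        reference_hb=cal["hemoglobin"],
    )


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute all stages and write every output CSV; returns written paths.

    All stages compute in memory first; files appear only after every stage
    succeeded, so a failed run leaves no partial output set behind.
    """
    stage = "generate"
    try:
        logger.info("generating population: n=%d seed=%d", cfg.n, cfg.population_seed)
        population: PopulationTable = sample_population(
            cfg.n, cfg.specs, cfg.population_seed
        )

        stage = "calibrate"
        model = calibrated_model(cfg)
        logger.info("calibrated kappa=%.6g", model.kappa)

        stage = "solve"
        results: pd.DataFrame = solve_population(population, model, cfg.analysis)
        n_conv = int(results["converged"].sum())
        logger.info("solved %d patients (%d converged)", len(results), n_conv)

        stage = "bin"
        bins = bin_by_lifespan(results, cfg.analysis)

        stage = "grid"
        grid = lifespan_epo_grid(results, cfg.analysis)
    except Exception as exc:
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc

    stage = "write"
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in OUTPUT_FILES.items()}
    written: list[Path] = []
    try:
        cfg.echo(out)
        written.append(paths["config"])
        population.to_csv(paths["population"])
        written.append(paths["population"])
        results.to_csv(paths["results"], index=False)
        written.append(paths["results"])
        bins.to_csv(paths["bins"], index=False)
        written.append(paths["bins"])
        grid.to_csv(paths["grid"], index=False)
        written.append(paths["grid"])
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage 'write' failed: {exc}") from exc
    logger.info("wrote %d files to %s", len(paths), out)
    return paths
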