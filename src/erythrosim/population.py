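"""Virtual hemodialysis-patient populations.

Generates cohorts of "virtual patients": per-patient erythropoiesis parameter
sets whose marginal distributions emulate those estimated for a large US
hemodialysis cohort. The two distributions with published summary statistics
are the circulating red-blood-cell (RBC) life span — mean 76 d, SD 21 d,
hard range 33–137 d, modeled as a truncated normal whose *post-truncation*
moments are calibrated to hit the reported mean/SD — and the endogenous
erythropoietin (Epo) concentration — median 15 U/L with quartiles
10.2/21.1 U/L, modeled as a lognormal fitted to those quantiles.

The remaining patient parameters (ESA half-life, Epo half-effect
concentration for apoptosis suppression, maturation-velocity factor) have no
published distributions; configurable lognormal defaults provide realistic
inter-patient heterogeneity.  All parameters are sampled independently, each
from its own seed substream, so adding a parameter never perturbs the draws
of another.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import truncnorm

__all__ = [
    "CalibrationError",
    "TruncNormSpec",
    "LognormSpec",
    "PatientParams",
    "PopulationSpecs",
    "PopulationTable",
    "fit_truncated_normal",
    "fit_lognormal_from_quantiles",
    "default_specs",
    "sample_population",
]

#: standard-normal 75th percentile, used in the quartile fit
Z75 = 0.6744897501960817

POPULATION_CSV_COLUMNS = [
    "patient_id",
    "rbc_life_span_days",
    "endogenous_epo_u_per_l",
    "esa_half_life_h",
    "apoptosis_sensitivity_u_per_l",
    "maturation_factor",
]


class CalibrationError(RuntimeError):
    """Raised when a generator spec cannot be calibrated to its targets."""


@dataclass(frozen=True)
class TruncNormSpec:
    """Normal distribution truncated to [lower, upper].

    ``location``/``scale`` are the parameters of the *parent* normal, not the
    post-truncation mean/SD; use :func:`fit_truncated_normal` to obtain a spec
    whose truncated moments match stated targets.
    """

    location: float
    scale: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("TruncNormSpec requires lower < upper")
        if not self.scale > 0:
            raise ValueError("TruncNormSpec requires scale > 0")

    @property
    def _ab(self) -> tuple[float, float]:
        a = (self.lower - self.location) / self.scale
        b = (self.upper - self.location) / self.scale
        return a, b

    def mean(self) -> float:
        a, b = self._ab
        return float(truncnorm.mean(a, b, loc=self.location, scale=self.scale))

    def std(self) -> float:
        a, b = self._ab
        return float(truncnorm.std(a, b, loc=self.location, scale=self.scale))

    def ppf(self, q: np.ndarray) -> np.ndarray:
        a, b = self._ab
        x = truncnorm.ppf(q, a, b, loc=self.location, scale=self.scale)
        # inverse-CDF sampling can graze the bounds in floating point
        return np.clip(x, self.lower, self.upper)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.random(n))


@dataclass(frozen=True)
class LognormSpec:
    """Lognormal parameterized by the log of its median and the log-scale SD."""

    log_median: float
    log_sd: float

    def __post_init__(self) -> None:
        if not self.log_sd > 0:
            raise ValueError("LognormSpec requires log_sd > 0")

    @property
    def median(self) -> float:
        return math.exp(self.log_median)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.normal(self.log_median, self.log_sd, size=n))


@dataclass(frozen=True)
class PatientParams:
    """One virtual patient's erythropoiesis-related parameter set."""

    patient_id: int
    rbc_life_span: float  # days
    endogenous_epo: float  # U/L
    esa_half_life: float  # hours
    apoptosis_sensitivity: float  # U/L; half-effect Epo for apoptosis suppression
    maturation_factor: float  # dimensionless; ESA effect on maturation velocity

    def __post_init__(self) -> None:
        if not self.endogenous_epo > 0:
            raise ValueError("endogenous_epo must be positive")
        if not self.esa_half_life > 0:
            raise ValueError("esa_half_life must be positive")
        if not self.rbc_life_span >= 0:
            raise ValueError("rbc_life_span must be non-negative")
        if self.maturation_factor < 0:
            raise ValueError("maturation_factor must be >= 0")


@dataclass(frozen=True)
class PopulationSpecs:
    """Generator specs for every sampled patient parameter.

    Field order fixes the seed-substream assignment; append new fields at the
    end so existing fields' draws are unchanged under the same root seed.
    """

    life_span: TruncNormSpec
    endogenous_epo: LognormSpec
    esa_half_life: LognormSpec = field(
        default_factory=lambda: LognormSpec(math.log(20.0), 0.3)
    )
    apoptosis_sensitivity: LognormSpec = field(
        default_factory=lambda: LognormSpec(math.log(30.0), 0.4)
    )
    maturation_factor: LognormSpec = field(
        default_factory=lambda: LognormSpec(math.log(0.5), 0.4)
    )


@dataclass(frozen=True)
class PopulationTable:
    """An ordered virtual-patient cohort plus the recipe that produced it."""

    frame: pd.DataFrame
    seed: int
    specs: PopulationSpecs

    def __len__(self) -> int:
        return len(self.frame)

    def patients(self) -> list[PatientParams]:
        return [
            PatientParams(
                patient_id=int(r.patient_id),
                rbc_life_span=float(r.rbc_life_span_days),
                endogenous_epo=float(r.endogenous_epo_u_per_l),
                esa_half_life=float(r.esa_half_life_h),
                apoptosis_sensitivity=float(r.apoptosis_sensitivity_u_per_l),
                maturation_factor=float(r.maturation_factor),
            )
            for r in self.frame.itertuples(index=False)
        ]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def fit_truncated_normal(
    target_mean: float,
    target_sd: float,
    lower: float,
    upper: float,
    rel_tol: float = 1e-6,
) -> TruncNormSpec:
    """Calibrate a truncated normal so its *post-truncation* mean and SD hit
    the targets.

    Naively truncating N(target_mean, target_sd) to an asymmetric range
    shifts the realized moments (for the RBC life-span range [33, 137] the
    naive truncated mean lands above 76 d), so the parent location/scale are
    solved numerically with a 2-D root find.

    Raises
    ------
    CalibrationError
        If the solver does not reach ``rel_tol`` relative accuracy.
    """
    if not lower < target_mean < upper:
        raise ValueError("require lower < target_mean < upper")
    if not target_sd > 0:
        raise ValueError("target_sd must be positive")

    def residual(x: np.ndarray) -> list[float]:
        loc, log_scale = x
        spec = TruncNormSpec(loc, math.exp(log_scale), lower, upper)
        return [
            (spec.mean() - target_mean) / target_sd,
            (spec.std() - target_sd) / target_sd,
        ]

    sol = optimize.root(
        residual, x0=[target_mean, math.log(target_sd)], method="hybr", tol=1e-13
    )
    spec = TruncNormSpec(float(sol.x[0]), math.exp(float(sol.x[1])), lower, upper)
    scale_ref = max(abs(target_mean), target_sd)
    ok = (
        abs(spec.mean() - target_mean) <= rel_tol * scale_ref
        and abs(spec.std() - target_sd) <= rel_tol * target_sd
    )
    if not ok:
        raise CalibrationError(
            f"truncated-normal calibration failed for mean={target_mean}, "
            f"sd={target_sd} on [{lower}, {upper}]: {sol.message}"
        )
    return spec


def fit_lognormal_from_quantiles(median: float, q25: float, q75: float) -> LognormSpec:
    """Fit a lognormal from a median and quartiles.

    The log-median is matched exactly.  The two quartile equations
    ``log_sd * z_0.75 = ln(median/q25)`` and ``log_sd * z_0.75 =
    ln(q75/median)`` are generally inconsistent for real (right-skewed but
    not exactly lognormal) data, so ``log_sd`` is the least-squares solution:
    the average of the two implied values.
    """
    if not 0 < q25 < median < q75:
        raise ValueError("require 0 < q25 < median < q75")
    log_sd = (math.log(median / q25) + math.log(q75 / median)) / (2.0 * Z75)
    return LognormSpec(log_median=math.log(median), log_sd=log_sd)


def default_specs(
    life_span_mean: float = 76.0,
    life_span_sd: float = 21.0,
    life_span_min: float = 33.0,
    life_span_max: float = 137.0,
    epo_median: float = 15.0,
    epo_q25: float = 10.2,
    epo_q75: float = 21.1,
    **overrides: LognormSpec,
) -> PopulationSpecs:
    """Build the default cohort specs (hemodialysis-population statistics)."""
    return PopulationSpecs(
        life_span=fit_truncated_normal(
            life_span_mean, life_span_sd, life_span_min, life_span_max
        ),
        endogenous_epo=fit_lognormal_from_quantiles(epo_median, epo_q25, epo_q75),
        **overrides,
    )


def sample_population(
    n: int, specs: PopulationSpecs | None = None, seed: int = 0
) -> PopulationTable:
    """Draw ``n`` independent virtual patients.

    Life spans are drawn by inverse CDF of the truncated normal, so no value
    can ever fall outside the configured range.  Each parameter uses its own
    substream spawned from the root seed; identical ``(n, specs, seed)``
    reproduce the table bit-for-bit.
    """
    if n < 1:
        raise ValueError("population size n must be >= 1")
    if specs is None:
        specs = default_specs()

    spec_fields = [f.name for f in dataclasses.fields(PopulationSpecs)]
    streams = np.random.SeedSequence(seed).spawn(len(spec_fields))
    draws = {
        name: getattr(specs, name).sample(n, np.random.default_rng(stream))
        for name, stream in zip(spec_fields, streams)
    }

    frame = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1, dtype=np.int64),
            "rbc_life_span_days": draws["life_span"],
            "endogenous_epo_u_per_l": draws["endogenous_epo"],
            "esa_half_life_h": draws["esa_half_life"],
            "apoptosis_sensitivity_u_per_l": draws["apoptosis_sensitivity"],
            "maturation_factor": draws["maturation_factor"],
        }
    )
    return PopulationTable(frame=frame, seed=seed, specs=specs)
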