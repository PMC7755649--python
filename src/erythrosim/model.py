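"""Mechanistic erythropoiesis model with Epo-regulated progenitor survival.

The model is a minimal representation of the erythroid proliferative
hierarchy: a constant stem-cell influx S0 feeds a proliferating progenitor
compartment (exponential amplification over a fixed window tau_p), followed
by the Epo-sensitive CFU-E stage where apoptosis at rate alpha(E) prunes the
cohort over its residence time tau_CFU.  Erythropoietin suppresses CFU-E
apoptosis through a decreasing Hill function, so the circulation-entry flux

    P(E) = S0 * exp(beta * tau_p - alpha(E) * tau_CFU),
    alpha(E) = alpha_max * theta^h / (theta^h + E^h),

is strictly increasing in total Epo E.  Circulating cells survive to the
patient-specific life span L and are then removed abruptly, which makes the
steady state closed-form: RBC count = P(E) * L and hemoglobin
Hb = kappa * P(E) * L, with kappa the flux-to-hemoglobin conversion fixed by
calibration to a reference anchor (healthy physiology: Hb 14 g/dl at
L = 120 d and E = 15 U/L).  Hematocrit is reported via the fixed rule-of-three
conversion hct = 3 * Hb.

A dynamic simulator does the same bookkeeping on an age grid: cohorts enter
after an Epo-dependent maturation delay, age step by step, and are removed at
age L, with optional neocytolysis (extra removal of young cells at low Epo).
ESA pharmacokinetics are one-compartment: superposed exponential decays with
the patient's half-life.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .population import PatientParams

__all__ = [
    "EpoCapError",
    "UncalibratedModelError",
    "NeocytolysisParams",
    "ModelParams",
    "SteadyState",
    "EsaSchedule",
    "Trajectory",
    "apoptosis_rate",
    "production_flux",
    "steady_state",
    "calibrate_kappa",
    "esa_concentration",
    "total_epo_function",
    "simulate",
]

LN2 = float(np.log(2.0))


class EpoCapError(ValueError):
    """Total Epo exceeds the model's concentration cap."""


class UncalibratedModelError(RuntimeError):
    """Hemoglobin requested before the kappa conversion was calibrated."""


@dataclass(frozen=True)
class NeocytolysisParams:
    """Selective removal of young circulating RBCs when Epo is low.

    When enabled, cohorts younger than ``age_cutoff`` decay at the extra rate
    ``extra_rate`` whenever total Epo falls below ``epo_threshold``.  Disabled
    by default; the requirement analysis holds Epo constant at need, where
    neocytolysis would not engage.
    """

    enabled: bool = False
    age_cutoff: float = 10.0  # days
    epo_threshold: float = 10.0  # U/L
    extra_rate: float = 0.05  # 1/day

    def __post_init__(self) -> None:
        if self.age_cutoff < 0 or self.epo_threshold < 0 or self.extra_rate < 0:
            raise ValueError("neocytolysis parameters must be non-negative")


@dataclass(frozen=True)
class ModelParams:
    """Constants of the mechanistic model (patient-independent)."""

    stem_influx: float = 1.0  # cells/day, arbitrary scale (S0)
    proliferation_rate: float = 0.7  # 1/day (beta)
    apoptosis_max: float = 0.35  # 1/day (alpha_max)
    hill_exponent: float = 2.0  # dimensionless (h)
    cfu_residence: float = 6.0  # days (tau_CFU)
    proliferation_window: float = 5.0  # days (tau_p)
    maturation_delay: float = 3.0  # days (tau_d0), zero-Epo-effect delay
    hb_per_flux: float | None = None  # g/dl per (cells/day * day); None = uncalibrated
    epo_cap: float = 10_000.0  # U/L
    hct_per_hb: float = 3.0  # % per (g/dl), rule-of-three approximation
    neocytolysis: NeocytolysisParams = field(default_factory=NeocytolysisParams)

    def __post_init__(self) -> None:
        for name in (
            "stem_influx",
            "proliferation_rate",
            "apoptosis_max",
            "cfu_residence",
            "proliferation_window",
            "maturation_delay",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hill_exponent < 1:
            raise ValueError("hill_exponent must be >= 1")
        if not self.epo_cap > 0:
            raise ValueError("epo_cap must be positive")
        if self.hb_per_flux is not None and not self.hb_per_flux > 0:
            raise ValueError("hb_per_flux must be positive once set")

    @property
    def kappa(self) -> float:
        if self.hb_per_flux is None:
            raise UncalibratedModelError(
                "model is uncalibrated: run calibrate_kappa() first"
            )
        return self.hb_per_flux


@dataclass(frozen=True)
class SteadyState:
    """Equilibrium of the model at a constant total Epo concentration."""

    epo_total: float  # U/L
    production_flux: float  # cells/day
    rbc_count: float  # cells, arbitrary scale
    hemoglobin: float  # g/dl
    hematocrit: float  # %


@dataclass(frozen=True)
class EsaSchedule:
    """ESA administrations as serum-concentration increments.

    Each dose adds ``concentration_increment`` U/L at its time and decays as
    a one-compartment exponential with the given half-life.
    """

    times: tuple[float, ...]  # days
    increments: tuple[float, ...]  # U/L
    half_life: float  # hours

    def __post_init__(self) -> None:
        if len(self.times) != len(self.increments):
            raise ValueError("times and increments must have equal length")
        if any(b < a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("dose times must be non-decreasing")
        if any(d < 0 for d in self.increments):
            raise ValueError("dose increments must be non-negative")
        if not self.half_life > 0:
            raise ValueError("half_life must be positive")

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[float, float]], half_life: float
    ) -> "EsaSchedule":
        times = tuple(float(t) for t, _ in pairs)
        increments = tuple(float(d) for _, d in pairs)
        return cls(times=times, increments=increments, half_life=half_life)


@dataclass(frozen=True)
class Trajectory:
    """Time courses from the dynamic simulator (equal-length arrays).

    ``total_cells``, ``entered`` and ``removed`` expose the raw cohort
    bookkeeping (cells in circulation, cells entering during the step ending
    at each time, cells removed by ageing or neocytolysis) so that cell
    conservation can be audited externally.
    """

    time: np.ndarray  # days
    hemoglobin: np.ndarray  # g/dl
    flux: np.ndarray  # cells/day entering circulation
    epo: np.ndarray  # U/L total Epo
    total_cells: np.ndarray  # cells (raw, unweighted)
    entered: np.ndarray  # cells entering in the step ending here (0 at t=0)
    removed: np.ndarray  # cells removed in the step ending here (0 at t=0)

    def __post_init__(self) -> None:
        n = len(self.time)
        arrays = (
            self.hemoglobin,
            self.flux,
            self.epo,
            self.total_cells,
            self.entered,
            self.removed,
        )
        if any(len(a) != n for a in arrays):
            raise ValueError("trajectory arrays must have equal length")


def apoptosis_rate(
    E_total: float | np.ndarray, patient: PatientParams, model: ModelParams
) -> float | np.ndarray:
    """CFU-E apoptosis rate alpha(E): decreasing Hill function of total Epo.

    alpha(0) = alpha_max, alpha(theta) = alpha_max / 2 at the patient's
    half-effect concentration theta, and alpha -> 0 as E -> infinity.
    """
    E = np.asarray(E_total, dtype=float)
    if np.any(E < 0):
        raise ValueError("total Epo must be non-negative")
    theta = patient.apoptosis_sensitivity
    h = model.hill_exponent
    out = model.apoptosis_max * theta**h / (theta**h + E**h)
    return float(out) if np.isscalar(E_total) else out


def production_flux(
    E_total: float | np.ndarray, patient: PatientParams, model: ModelParams
) -> float | np.ndarray:
    """Circulation-entry flux P(E) = S0 * exp(beta*tau_p - alpha(E)*tau_CFU)."""
    alpha = apoptosis_rate(E_total, patient, model)
    out = model.stem_influx * np.exp(
        model.proliferation_rate * model.proliferation_window
        - np.asarray(alpha) * model.cfu_residence
    )
    return float(out) if np.isscalar(E_total) else out


def steady_state(
    E_total: float, patient: PatientParams, model: ModelParams
) -> SteadyState:
    """Closed-form equilibrium under constant total Epo.

    With abrupt removal at age L the standing RBC count is flux times life
    span; neocytolysis is never active here (constant Epo at or above need).
    """
    if E_total < 0:
        raise ValueError("total Epo must be non-negative")
    if E_total > model.epo_cap:
        raise EpoCapError(
            f"E_total={E_total} exceeds the model cap {model.epo_cap} U/L"
        )
    P = production_flux(E_total, patient, model)
    L = patient.rbc_life_span
    rbc = P * L
    hb = model.kappa * rbc
    return SteadyState(
        epo_total=float(E_total),
        production_flux=float(P),
        rbc_count=float(rbc),
        hemoglobin=float(hb),
        hematocrit=float(model.hct_per_hb * hb),
    )


def calibrate_kappa(
    model: ModelParams,
    reference_life_span: float = 120.0,
    reference_epo: float = 15.0,
    reference_hb: float = 14.0,
    reference_sensitivity: float = 30.0,
) -> ModelParams:
    """Fix the flux-to-hemoglobin conversion kappa against a reference anchor.

    The anchor is a healthy-physiology patient (life span 120 d) who is
    normo-hemic (14 g/dl) at the cohort's median Epo (15 U/L).  Because S0 and
    kappa enter only through their product, rescaling S0 and recalibrating
    leaves every hemoglobin output unchanged.
    """
    if min(reference_life_span, reference_epo, reference_hb) <= 0:
        raise ValueError("reference values must be positive")
    ref_patient = PatientParams(
        patient_id=0,
        rbc_life_span=reference_life_span,
        endogenous_epo=reference_epo,
        esa_half_life=20.0,
        apoptosis_sensitivity=reference_sensitivity,
        maturation_factor=0.0,
    )
    P = production_flux(reference_epo, ref_patient, model)
    rbc = P * reference_life_span
    if rbc <= 0:
        raise ValueError("zero production flux at the calibration reference")
    return dataclasses.replace(model, hb_per_flux=reference_hb / rbc)


def esa_concentration(
    schedule: EsaSchedule, t: float | np.ndarray
) -> float | np.ndarray:
    """Serum ESA concentration at time t: superposed one-compartment decays."""
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt < 0):
        raise ValueError("time must be non-negative")
    rate = LN2 * 24.0 / schedule.half_life  # 1/day
    out = np.zeros_like(tt)
    for ti, di in zip(schedule.times, schedule.increments):
        mask = tt >= ti
        out[mask] += di * np.exp(-rate * (tt[mask] - ti))
    return float(out[0]) if np.isscalar(t) else out


def total_epo_function(
    patient: PatientParams, schedule: EsaSchedule | None = None
) -> Callable[[float], float]:
    """Total Epo E(t) = endogenous + ESA concentration (if any)."""
    if schedule is None:
        return lambda t: patient.endogenous_epo
    return lambda t: patient.endogenous_epo + esa_concentration(schedule, t)


def _maturation_delay(E: float, patient: PatientParams, model: ModelParams) -> float:
    """Epo shortens the marrow transit delay: tau_d0 / (1 + mf * E/(E+theta))."""
    theta = patient.apoptosis_sensitivity
    return model.maturation_delay / (
        1.0 + patient.maturation_factor * E / (E + theta)
    )


def simulate(
    patient: PatientParams,
    model: ModelParams,
    epo_of_t: Callable[[float], float],
    t_end: float,
    dt: float,
    start: str = "empty",
) -> Trajectory:
    """Age-structured simulation of the circulating RBC pool.

    Each step a cohort of size P(E(t - tau_d)) * dt enters circulation, where
    the maturation delay tau_d shrinks with current Epo; cohorts age on a
    uniform grid and are removed abruptly at the patient's life span L.  The
    hemoglobin readout weights the oldest (partial) age bin by its overlap
    with [0, L), so at constant Epo the standing total equals P*L exactly and
    the trajectory converges to the analytic steady state.

    Parameters
    ----------
    start:
        ``"empty"`` begins with no circulating cells (burn-in of ~5 L before
        steady readings); ``"steady"`` initializes at the steady state for
        E(0).
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    L = patient.rbc_life_span
    n_steps = int(round(t_end / dt))
    n_bins = max(int(np.ceil(L / dt)), 1)
    # overlap of age bin [j*dt, (j+1)*dt) with [0, L), as a fraction of dt
    ages = np.arange(n_bins) * dt
    weights = np.clip((L - ages) / dt, 0.0, 1.0)
    neo = model.neocytolysis
    neo_mask = ages < neo.age_cutoff if neo.enabled else None

    cohorts = np.zeros(n_bins)
    if start == "steady":
        cohorts[:] = production_flux(float(epo_of_t(0.0)), patient, model) * dt
    elif start != "empty":
        raise ValueError("start must be 'empty' or 'steady'")

    kappa = model.kappa
    times = np.arange(n_steps + 1) * dt
    hb = np.empty(n_steps + 1)
    flux = np.empty(n_steps + 1)
    epo = np.empty(n_steps + 1)
    total = np.empty(n_steps + 1)
    entered = np.zeros(n_steps + 1)
    removed = np.zeros(n_steps + 1)

    e0 = float(epo_of_t(0.0))
    epo[0] = e0
    flux[0] = production_flux(e0, patient, model)
    hb[0] = kappa * float(cohorts @ weights)
    total[0] = float(cohorts.sum())

    for k in range(n_steps):
        t = k * dt
        E_now = float(epo_of_t(t))
        tau = _maturation_delay(E_now, patient, model)
        P_in = production_flux(float(epo_of_t(max(t - tau, 0.0))), patient, model)
        lysed = 0.0
        if neo_mask is not None and E_now < neo.epo_threshold:
            young = cohorts[neo_mask]
            lysed = float(young.sum()) * (1.0 - np.exp(-neo.extra_rate * dt))
            cohorts[neo_mask] = young * np.exp(-neo.extra_rate * dt)
        # age by one bin; the oldest bin exits circulation
        aged_out = float(cohorts[-1])
        cohorts[1:] = cohorts[:-1]
        cohorts[0] = P_in * dt
        hb[k + 1] = kappa * float(cohorts @ weights)
        flux[k + 1] = P_in
        epo[k + 1] = float(epo_of_t(t + dt))
        total[k + 1] = float(cohorts.sum())
        entered[k + 1] = P_in * dt
        removed[k + 1] = aged_out + lysed

    return Trajectory(
        time=times,
        hemoglobin=hb,
        flux=flux,
        epo=epo,
        total_cells=total,
        entered=entered,
        removed=removed,
    )
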