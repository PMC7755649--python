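"""Per-patient required-Epo analysis and population summaries.

For each virtual patient, finds the constant total serum Epo concentration
E* at which the steady-state hemoglobin sits in the target window
10.49–10.51 g/dl (bracketing + Brent root find on the closed-form steady
state), reports the increase over the patient's endogenous Epo, and
summarizes the population as (i) box-plot statistics of required Epo per
10-day RBC-life-span bin and (ii) the mean required increase on a 2-D
(life-span x endogenous-Epo) grid, keeping only cells with at least 25
patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model import ModelParams, steady_state
from .population import PatientParams, PopulationTable

__all__ = [
    "AnalysisConfig",
    "RequiredEpo",
    "BoxplotStats",
    "required_total_epo",
    "solve_population",
    "boxplot_stats",
    "bin_by_lifespan",
    "lifespan_epo_grid",
]

RESULTS_CSV_COLUMNS = [
    "patient_id",
    "rbc_life_span_days",
    "endogenous_epo_u_per_l",
    "required_total_epo_u_per_l",
    "delta_raw_u_per_l",
    "delta_clamped_u_per_l",
    "achieved_hb_g_dl",
    "converged",
    "iterations",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Targets and binning rules for the requirement analysis.

    The hemoglobin target is the window [hb_lo, hb_hi]; the solver aims for
    its midpoint and declares convergence on window membership.  Life-span
    bins are half-open 10-day bins aligned to multiples of the width;
    endogenous-Epo bins start at 5 U/L with width 10 (5–15, 15–25, ...).
    """

    hb_lo: float = 10.49  # g/dl
    hb_hi: float = 10.51  # g/dl
    lifespan_bin_width: float = 10.0  # days
    epo_bin_start: float = 5.0  # U/L
    epo_bin_width: float = 10.0  # U/L
    min_cell_count: int = 25
    clamp_negative_delta: bool = True

    def __post_init__(self) -> None:
        if not self.hb_lo < self.hb_hi:
            raise ValueError("require hb_lo < hb_hi")
        if self.lifespan_bin_width <= 0 or self.epo_bin_width <= 0:
            raise ValueError("bin widths must be positive")
        if self.min_cell_count < 1:
            raise ValueError("min_cell_count must be >= 1")

    @property
    def hb_target(self) -> float:
        return 0.5 * (self.hb_lo + self.hb_hi)


@dataclass(frozen=True)
class RequiredEpo:
    """Result of the per-patient required-Epo solve."""

    patient_id: int
    required_total_epo: float  # U/L
    delta_raw: float  # U/L, required - endogenous (may be negative)
    delta_clamped: float  # U/L, max(0, delta_raw)
    achieved_hb: float  # g/dl
    converged: bool
    iterations: int


class BoxplotStats(NamedTuple):
    """Tukey box-plot summary with the 1.5*IQR outlier rule."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    n_outliers: int


def required_total_epo(
    patient: PatientParams, model: ModelParams, cfg: AnalysisConfig | None = None
) -> RequiredEpo:
    """Constant total Epo at which the patient's steady-state Hb hits target.

    Steady-state hemoglobin is strictly increasing in Epo, so the root is
    bracketed by doubling the upper endpoint from 1 U/L until the target is
    straddled (or the model's Epo cap is reached) and then polished with
    Brent's method.  A patient whose hemoglobin stays below the window even
    at the cap is a non-achiever: ``converged=False`` with the cap reported
    as the requirement.  The converse corner (hemoglobin above the window
    already at zero Epo) likewise returns ``converged=False`` with a zero
    requirement.
    """
    if cfg is None:
        cfg = AnalysisConfig()
    target = cfg.hb_target

    def hb(E: float) -> float:
        value = steady_state(E, patient, model).hemoglobin
        if not math.isfinite(value):
            raise ArithmeticError(
                f"non-finite hemoglobin at E={E} for patient {patient.patient_id}"
            )
        return value

    def _result(E: float, iterations: int) -> RequiredEpo:
        achieved = hb(E)
        return RequiredEpo(
            patient_id=patient.patient_id,
            required_total_epo=float(E),
            delta_raw=float(E - patient.endogenous_epo),
            delta_clamped=float(max(0.0, E - patient.endogenous_epo)),
            achieved_hb=achieved,
            converged=bool(cfg.hb_lo <= achieved <= cfg.hb_hi),
            iterations=iterations,
        )

    if hb(0.0) >= target:
        return _result(0.0, 0)

    hi = 1.0
    n_doublings = 0
    while hb(hi) < target and hi < model.epo_cap:
        hi = min(2.0 * hi, model.epo_cap)
        n_doublings += 1
    if hb(hi) < target:  # hi == epo_cap: target unreachable
        return _result(model.epo_cap, n_doublings)

    root, info = optimize.brentq(
        lambda E: hb(E) - target, 0.0, hi, xtol=1e-9, full_output=True
    )
    return _result(float(root), n_doublings + info.iterations)


def solve_population(
    population: PopulationTable | Sequence[PatientParams],
    model: ModelParams,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Run the required-Epo solve for every patient; one row per patient."""
    patients = (
        population.patients()
        if isinstance(population, PopulationTable)
        else list(population)
    )
    if not patients:
        raise ValueError("population is empty")
    rows = []
    for p in patients:
        r = required_total_epo(p, model, cfg)
        rows.append(
            (
                p.patient_id,
                p.rbc_life_span,
                p.endogenous_epo,
                r.required_total_epo,
                r.delta_raw,
                r.delta_clamped,
                r.achieved_hb,
                r.converged,
                r.iterations,
            )
        )
    return pd.DataFrame(rows, columns=RESULTS_CSV_COLUMNS)


def boxplot_stats(values: Sequence[float] | np.ndarray) -> BoxplotStats:
    """Median, quartiles, whiskers and outlier count of a sample.

    Quartiles use linear interpolation of order statistics; whiskers span the
    most extreme values within 1.5*IQR of the box, and values beyond are
    counted as outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("boxplot_stats requires a non-empty input")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        n_outliers=int(x.size - inside.size),
    )


def _lifespan_bin_lo(life_span: np.ndarray, width: float) -> np.ndarray:
    return np.floor(life_span / width) * width


def bin_by_lifespan(
    results: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    value_column: str = "required_total_epo_u_per_l",
) -> pd.DataFrame:
    """Box-plot statistics of required Epo per half-open life-span bin.

    Bins are [lo, lo + width) aligned to multiples of the width; only
    converged patients enter, empty bins produce no row, and the bin
    population count is reported alongside the statistics.
    """
    if cfg is None:
        cfg = AnalysisConfig()
    if results.empty:
        raise ValueError("results table is empty")
    conv = results[results["converged"].astype(bool)]
    out = []
    bins = _lifespan_bin_lo(
        conv["rbc_life_span_days"].to_numpy(), cfg.lifespan_bin_width
    )
    for lo in np.unique(bins):
        vals = conv.loc[bins == lo, value_column].to_numpy()
        s = boxplot_stats(vals)
        out.append(
            (
                lo,
                lo + cfg.lifespan_bin_width,
                len(vals),
                s.median,
                s.q1,
                s.q3,
                s.whisker_lo,
                s.whisker_hi,
                s.n_outliers,
            )
        )
    return pd.DataFrame(
        out,
        columns=[
            "bin_lo_days",
            "bin_hi_days",
            "n",
            "median",
            "q1",
            "q3",
            "whisker_lo",
            "whisker_hi",
            "n_outliers",
        ],
    )


def lifespan_epo_grid(
    results: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Mean required Epo increase on the (life span x endogenous Epo) grid.

    2-D half-open binning: 10-day life-span bins crossed with endogenous-Epo
    bins of width 10 U/L starting at 5 U/L.  The reported mean uses the
    clamped delta when ``cfg.clamp_negative_delta`` (raw otherwise); cells
    are flagged ``included`` only when populated by at least
    ``cfg.min_cell_count`` converged patients.  Patients with endogenous Epo
    below the first bin edge fall outside the grid.
    """
    if cfg is None:
        cfg = AnalysisConfig()
    if results.empty:
        return pd.DataFrame(
            columns=[
                "ls_bin_lo",
                "ls_bin_hi",
                "epo_bin_lo",
                "epo_bin_hi",
                "n",
                "mean_delta",
                "included",
            ]
        )
    conv = results[results["converged"].astype(bool)]
    delta_col = "delta_clamped_u_per_l" if cfg.clamp_negative_delta else "delta_raw_u_per_l"
    ls_lo = _lifespan_bin_lo(
        conv["rbc_life_span_days"].to_numpy(), cfg.lifespan_bin_width
    )
    epo = conv["endogenous_epo_u_per_l"].to_numpy()
    in_grid = epo >= cfg.epo_bin_start
    epo_lo = np.full_like(epo, np.nan)
    epo_lo[in_grid] = (
        np.floor((epo[in_grid] - cfg.epo_bin_start) / cfg.epo_bin_width)
        * cfg.epo_bin_width
        + cfg.epo_bin_start
    )
    delta = conv[delta_col].to_numpy()

    rows = []
    pairs = {
        (l, e)
        for l, e, ok in zip(ls_lo, epo_lo, in_grid)
        if ok
    }
    for l, e in sorted(pairs):
        mask = (ls_lo == l) & (epo_lo == e)
        n = int(mask.sum())
        rows.append(
            (
                l,
                l + cfg.lifespan_bin_width,
                e,
                e + cfg.epo_bin_width,
                n,
                float(delta[mask].mean()),
                n >= cfg.min_cell_count,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ls_bin_lo",
            "ls_bin_hi",
            "epo_bin_lo",
            "epo_bin_hi",
            "n",
            "mean_delta",
            "included",
        ],
    )
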