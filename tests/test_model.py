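"""Mechanistic model: Hill regulation, steady state, PK, dynamic simulator."""

import dataclasses
import math

import numpy as np
import pytest

from erythrosim.model import (
    EpoCapError,
    EsaSchedule,
    ModelParams,
    NeocytolysisParams,
    UncalibratedModelError,
    apoptosis_rate,
    calibrate_kappa,
    esa_concentration,
    production_flux,
    simulate,
    steady_state,
)

from conftest import make_patient, random_patients


class TestApoptosisRate:
    def test_zero_epo_gives_maximal_apoptosis(self, model):
        p = make_patient()
        assert apoptosis_rate(0.0, p, model) == pytest.approx(model.apoptosis_max)

    def test_half_effect_at_sensitivity(self, model):
        p = make_patient(apoptosis_sensitivity=42.0)
        assert apoptosis_rate(42.0, p, model) == pytest.approx(model.apoptosis_max / 2)

    def test_strictly_decreasing_in_epo(self, model):
        p = make_patient()
        grid = np.linspace(0.0, model.epo_cap, 100)
        alpha = apoptosis_rate(grid, p, model)
        assert np.all(np.diff(alpha) < 0)

    def test_negative_epo_rejected(self, model):
        with pytest.raises(ValueError):
            apoptosis_rate(-1.0, make_patient(), model)


class TestProductionFlux:
    def test_no_regulation_when_apoptosis_absent(self):
        m = ModelParams(apoptosis_max=0.0)
        p = make_patient()
        expected = m.stem_influx * math.exp(m.proliferation_rate * m.proliferation_window)
        for E in (0.0, 15.0, 500.0):
            assert production_flux(E, p, m) == pytest.approx(expected)

    def test_high_epo_limit_suppresses_apoptosis(self, model):
        p = make_patient()
        limit = model.stem_influx * math.exp(
            model.proliferation_rate * model.proliferation_window
        )
        assert production_flux(1e9, p, model) == pytest.approx(limit, rel=1e-6)
        assert production_flux(15.0, p, model) < limit

    def test_strictly_increasing_in_epo(self, model):
        p = make_patient()
        grid = np.linspace(0.0, model.epo_cap, 200)
        assert np.all(np.diff(production_flux(grid, p, model)) > 0)


class TestSteadyState:
    def test_zero_life_span_means_zero_hemoglobin(self, model):
        ss = steady_state(15.0, make_patient(rbc_life_span=0.0), model)
        assert ss.hemoglobin == 0.0
        assert ss.rbc_count == 0.0

    def test_hemoglobin_linear_in_life_span(self, model):
        hb1 = steady_state(15.0, make_patient(rbc_life_span=60.0), model).hemoglobin
        hb2 = steady_state(15.0, make_patient(rbc_life_span=120.0), model).hemoglobin
        assert hb2 == pytest.approx(2 * hb1, rel=1e-12)

    def test_hematocrit_tracks_hemoglobin(self, model):
        ss = steady_state(20.0, make_patient(), model)
        assert ss.hematocrit == pytest.approx(model.hct_per_hb * ss.hemoglobin)

    def test_monotone_in_epo_and_life_span(self, model):
        hbs = [
            steady_state(E, make_patient(), model).hemoglobin
            for E in np.linspace(0, 200, 50)
        ]
        assert np.all(np.diff(hbs) > 0)
        hbs_L = [
            steady_state(15.0, make_patient(rbc_life_span=L), model).hemoglobin
            for L in np.linspace(33, 137, 50)
        ]
        assert np.all(np.diff(hbs_L) > 0)

    def test_cap_exceeded_raises(self, model):
        with pytest.raises(EpoCapError):
            steady_state(model.epo_cap + 1.0, make_patient(), model)

    def test_uncalibrated_model_raises(self):
        with pytest.raises(UncalibratedModelError):
            steady_state(15.0, make_patient(), ModelParams())


class TestCalibration:
    def test_anchor_reproduced_to_machine_precision(self, model):
        ref = make_patient(rbc_life_span=120.0, apoptosis_sensitivity=30.0)
        assert steady_state(15.0, ref, model).hemoglobin == pytest.approx(14.0, abs=1e-12)

    def test_kappa_formula(self, model):
        ref = make_patient(rbc_life_span=120.0, apoptosis_sensitivity=30.0)
        expected = 14.0 / (production_flux(15.0, ref, model) * 120.0)
        assert model.kappa == pytest.approx(expected, rel=1e-12)

    def test_stem_influx_scale_invariance(self, model):
        """Only the product S0 * kappa matters once calibrated."""
        scaled = calibrate_kappa(
            dataclasses.replace(ModelParams(), stem_influx=7.5)
        )
        for p in random_patients(5, seed=5):
            for E in (3.0, 15.0, 80.0):
                assert steady_state(E, p, scaled).hemoglobin == pytest.approx(
                    steady_state(E, p, model).hemoglobin, rel=1e-12
                )

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            calibrate_kappa(ModelParams(), reference_life_span=0.0)


class TestEsaConcentration:
    def test_zero_before_first_dose(self):
        s = EsaSchedule(times=(10.0,), increments=(50.0,), half_life=20.0)
        assert esa_concentration(s, 5.0) == 0.0

    def test_half_life_definition(self):
        s = EsaSchedule(times=(0.0,), increments=(50.0,), half_life=24.0)
        assert esa_concentration(s, 1.0) == pytest.approx(25.0, rel=1e-12)

    def test_superposition_of_overlapping_doses(self):
        s = EsaSchedule(times=(0.0, 3.0), increments=(40.0, 60.0), half_life=30.0)
        rate = math.log(2) * 24.0 / 30.0
        for t in (3.0, 5.5, 10.0):
            expected = 40.0 * math.exp(-rate * t) + 60.0 * math.exp(-rate * (t - 3.0))
            assert esa_concentration(s, t) == pytest.approx(expected, rel=1e-12)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            EsaSchedule(times=(5.0, 1.0), increments=(1.0, 1.0), half_life=20.0)
        with pytest.raises(ValueError):
            EsaSchedule(times=(0.0,), increments=(-1.0,), half_life=20.0)
        with pytest.raises(ValueError):
            EsaSchedule(times=(0.0,), increments=(1.0,), half_life=0.0)


class TestSimulate:
    def test_converges_to_analytic_steady_state(self, model):
        p = make_patient(rbc_life_span=76.0)
        traj = simulate(p, model, lambda t: 15.0, t_end=5 * 76.0 + 20, dt=0.25)
        target = steady_state(15.0, p, model).hemoglobin
        assert abs(traj.hemoglobin[-1] - target) < 1e-3

    def test_steady_start_is_already_at_equilibrium(self, model):
        p = make_patient()
        traj = simulate(p, model, lambda t: 15.0, t_end=30.0, dt=0.25, start="steady")
        target = steady_state(15.0, p, model).hemoglobin
        np.testing.assert_allclose(traj.hemoglobin, target, atol=1e-9)

    def test_step_increase_delay_and_monotone_rise(self, model):
        """After an Epo step, Hb rises monotonically and no earlier than the
        maturation delay at the new Epo level."""
        p = make_patient(maturation_factor=0.5, apoptosis_sensitivity=30.0)
        t0, e_lo, e_hi, dt = 10.0, 15.0, 60.0, 0.05
        tau_new = model.maturation_delay / (1 + 0.5 * e_hi / (e_hi + 30.0))
        epo = lambda t: e_hi if t >= t0 else e_lo
        traj = simulate(p, model, epo, t_end=60.0, dt=dt, start="steady")
        hb0 = traj.hemoglobin[0]
        departed = np.abs(traj.hemoglobin - hb0) > 1e-9
        assert departed.any()
        first = traj.time[departed][0]
        assert first >= t0 + tau_new - 1e-9
        assert np.all(np.diff(traj.hemoglobin) >= -1e-12)

    def test_neocytolysis_lowers_steady_hemoglobin(self, model):
        """Constant Epo below the neocytolysis threshold removes young cells
        and must end strictly below the neocytolysis-off steady state."""
        p = make_patient(rbc_life_span=60.0)
        neo_on = dataclasses.replace(
            model,
            neocytolysis=NeocytolysisParams(
                enabled=True, age_cutoff=10.0, epo_threshold=12.0, extra_rate=0.05
            ),
        )
        epo = lambda t: 8.0  # always below threshold
        t_end = 5 * 60.0
        hb_off = simulate(p, model, epo, t_end, 0.25).hemoglobin[-1]
        hb_on = simulate(p, neo_on, epo, t_end, 0.25).hemoglobin[-1]
        assert hb_on < hb_off
        # rough magnitude: young cohorts carry the extra decay for age_cutoff days
        assert hb_on > hb_off * math.exp(-0.05 * 10.0) * 0.9

    def test_cohort_conservation(self, model):
        """Entering minus removed cells equals the change in the standing
        count at every step, including with neocytolysis active."""
        neo_on = dataclasses.replace(
            model,
            neocytolysis=NeocytolysisParams(
                enabled=True, age_cutoff=8.0, epo_threshold=20.0, extra_rate=0.1
            ),
        )
        p = make_patient(rbc_life_span=40.0)
        for m in (model, neo_on):
            traj = simulate(p, m, lambda t: 10.0 + 5 * math.sin(t / 7), 120.0, 0.25)
            delta = np.diff(traj.total_cells)
            balance = traj.entered[1:] - traj.removed[1:]
            scale = max(traj.total_cells.max(), 1.0)
            np.testing.assert_allclose(delta, balance, atol=1e-9 * scale)

    def test_invalid_grid_rejected(self, model):
        with pytest.raises(ValueError):
            simulate(make_patient(), model, lambda t: 15.0, t_end=10.0, dt=0.0)
        with pytest.raises(ValueError):
            simulate(make_patient(), model, lambda t: 15.0, t_end=0.0, dt=0.1)
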