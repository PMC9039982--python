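"""Unit tests for the multi-compartment lung mechanics and gas exchange."""

import numpy as np
import pytest

import aprvdp._kernels as K
from aprvdp import (CompartmentParams, CompartmentState, LungSimulator,
                    ModelConfig, VirtualPatient, blood_gas,
                    compartment_elastic_pressure, healthy_frc,
                    recruitment_update, run_vcv, VCVSettings)
from conftest import make_uniform_patient


class TestElasticPressure:
    def test_strictly_increasing_in_volume(self):
        params = CompartmentParams(p_ext=3.0, k_stiff=0.4, top=30.0, r_b=800)
        v = np.linspace(0.001, 0.06, 200)
        p = compartment_elastic_pressure(params, v)
        assert np.all(np.diff(p) > 0)

    def test_p_ext_additivity(self):
        a = CompartmentParams(p_ext=0.0, k_stiff=0.2, top=30.0, r_b=800)
        b = CompartmentParams(p_ext=5.0, k_stiff=0.2, top=30.0, r_b=800)
        for v in (0.01, 0.025, 0.04):
            assert compartment_elastic_pressure(b, v) == pytest.approx(
                compartment_elastic_pressure(a, v) + 5.0)

    def test_increasing_in_stiffness_above_resting_volume(self):
        soft = CompartmentParams(p_ext=0.0, k_stiff=0.0, top=30.0, r_b=800)
        stiff = CompartmentParams(p_ext=0.0, k_stiff=0.8, top=30.0, r_b=800)
        v = 0.035  # above V0 = 0.025
        assert compartment_elastic_pressure(stiff, v) \
            > compartment_elastic_pressure(soft, v)

    def test_zero_recoil_at_resting_volume(self):
        params = CompartmentParams(p_ext=0.0, k_stiff=0.3, top=30.0, r_b=800)
        cfg = ModelConfig()
        assert compartment_elastic_pressure(params, cfg.v0) == pytest.approx(0)

    def test_negative_volume_rejected(self):
        params = CompartmentParams(p_ext=0.0, k_stiff=0.0, top=30.0, r_b=800)
        with pytest.raises(ValueError, match="non-negative"):
            compartment_elastic_pressure(params, -0.01)


class TestRecruitment:
    @pytest.mark.parametrize("proximal,expected", [
        (29.9, False), (30.0, True), (35.0, True)])
    def test_opening_threshold(self, proximal, expected):
        params = CompartmentParams(p_ext=0.0, k_stiff=0.0, top=30.0, r_b=800)
        state = CompartmentState(volume=0.001, is_open=False, p_alv=0.0,
                                 f_o2=0.2, f_co2=0.05)
        assert recruitment_update(state, proximal, params).is_open is expected

    def test_closing_by_volume(self):
        cfg = ModelConfig()
        params = CompartmentParams(p_ext=0.0, k_stiff=0.0, top=30.0, r_b=800)
        open_state = CompartmentState(volume=0.5 * cfg.v_close, is_open=True,
                                      p_alv=0.0, f_o2=0.2, f_co2=0.05)
        assert recruitment_update(open_state, 40.0, params).is_open is False

    def test_idempotent_at_constant_pressure(self):
        params = CompartmentParams(p_ext=0.0, k_stiff=0.0, top=30.0, r_b=800)
        state = CompartmentState(volume=0.02, is_open=False, p_alv=0.0,
                                 f_o2=0.2, f_co2=0.05)
        once = recruitment_update(state, 31.0, params)
        twice = recruitment_update(once, 31.0, params)
        assert once.is_open == twice.is_open


class TestMechanics:
    def test_healthy_reference_frc(self):
        assert healthy_frc() == pytest.approx(2.5, abs=0.05)

    def test_rc_release_matches_analytic(self, rc_patient, linear_config):
        """Pressure step release of a linear RC lung: flow(t) =
        ((P0-P1)/R) exp(-t/tau) with tau = R*C, within 1% at dt = 1 ms."""
        sim = LungSimulator(rc_patient, linear_config)
        sim.reset(pressure=30.0, force_open=True)
        n = 500
        mode = np.zeros(n, dtype=np.int8)
        val = np.zeros(n)
        (paw, plung, flow, vol), _ = sim.run_segment(mode, val)
        cfg = linear_config
        c_total = 100 * cfg.c0
        r_total = cfg.r_central + rc_patient.r_b[0] / 100 \
            + cfg.dt / c_total  # semi-implicit solver adds dt/C
        tau = r_total * c_total
        t = np.arange(n) * cfg.dt
        analytic = -(30.0 / r_total) * np.exp(-t / tau)
        assert np.max(np.abs(flow - analytic) / np.abs(analytic).max()) < 0.01

    def test_volume_conservation(self):
        """Change in total alveolar volume equals the integral of mouth
        flow (the dead-space column is volume-rigid)."""
        patient = make_uniform_patient(r_b=950.0, top=5.0)
        cfg = ModelConfig()
        sim = LungSimulator(patient, cfg)
        sim.reset(pressure=0.0, force_open=True)
        v_start = sim.total_alveolar_volume
        n = 2000
        mode = np.zeros(n, dtype=np.int8)
        val = np.where(np.arange(n) < 1200, 20.0, 2.0)
        (paw, plung, flow, vol), _ = sim.run_segment(mode, val)
        assert abs((sim.total_alveolar_volume - v_start)
                   - flow.sum() * cfg.dt) < 1e-4

    def test_zero_flow_holds_volume(self, rc_patient, linear_config):
        sim = LungSimulator(rc_patient, linear_config)
        sim.reset(pressure=5.0, force_open=True)
        v0 = sim.equilibrate(5.0, duration=2.0)
        v1 = sim.equilibrate(5.0, duration=2.0)
        assert v1 == pytest.approx(v0, abs=1e-6)

    def test_single_step_and_state_snapshot(self, rc_patient, linear_config):
        sim = LungSimulator(rc_patient, linear_config)
        sim.reset(pressure=5.0, force_open=True, fio2=0.4)
        out = sim.step(("pressure", 20.0))
        assert out["paw"] == pytest.approx(20.0)
        assert out["flow"] > 0  # inflation toward the higher pressure
        state = sim.state()
        assert len(state.compartments) == 100
        comp = state.compartments[0]
        assert 0 <= comp.f_o2 <= 1 and 0 <= comp.f_co2 <= 1
        assert comp.f_balance == pytest.approx(
            1 - comp.f_o2 - comp.f_co2)
        assert state.alveolar_volume == pytest.approx(
            sim.total_alveolar_volume)

    def test_dt_stability_bound_reported(self):
        patient = make_uniform_patient(r_b=20.0)
        with pytest.raises(ValueError, match="time constant"):
            LungSimulator(patient, ModelConfig(dt=0.02))

    def test_compartment_permutation_invariance(self):
        """Compartments are exchangeable: permuting them leaves every
        whole-lung measurement unchanged."""
        rng = np.random.default_rng(0)
        patient = VirtualPatient(
            p_ext=rng.uniform(0, 15, 100), k_stiff=rng.uniform(-0.5, 0.8, 100),
            top=rng.uniform(5, 60, 100), r_b=rng.uniform(300, 3000, 100))
        perm = rng.permutation(100)
        shuffled = VirtualPatient(
            p_ext=patient.p_ext[perm], k_stiff=patient.k_stiff[perm],
            top=patient.top[perm], r_b=patient.r_b[perm])
        settings = VCVSettings(vt=0.42, peep=8.0, rr=15.0, dc=0.35, fio2=0.5)
        ms = []
        for p in (patient, shuffled):
            with pytest.warns(UserWarning):
                trace = run_vcv(p, settings, duration=20.0, min_cycles=4)
            ms.append((trace.pa_o2, trace.pa_co2,
                       trace.per_cycle["p_plat"].iloc[-1]))
        assert ms[0] == pytest.approx(ms[1], rel=1e-9)


class TestBloodGas:
    def test_full_shunt_returns_venous(self):
        patient = VirtualPatient.healthy_reference()
        cv = (K.o2_blood_content(40.0, patient.hb), K.co2_blood_content(46.0))
        pao2, paco2, _ = blood_gas([100.0], [40.0], [0.0], patient,
                                   shunt_weight=1.0, venous=cv)
        assert pao2 == pytest.approx(40.0, abs=0.1)
        assert paco2 == pytest.approx(46.0, abs=0.1)

    def test_zero_shunt_equals_end_capillary(self):
        patient = VirtualPatient.healthy_reference()
        pao2, _, _ = blood_gas([110.0] * 5, [40.0] * 5, [0.2] * 5, patient,
                               shunt_weight=0.0)
        assert pao2 == pytest.approx(110.0, abs=0.2)

    def test_more_shunt_lowers_pao2(self):
        patient = VirtualPatient.healthy_reference()
        lo, _, _ = blood_gas([300.0], [40.0], [0.9], patient,
                             shunt_weight=0.1)
        hi, _, _ = blood_gas([300.0], [40.0], [0.8], patient,
                             shunt_weight=0.2)
        assert hi < lo

    def test_rejects_nonpositive_hb(self):
        patient = VirtualPatient.healthy_reference()
        patient.hb = 0.0
        with pytest.raises(ValueError, match="haemoglobin"):
            blood_gas([100.0], [40.0], [1.0], patient, shunt_weight=0.0)

    def test_weights_must_sum_to_one(self):
        patient = VirtualPatient.healthy_reference()
        with pytest.raises(ValueError, match="sum to 1"):
            blood_gas([100.0], [40.0], [0.5], patient, shunt_weight=0.1)

    def test_steady_state_gas_balance(self):
        """At cyclic steady state the mouth O2 uptake approaches VO2 and
        the CO2 output approaches RQ*VO2 (5% tolerance)."""
        patient = make_uniform_patient(r_b=950.0, k_stiff=0.3, top=5.0,
                                       p_ext=5.0)
        patient.vo2 = 250.0
        patient.rq = 0.8
        settings = VCVSettings(vt=0.45, peep=6.0, rr=14.0, dc=0.35, fio2=0.5)
        trace = run_vcv(patient, settings, duration=600.0, min_cycles=40)
        last = trace.per_cycle.iloc[-1]
        t_cycle = 60.0 / settings.rr
        vo2_mouth = last["mouth_o2_uptake"] / t_cycle * 60e3   # mL/min
        vco2_mouth = last["mouth_co2_output"] / t_cycle * 60e3
        assert vo2_mouth == pytest.approx(patient.vo2, rel=0.05)
        assert vco2_mouth == pytest.approx(patient.rq * patient.vo2, rel=0.05)


class TestValidation:
    def test_patient_requires_100_compartments(self):
        with pytest.raises(ValueError, match="100"):
            VirtualPatient(p_ext=np.zeros(5), k_stiff=np.zeros(5),
                           top=np.zeros(5), r_b=np.ones(5))

    def test_bounds_checked(self):
        patient = VirtualPatient.healthy_reference()
        patient.validate()
        patient.vo2 = 500.0
        with pytest.raises(ValueError, match="VO2"):
            patient.validate()

    def test_compartment_params_bounds(self):
        CompartmentParams(p_ext=0, k_stiff=0, top=30, r_b=800).validate()
        with pytest.raises(ValueError):
            CompartmentParams(p_ext=40, k_stiff=0, top=30, r_b=800).validate()
        with pytest.raises(ValueError):
            CompartmentParams(p_ext=0, k_stiff=0, top=30, r_b=-1).validate()
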