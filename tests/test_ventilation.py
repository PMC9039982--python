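"""Tests of the APRV/VCV drivers and waveform measurement extraction."""

import numpy as np
import pytest

from aprvdp import (APRVSettings, LungSimulator, ModelConfig, VCVSettings,
                    WaveformTrace, extract_measurements, run_aprv, run_vcv)
from conftest import make_uniform_patient


class TestSettings:
    def test_mandatory_rate(self):
        s = APRVSettings(p_high=30, p_low=5, t_high=5.0, t_low=0.5)
        assert s.mandatory_rate == pytest.approx(60 / 5.5)

    @pytest.mark.parametrize("kwargs", [
        dict(p_high=5, p_low=5, t_high=5, t_low=0.5),
        dict(p_high=30, p_low=-1, t_high=5, t_low=0.5),
        dict(p_high=30, p_low=5, t_high=0, t_low=0.5),
    ])
    def test_invalid_aprv_settings(self, kwargs):
        with pytest.raises(ValueError):
            APRVSettings(**kwargs)

    @pytest.mark.parametrize("kwargs", [
        dict(vt=0, peep=5, rr=15), dict(vt=0.4, peep=5, rr=0),
        dict(vt=0.4, peep=5, rr=15, dc=1.2)])
    def test_invalid_vcv_settings(self, kwargs):
        with pytest.raises(ValueError):
            VCVSettings(**kwargs)


class TestAPRV:
    def test_square_pressure_wave(self, rc_patient, linear_config):
        settings = APRVSettings(p_high=30, p_low=5, t_high=5, t_low=0.5)
        trace = run_aprv(rc_patient, settings, duration=60,
                         config=linear_config)
        assert set(np.round(np.unique(trace.paw), 6)) == {5.0, 30.0}

    def test_rc_peep_tot_analytic(self, rc_patient, linear_config):
        """Single-compartment RC release, tau = 0.5 s = T_low:
        PEEP_tot = P_high * exp(-1) ~ 11.0 cmH2O."""
        settings = APRVSettings(p_high=30, p_low=0, t_high=5, t_low=0.5)
        trace = run_aprv(rc_patient, settings, duration=120,
                         config=linear_config)
        ms = extract_measurements(trace)
        assert ms.peep_tot == pytest.approx(30 * np.exp(-1), rel=0.02)

    def test_long_release_empties_lung(self, rc_patient, linear_config):
        """T_low >> tau: complete exhalation, PEEP_tot -> P_low."""
        settings = APRVSettings(p_high=30, p_low=5, t_high=5, t_low=5.0)
        trace = run_aprv(rc_patient, settings, duration=120,
                         config=linear_config)
        ms = extract_measurements(trace)
        assert ms.peep_tot == pytest.approx(5.0, abs=0.1)

    def test_released_volume_matches_compliance(self, rc_patient,
                                                linear_config):
        """V_released = C * (P_start - PEEP_tot) for the linear lung."""
        settings = APRVSettings(p_high=30, p_low=0, t_high=5, t_low=0.5)
        trace = run_aprv(rc_patient, settings, duration=120,
                         config=linear_config)
        ms = extract_measurements(trace)
        c_total = 100 * linear_config.c0
        assert ms.v_released == pytest.approx(
            c_total * (ms.p_plat - ms.peep_tot), rel=0.02)

    def test_pefr_eefr_analytic(self, rc_patient, linear_config):
        """PEFR = (P_plat - P_low)/R and EEFR = PEFR*exp(-T_low/tau)."""
        settings = APRVSettings(p_high=30, p_low=0, t_high=5, t_low=0.5)
        trace = run_aprv(rc_patient, settings, duration=120,
                         config=linear_config)
        ms = extract_measurements(trace)
        c_total = 100 * linear_config.c0
        r_total = linear_config.r_central + rc_patient.r_b[0] / 100 \
            + linear_config.dt / c_total
        tau = r_total * c_total
        assert ms.pefr / 60 == pytest.approx(ms.p_plat / r_total, rel=0.01)
        assert ms.eefr / ms.pefr == pytest.approx(
            np.exp(-(settings.t_low - linear_config.dt) / tau), rel=0.01)

    def test_warns_when_not_steady(self, rc_patient, linear_config):
        settings = APRVSettings(p_high=30, p_low=5, t_high=5, t_low=0.5)
        with pytest.warns(UserWarning, match="steady"):
            trace = run_aprv(rc_patient, settings, duration=11.1,
                             config=linear_config, min_cycles=2)
        assert trace.steady is False

    def test_duration_must_cover_two_cycles(self, rc_patient, linear_config):
        with pytest.raises(ValueError, match="two"):
            run_aprv(rc_patient, APRVSettings(30, 5, 5, 0.5), duration=6,
                     config=linear_config)


class TestVCV:
    def test_linear_statics(self, rc_patient, linear_config):
        """P_plat - PEEP_tot = VT/C on the linear patient (2%)."""
        c_total = 100 * linear_config.c0
        for vt in (0.3, 0.6):
            settings = VCVSettings(vt=vt, peep=5.0, rr=12.0, dc=0.3)
            trace = run_vcv(rc_patient, settings, duration=120,
                            config=linear_config)
            ms = extract_measurements(trace)
            assert ms.p_plat - ms.peep_tot == pytest.approx(
                vt / c_total, rel=0.02)
            assert ms.c == pytest.approx(c_total, rel=0.02)

    def test_excessive_vt_rejected(self, rc_patient):
        settings = VCVSettings(vt=30.0, peep=5.0, rr=12.0)
        with pytest.raises(ValueError, match="bound"):
            run_vcv(rc_patient, settings, duration=60)

    def test_peak_exceeds_plateau(self, rc_patient, linear_config):
        settings = VCVSettings(vt=0.45, peep=5.0, rr=14.0, dc=0.35)
        trace = run_vcv(rc_patient, settings, duration=60,
                        config=linear_config)
        ms = extract_measurements(trace)
        assert ms.p_peak > ms.p_plat > ms.peep_tot


class TestExtractMeasurements:
    def test_stated_raw_formula(self):
        """R_aw = (P_peak - P_plat)/PeakFlow: 32, 28, 60 L/min -> 4/60."""
        n = 1000
        t = np.arange(n) * 1e-3
        flow = np.where(t < 0.5, 1.0, -1.0)   # 60 L/min each way
        paw = np.where(t < 0.5, 32.0, 5.0)
        plung = np.where(t < 0.5, 28.0, 12.0)
        vol = 2.0 + np.cumsum(flow) * 1e-3
        trace = WaveformTrace(time=t, paw=paw, plung=plung, flow=flow,
                              volume=vol, dt_sample=1e-3, mode="aprv",
                              settings=None, cycle_samples=n, steady=True,
                              fio2=0.5, pa_o2=100.0)
        ms = extract_measurements(trace)
        assert ms.r_aw == pytest.approx(4.0 / 60.0)
        assert ms.p_peak == 32.0
        assert ms.p_plat == 28.0
        assert ms.peep_tot == 12.0
        assert ms.pefr == pytest.approx(60.0)
        assert ms.v_released == pytest.approx(0.5)
        assert ms.pf_ratio == pytest.approx(200.0)
        assert ms.c == pytest.approx(0.5 / 16.0)
        assert ms.e == pytest.approx(16.0 / 0.5)

    def test_requires_full_cycle(self):
        trace = WaveformTrace(
            time=np.arange(10) * 1e-3, paw=np.ones(10), plung=np.ones(10),
            flow=np.ones(10), volume=np.ones(10), dt_sample=1e-3,
            mode="aprv", settings=None, cycle_samples=100, steady=True,
            fio2=0.5)
        with pytest.raises(ValueError, match="full"):
            extract_measurements(trace)

    def test_pressure_ordering_invariant(self):
        """For a lung under APRV: P_low <= PEEP_tot <= P_plat <= P_high."""
        patient = make_uniform_patient(r_b=950.0, k_stiff=0.3, p_ext=8.0,
                                       top=20.0)
        settings = APRVSettings(p_high=30, p_low=5, t_high=5, t_low=0.5)
        trace = run_aprv(patient, settings, duration=300)
        ms = extract_measurements(trace)
        assert settings.p_low <= ms.peep_tot <= ms.p_plat <= settings.p_high

    def test_csv_roundtrip(self, rc_patient, linear_config, tmp_path):
        settings = APRVSettings(p_high=30, p_low=5, t_high=5, t_low=0.5)
        trace = run_aprv(rc_patient, settings, duration=60,
                         config=linear_config)
        path = tmp_path / "wave.csv"
        trace.to_csv(path)
        back = WaveformTrace.from_csv(path, mode="aprv",
                                      cycle_duration=settings.cycle_duration)
        ms0 = extract_measurements(trace)
        ms1 = extract_measurements(back)
        assert ms1.p_plat == pytest.approx(ms0.p_plat, rel=1e-6)
        assert ms1.v_released == pytest.approx(ms0.v_released, rel=1e-4)
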