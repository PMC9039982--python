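"""Bedside estimators of the ventilator driving pressure during APRV.

True driving pressure is defined on the lung-pressure waveform,

    dP = P_plat - PEEP_tot,

which a ventilator cannot display during APRV because the releases are too
short for the lung to empty.  Three bedside surrogates are implemented:

* the time-constant method: estimate the intrinsic PEEP left at the end of
  the release as PEEP_i = [ (n/2) * tau * PEFR - V_released ] * E with
  tau = R_aw * C, assuming full exhalation takes n = 4 (or 3) time
  constants, then dP = P_high - (PEEP_i + P_low);
* the mono-exponential method: assume flow, volume and pressure decay
  mono-exponentially, so PEEP_i = (EEFR/PEFR) * P_high and
  dP = P_high - ((EEFR/PEFR) * P_high + P_low);
* the VCV-switch method: temporarily ventilate with VCV at VT = V_released
  and PEEP = PEEP_tot, read the plateau and take dP = P_plat(VCV) - PEEP
  (assuming the monitoring PEEP equals the true total expiratory pressure).

The mechanics entering tau and E come from the patient's baseline
constant-flow VCV measurement set: under APRV's square pressure wave the
lung pressure approaches P_high at end-inspiration, so an APRV-derived
(P_peak - P_plat)/PeakFlow resistance degenerates to zero and with it the
time constant.  Only a constant-flow breath yields a usable R_aw and static
compliance, which is also how the measurement is made at the bedside.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .model_core import LungSimulator, ModelConfig, VirtualPatient
from .ventilation import (APRVSettings, MeasurementSet, VCVSettings,
                          extract_measurements, run_vcv)


@dataclasses.dataclass
class DPReport:
    """True driving pressure, its four bedside estimates, and their errors."""

    dp_true: float
    dp_mono: float
    dp_tau4: float
    dp_tau3: float
    dp_vcv: float = np.nan

    def error(self, name: str) -> float:
        """Estimation error (estimate - truth) for 'mono'|'tau4'|'tau3'|'vcv'."""
        return getattr(self, f"dp_{name}") - self.dp_true

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("mono", "tau4", "tau3", "vcv"):
            d[f"err_{name}"] = self.error(name)
        return d


def dp_true(p_plat: float, peep_tot: float) -> float:
    """True driving pressure from the lung pressure waveform (cmH2O)."""
    if p_plat < peep_tot:
        raise ValueError("P_plat must not be below PEEP_tot")
    return p_plat - peep_tot


def peepi_tau(tau: float, pefr: float, v_released: float, elastance: float,
              n_tau: int = 4) -> float:
    """Intrinsic PEEP estimate from the time-constant method (cmH2O).

    PEEP_i = [ (n_tau/2) * tau * PEFR - V_released ] * elastance, with
    tau in s, PEFR in L/s, V_released in L and elastance in cmH2O/L.
    A negative estimate (possible when V_released is large) is clamped to
    zero with a warning; negative intrinsic PEEP is unphysical.
    """
    if n_tau not in (3, 4):
        raise ValueError("n_tau must be 3 or 4")
    if tau <= 0 or pefr <= 0 or v_released <= 0 or elastance <= 0:
        raise ValueError("tau, PEFR, V_released and elastance must be positive")
    peepi = (0.5 * n_tau * tau * pefr - v_released) * elastance
    if peepi < 0:
        warnings.warn("negative intrinsic-PEEP estimate clamped to zero")
        return 0.0
    return peepi


def dp_from_peepi(p_high: float, p_low: float, peepi: float) -> float:
    """Driving pressure from an intrinsic-PEEP estimate:
    dP = P_high - (PEEP_i + P_low)."""
    for v in (p_high, p_low, peepi):
        if not np.isfinite(v):
            raise ValueError("inputs must be finite")
    return p_high - (peepi + p_low)


def dp_mono(p_high: float, p_low: float, eefr: float, pefr: float) -> float:
    """Mono-exponential-decay estimate of driving pressure.

    dP = P_high - ((EEFR/PEFR) * P_high + P_low).  EEFR and PEFR are flow
    magnitudes in any (identical) unit; only their ratio enters.
    """
    if pefr <= 0:
        raise ValueError("PEFR must be positive")
    if eefr < 0 or eefr > pefr:
        raise ValueError("EEFR must lie in [0, PEFR]")
    return p_high - ((eefr / pefr) * p_high + p_low)


def dp_vcv_switch(patient: VirtualPatient,
                  aprv_measurements: MeasurementSet,
                  fio2: float,
                  rr: float,
                  dc: float = 0.33,
                  config: ModelConfig | None = None,
                  sim: LungSimulator | None = None,
                  duration: float = 300.0) -> float:
    """Driving-pressure estimate by temporarily switching to VCV.

    Ventilates (for 5 simulated minutes or until steady) with
    VT = V_released and PEEP = PEEP_tot from the APRV measurement set, then
    returns P_plat(VCV) - PEEP, assuming the monitoring PEEP recorded equals
    the actual total expiratory pressure.  Pass the simulator that produced
    the APRV run as ``sim`` to carry over the recruitment state, as the
    in-silico protocol does.
    """
    settings = VCVSettings(
        vt=aprv_measurements.v_released,
        peep=aprv_measurements.peep_tot,
        rr=rr, dc=dc, fio2=fio2,
    )
    trace = run_vcv(patient, settings, duration=duration, config=config,
                    sim=sim)
    ms = extract_measurements(trace)
    return ms.p_plat - settings.peep


def expiratory_time_constant(baseline: MeasurementSet) -> float:
    """tau = resistance x static compliance, in seconds, from a baseline
    constant-flow VCV measurement set (R_aw is stored per L/min)."""
    r = baseline.r_aw * 60.0   # cmH2O/(L/s)
    tau = r * baseline.c
    if not np.isfinite(tau) or tau <= 0:
        raise ValueError("baseline measurements give no usable time constant")
    return tau


def estimate_all(aprv_ms: MeasurementSet, baseline_ms: MeasurementSet,
                 settings: APRVSettings,
                 patient: VirtualPatient | None = None,
                 config: ModelConfig | None = None,
                 sim: LungSimulator | None = None,
                 rr: float = 15.0, dc: float = 0.33,
                 run_vcv_switch: bool = True) -> DPReport:
    """Compute the true driving pressure and every bedside estimate.

    ``aprv_ms`` supplies the release quantities (PEFR, EEFR, V_released,
    PEEP_tot, P_plat); ``baseline_ms`` the constant-flow mechanics (R_aw, C,
    E) entering the time-constant method.  The VCV-switch estimate needs the
    ``patient`` (and ideally the post-APRV ``sim`` state); disable it with
    ``run_vcv_switch=False`` when only waveform data are available.
    """
    truth = dp_true(aprv_ms.p_plat, aprv_ms.peep_tot)
    mono = dp_mono(settings.p_high, settings.p_low,
                   aprv_ms.eefr, aprv_ms.pefr)
    tau = expiratory_time_constant(baseline_ms)
    pefr_ls = aprv_ms.pefr / 60.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pi4 = peepi_tau(tau, pefr_ls, aprv_ms.v_released, baseline_ms.e, 4)
        pi3 = peepi_tau(tau, pefr_ls, aprv_ms.v_released, baseline_ms.e, 3)
    tau4 = dp_from_peepi(settings.p_high, settings.p_low, pi4)
    tau3 = dp_from_peepi(settings.p_high, settings.p_low, pi3)
    vcv = np.nan
    if run_vcv_switch:
        if patient is None:
            raise ValueError("VCV-switch estimation requires the patient")
        vcv = dp_vcv_switch(patient, aprv_ms, settings.fio2, rr, dc,
                            config=config, sim=sim)
    return DPReport(dp_true=truth, dp_mono=mono, dp_tau4=tau4,
                    dp_tau3=tau3, dp_vcv=vcv)
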