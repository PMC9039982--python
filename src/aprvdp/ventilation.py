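"""Ventilator boundary conditions and waveform measurements.

Two modes are provided.  APRV is driven as a square pressure wave: ``P_high``
held for ``T_high`` followed by a release to ``P_low`` for ``T_low``
(BiLevel with extreme I:E inversion, no spontaneous effort).  VCV delivers a
constant inspiratory flow over the first 80% of the inspiratory time, an
end-inspiratory hold over the remaining 20% (long enough to read a plateau),
then passive expiration against the set PEEP.

Runs proceed breath by breath until cyclic steady state (consecutive-cycle
total PEEP within 0.1 cmH2O and arterial CO2 within 0.25 mmHg) or until the
requested duration is exhausted, whichever comes first; the measurement
bullet list is evaluated on the final complete cycle.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import _kernels as K
from .model_core import LungSimulator, ModelConfig, VirtualPatient


@dataclasses.dataclass
class APRVSettings:
    """Airway pressure release ventilation settings."""

    p_high: float          # cmH2O
    p_low: float           # cmH2O
    t_high: float = 5.0    # s
    t_low: float = 0.5     # s
    fio2: float = 0.21

    def __post_init__(self):
        if not self.p_high > self.p_low >= 0:
            raise ValueError("require P_high > P_low >= 0")
        if self.t_high <= 0 or self.t_low <= 0:
            raise ValueError("phase durations must be positive")

    @property
    def cycle_duration(self) -> float:
        return self.t_high + self.t_low

    @property
    def mandatory_rate(self) -> float:
        """Mandatory breath rate, breaths/min = 60/(T_high + T_low)."""
        return 60.0 / self.cycle_duration


@dataclasses.dataclass
class VCVSettings:
    """Volume-controlled ventilation settings."""

    vt: float              # tidal volume, L
    peep: float            # cmH2O
    rr: float              # breaths/min
    dc: float = 0.33       # duty cycle (inspiratory fraction of the cycle)
    fio2: float = 0.21

    def __post_init__(self):
        if self.vt <= 0:
            raise ValueError("VT must be positive")
        if self.rr <= 0:
            raise ValueError("RR must be positive")
        if not 0 < self.dc < 1:
            raise ValueError("DC must lie in (0, 1)")

    @property
    def cycle_duration(self) -> float:
        return 60.0 / self.rr


@dataclasses.dataclass
class WaveformTrace:
    """Sampled ventilation waveforms plus end-of-run blood-gas summary.

    ``flow`` is the mouth flow in L/s, inspiratory positive; ``plung`` is the
    volume-weighted mean alveolar pressure of the communicating lung;
    ``volume`` is total alveolar volume.
    """

    time: np.ndarray
    paw: np.ndarray
    plung: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    dt_sample: float
    mode: str                      # "aprv" | "vcv" | "external"
    settings: object | None
    cycle_samples: int             # samples per ventilator cycle
    steady: bool
    fio2: float
    pa_o2: float = np.nan
    pa_co2: float = np.nan
    petco2: float = np.nan
    per_cycle: pd.DataFrame | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.time) // self.cycle_samples

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "time_s": self.time,
            "paw_cmH2O": self.paw,
            "plung_cmH2O": self.plung,
            "flow_L_min": self.flow * 60.0,
            "volume_L": self.volume,
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mode: str = "external",
                 cycle_duration: float | None = None) -> "WaveformTrace":
        df = pd.read_csv(path)
        required = ["time_s", "paw_cmH2O", "plung_cmH2O", "flow_L_min",
                    "volume_L"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"waveform CSV missing columns: {missing}")
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError("waveform CSV must contain at least two samples")
        dt = float(np.median(np.diff(t)))
        if cycle_duration is None:
            cyc = len(t)
        else:
            cyc = int(round(cycle_duration / dt))
        return cls(
            time=t,
            paw=df["paw_cmH2O"].to_numpy(float),
            plung=df["plung_cmH2O"].to_numpy(float),
            flow=df["flow_L_min"].to_numpy(float) / 60.0,
            volume=df["volume_L"].to_numpy(float),
            dt_sample=dt, mode=mode, settings=None,
            cycle_samples=cyc, steady=True, fio2=np.nan,
        )


@dataclasses.dataclass
class MeasurementSet:
    """Quantities read from the waveforms of one ventilator cycle.

    Flows are magnitudes in L/min; volumes in L except V_frc (mL);
    R_aw in cmH2O/(L/min); C in L/cmH2O with E = 1/C in cmH2O/L.
    """

    p_plat: float
    p_peak: float
    peep_tot: float
    v_released: float
    pefr: float
    eefr: float
    v_t: float
    pf_ratio: float
    v_frc: float
    r_aw: float
    c: float
    e: float

    @property
    def pip(self) -> float:
        """Peak inspiratory pressure (ventilator waveform) -- alias of P_peak."""
        return self.p_peak

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pip"] = self.pip
        return d


def _aprv_cycle_program(settings: APRVSettings, dt: float):
    n_hi = int(round(settings.t_high / dt))
    n_lo = int(round(settings.t_low / dt))
    mode = np.zeros(n_hi + n_lo, dtype=np.int8)
    val = np.empty(n_hi + n_lo)
    val[:n_hi] = settings.p_high
    val[n_hi:] = settings.p_low
    return mode, val


def _vcv_cycle_program(settings: VCVSettings, dt: float,
                       flow_fraction: float = 0.8):
    t_cycle = settings.cycle_duration
    t_insp = settings.dc * t_cycle
    n_cycle = int(round(t_cycle / dt))
    n_insp = int(round(t_insp / dt))
    n_flow = max(1, int(round(flow_fraction * t_insp / dt)))
    q = settings.vt / (n_flow * dt)
    mode = np.zeros(n_cycle, dtype=np.int8)
    val = np.empty(n_cycle)
    mode[:n_insp] = 1
    val[:n_flow] = q
    val[n_flow:n_insp] = 0.0          # end-inspiratory hold
    val[n_insp:] = settings.peep      # passive expiration
    return mode, val


def _run_cyclic(sim: LungSimulator, mode, val, duration, min_cycles,
                peep_tol=0.1, paco2_tol=0.25, record_last=2):
    """Breath-by-breath loop with steady-state detection.

    Records every cycle's measurement summary; keeps full-resolution traces
    for all cycles (the caller trims what it needs).
    """
    dt = sim.config.dt
    t_cycle = len(mode) * dt
    max_cycles = max(min_cycles, int(round(duration / t_cycle)))
    rows = []
    traces = []
    prev_peep = None
    prev_paco2 = None
    steady = False
    n_run = 0
    for c in range(max_cycles):
        tr, meas = sim.run_segment(mode, val)
        sim.update_venous(meas, t_cycle)
        traces.append(tr)
        if len(traces) > record_last:
            traces.pop(0)
        rows.append({
            "cycle": c,
            "pip": meas[K.M_PIP], "p_plat": meas[K.M_PPLAT],
            "peep_tot": meas[K.M_PEEPTOT], "v_frc": meas[K.M_VFRC],
            "pefr": meas[K.M_PEFR], "eefr": meas[K.M_EEFR],
            "v_released": meas[K.M_VREL], "v_insp": meas[K.M_VINSP],
            "petco2": meas[K.M_PETCO2],
            "pa_o2": sim.pa_o2, "pa_co2": sim.pa_co2,
            "mouth_o2_uptake": meas[K.M_MO2_IN] - meas[K.M_MO2_OUT],
            "mouth_co2_output": meas[K.M_MCO2_OUT] - meas[K.M_MCO2_IN],
            "n_open": int(np.sum(sim.is_open)),
        })
        n_run = c + 1
        peep = meas[K.M_PEEPTOT]
        if (c + 1 >= min_cycles and prev_peep is not None
                and abs(peep - prev_peep) < peep_tol
                and prev_paco2 is not None and np.isfinite(sim.pa_co2)
                and abs(sim.pa_co2 - prev_paco2) < paco2_tol):
            steady = True
            break
        prev_peep = peep
        prev_paco2 = sim.pa_co2
    return rows, traces, steady, n_run


def _assemble_trace(sim, traces, rows, steady, mode_name, settings, t_cycle):
    dt_s = sim.config.dt * sim.config.sample_every
    paw = np.concatenate([t[0] for t in traces])
    plung = np.concatenate([t[1] for t in traces])
    flow = np.concatenate([t[2] for t in traces])
    vol = np.concatenate([t[3] for t in traces])
    n = len(paw)
    t_end = sim.time
    time = t_end - (n - np.arange(n)) * dt_s
    return WaveformTrace(
        time=time, paw=paw, plung=plung, flow=flow, volume=vol,
        dt_sample=dt_s, mode=mode_name, settings=settings,
        cycle_samples=len(traces[-1][0]), steady=steady,
        fio2=sim.fio2, pa_o2=sim.pa_o2, pa_co2=sim.pa_co2,
        petco2=sim.petco2, per_cycle=pd.DataFrame(rows),
    )


def run_aprv(patient: VirtualPatient, settings: APRVSettings,
             duration: float = 1800.0, config: ModelConfig | None = None,
             sim: LungSimulator | None = None,
             min_cycles: int = 5) -> WaveformTrace:
    """Ventilate a patient with APRV until cyclic steady state.

    ``duration`` caps the simulated time (default the study's 30 min); the
    run stops as soon as consecutive cycles agree.  If no steady state is
    reached within ``duration`` the trace is flagged ``steady=False`` and a
    warning is issued.  Pass an existing ``sim`` to continue from its state.
    """
    if duration < 2 * settings.cycle_duration:
        raise ValueError("duration must cover at least two APRV cycles")
    config = config or ModelConfig()
    if sim is None:
        sim = LungSimulator(patient, config)
        sim.reset(pressure=settings.p_low, fio2=settings.fio2)
    else:
        sim.fio2 = settings.fio2
    mode, val = _aprv_cycle_program(settings, sim.config.dt)
    rows, traces, steady, _ = _run_cyclic(
        sim, mode, val, duration, min_cycles)
    if not steady:
        warnings.warn("APRV run did not reach cyclic steady state "
                      "within the requested duration")
    trace = _assemble_trace(sim, traces, rows, steady, "aprv", settings,
                            settings.cycle_duration)
    trace._sim = sim  # kept for estimator hand-off (VCV switch)
    return trace


def run_vcv(patient: VirtualPatient, settings: VCVSettings,
            duration: float = 300.0, config: ModelConfig | None = None,
            sim: LungSimulator | None = None,
            min_cycles: int = 5) -> WaveformTrace:
    """Ventilate a patient with constant-flow VCV until cyclic steady state."""
    config = config or ModelConfig()
    if sim is None:
        sim = LungSimulator(patient, config)
        sim.reset(pressure=settings.peep, fio2=settings.fio2)
    else:
        sim.fio2 = settings.fio2
    # physical bound: refuse a VT that would drive recoil beyond ~100 cmH2O
    cfg = sim.config
    if cfg.beta > 0:
        v_max = 100 * K.equilibrium_volume(100.0, 0.0, 0.0, cfg.beta,
                                           cfg.c0, cfg.v0, 0.0)
        if sim.total_alveolar_volume + settings.vt > v_max:
            raise ValueError(
                f"VT={settings.vt} L would exceed the physical lung volume "
                f"bound ({v_max:.2f} L)")
    mode, val = _vcv_cycle_program(settings, sim.config.dt)
    rows, traces, steady, _ = _run_cyclic(
        sim, mode, val, duration, min_cycles)
    if not steady:
        warnings.warn("VCV run did not reach cyclic steady state "
                      "within the requested duration")
    trace = _assemble_trace(sim, traces, rows, steady, "vcv", settings,
                            settings.cycle_duration)
    trace._sim = sim
    return trace


def extract_measurements(trace: WaveformTrace) -> MeasurementSet:
    """Evaluate the measurement bullet list on the final complete cycle.

    P_plat is the maximum of the lung-pressure waveform, P_peak the maximum
    of the ventilator-pressure waveform, PEEP_tot the lung pressure at end
    expiration, V_frc the minimum lung volume, PEFR/EEFR the peak and final
    magnitudes of expiratory flow, R_aw = (P_peak - P_plat)/peak inspiratory
    flow, C = V_t/(P_plat - PEEP_tot) and E = 1/C.
    """
    n = trace.cycle_samples
    if n < 2 or len(trace.paw) < n:
        raise ValueError("trace does not contain a full ventilator cycle")
    sl = slice(len(trace.paw) - n, len(trace.paw))
    paw = trace.paw[sl]
    plung = trace.plung[sl]
    flow = trace.flow[sl]
    vol = trace.volume[sl]
    dt = trace.dt_sample

    p_peak = float(paw.max())
    p_plat = float(plung.max())
    peep_tot = float(plung[-1])
    exp_mask = flow < 0
    if exp_mask.any():
        pefr = float(-flow[exp_mask].min())
        last_exp = np.nonzero(exp_mask)[0][-1]
        eefr = float(-flow[last_exp])
        v_released = float(-np.sum(flow[exp_mask]) * dt)
    else:
        pefr = eefr = v_released = 0.0
    insp_mask = flow > 0
    peak_insp = float(flow[insp_mask].max()) if insp_mask.any() else np.nan
    v_insp = float(np.sum(flow[insp_mask]) * dt) if insp_mask.any() else 0.0
    v_t = v_released if trace.mode == "aprv" else v_insp
    v_frc = float(vol.min()) * 1000.0
    r_aw = ((p_peak - p_plat) / (peak_insp * 60.0)
            if peak_insp and np.isfinite(peak_insp) and peak_insp > 0
            else np.nan)
    dp = p_plat - peep_tot
    c = v_t / dp if dp > 0 else np.nan
    e = 1.0 / c if c and np.isfinite(c) and c > 0 else np.nan
    pf = (trace.pa_o2 / trace.fio2
          if np.isfinite(trace.pa_o2) and trace.fio2 else np.nan)
    return MeasurementSet(
        p_plat=p_plat, p_peak=p_peak, peep_tot=peep_tot,
        v_released=v_released, pefr=pefr * 60.0, eefr=eefr * 60.0,
        v_t=v_t, pf_ratio=pf, v_frc=v_frc, r_aw=r_aw, c=c, e=e,
    )
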