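"""Mechanistic simulator of the ventilated ARDS lung.

The lung is modelled as 100 independently configurable alveolar compartments
in parallel behind a common proximal node, fed through a central airway
resistance and a series dead-space gas column.  Each compartment carries an
extrinsic pressure offset ``P_ext`` (positive values compress the unit and
promote collapse), a dimensionless stiffness ``k_stiff`` scaling its
exponential pressure-volume relation, a threshold opening pressure ``TOP``
that gates recruitment of a collapsed unit, and a bronchiolar inlet
resistance ``R_b`` that distributes flow among the parallel units.

Recoil pressure of a compartment with gas volume V is the sigmoid

    P_el(V) = P_ext + exp(k_stiff) * sinh(beta*(V - V0)) / (beta * C0)

with V0 = 25 mL and C0 = 0.5 mL/cmH2O chosen so that the healthy reference
lung (all P_ext = 0, k_stiff = 0) has an FRC of 2.5 L at zero airway pressure
and a total compliance of 50 mL/cmH2O there; ``beta`` (default 320 /L) sets
how quickly the units stiffen away from their resting volume (in both
directions, as on the flat limbs of a sigmoid PV curve).  ``beta = 0``
gives the exact linear limit used by the analytic test fixtures.

Gas exchange: uniform perfusion of cardiac output across all 100
compartments; blood reaching a collapsed compartment is shunted unchanged
(alveolar shunt), as is the anatomical shunt fraction.  End-capillary blood
equilibrates with alveolar gas via a Severinghaus O2 saturation curve and a
linearised CO2 dissociation curve; the mixed-venous composition is relaxed
to its Fick steady state (VO2, VCO2 = RQ*VO2) between breaths.

Units: pressures cmH2O, volumes L, flows L/s internally (L/min at user
interfaces), blood-gas tensions mmHg.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import _kernels as K

N_COMPARTMENTS = 100

# Table-style bounds for the calibration parameter space
PEXT_RANGE = (-50.0, 28.8)
KSTIFF_RANGE = (-2.0, 1.0)
TOP_RANGE = (5.0, 100.0)
RQ_RANGE = (0.7, 0.9)
VO2_RANGE = (150.0, 300.0)
HB_RANGE = (90.0, 160.0)
SHUNT_RANGE = (1.0, 2.0)      # percent
VD_RANGE = (60.0, 150.0)      # mL

MMHG_PER_KPA = 7.50062


def kpa(mmhg: float) -> float:
    """Convert a blood-gas tension from mmHg to kPa."""
    return mmhg / MMHG_PER_KPA


@dataclasses.dataclass
class ModelConfig:
    """Numerical and plumbing constants of the simulator.

    dt           -- integration step, s (fixed-step explicit update)
    beta         -- PV-curve curvature, 1/L (0 selects the linear limit)
    c0           -- per-compartment baseline compliance at V0, L/cmH2O
    v0           -- per-compartment resting volume, L
    r_central    -- central (conducting airway + tube) resistance, cmH2O/(L/s)
    exp_factor   -- expiratory/inspiratory resistance ratio (dynamic airway
                    compression and the expiratory circuit; >= 1)
    n_ds_slices  -- number of well-mixed slices of the series dead space
    gas_every    -- gas-exchange sub-stepping (every gas_every mechanics steps)
    close_frac   -- a compartment closes when V falls to close_frac * v0
    sample_every -- trace decimation (1 = record every step)
    """

    dt: float = 1e-3
    beta: float = 320.0
    c0: float = 5e-4
    v0: float = 0.025
    r_central: float = 1.5
    exp_factor: float = 2.4
    n_ds_slices: int = 10
    gas_every: int = 10
    close_frac: float = 0.01
    sample_every: int = 1

    @property
    def v_close(self) -> float:
        return self.close_frac * self.v0


@dataclasses.dataclass
class CompartmentParams:
    """Parameters of one alveolar compartment."""

    p_ext: float   # extrinsic pressure offset, cmH2O
    k_stiff: float  # dimensionless stiffness
    top: float     # threshold opening pressure, cmH2O
    r_b: float     # bronchiolar inlet resistance, cmH2O/(L/s)

    def validate(self) -> None:
        if not PEXT_RANGE[0] <= self.p_ext <= PEXT_RANGE[1]:
            raise ValueError(f"P_ext {self.p_ext} outside {PEXT_RANGE}")
        if not KSTIFF_RANGE[0] <= self.k_stiff <= KSTIFF_RANGE[1]:
            raise ValueError(f"k_stiff {self.k_stiff} outside {KSTIFF_RANGE}")
        if not TOP_RANGE[0] <= self.top <= TOP_RANGE[1]:
            raise ValueError(f"TOP {self.top} outside {TOP_RANGE}")
        if self.r_b <= 0:
            raise ValueError("R_b must be positive")


@dataclasses.dataclass
class CompartmentState:
    """Instantaneous state of one compartment."""

    volume: float          # gas volume, L
    is_open: bool
    p_alv: float           # alveolar pressure, cmH2O
    f_o2: float            # dry-gas O2 fraction
    f_co2: float           # dry-gas CO2 fraction

    @property
    def f_balance(self) -> float:
        """Implicit N2 (+ trace gas) fraction."""
        return max(0.0, 1.0 - self.f_o2 - self.f_co2)


@dataclasses.dataclass
class VirtualPatient:
    """A virtual ARDS patient: 100 compartments plus whole-body parameters."""

    p_ext: np.ndarray      # (100,) cmH2O
    k_stiff: np.ndarray    # (100,)
    top: np.ndarray        # (100,) cmH2O
    r_b: np.ndarray        # (100,) cmH2O/(L/s)
    rq: float = 0.8        # respiratory quotient
    vo2: float = 250.0     # O2 consumption, mL/min
    hb: float = 130.0      # haemoglobin, g/L
    shunt_anat: float = 1.5  # anatomical shunt, percent of cardiac output
    vd: float = 110.0      # anatomical dead space, mL
    body_mass: float = 70.0       # predicted body weight, kg
    cardiac_output: float = 5.0   # L/min

    def __post_init__(self):
        for name in ("p_ext", "k_stiff", "top", "r_b"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_COMPARTMENTS,):
                raise ValueError(
                    f"{name} must have exactly {N_COMPARTMENTS} entries"
                )
            setattr(self, name, arr)

    @property
    def top_mean(self) -> float:
        return float(np.mean(self.top))

    def validate(self) -> None:
        """Check all parameters against the calibration bounds."""
        checks = [
            (self.p_ext, PEXT_RANGE, "P_ext"),
            (self.k_stiff, KSTIFF_RANGE, "k_stiff"),
            (self.top, TOP_RANGE, "TOP"),
        ]
        for arr, (lo, hi), name in checks:
            if np.any(arr < lo - 1e-9) or np.any(arr > hi + 1e-9):
                raise ValueError(f"{name} outside [{lo}, {hi}]")
        if np.any(self.r_b <= 0):
            raise ValueError("R_b must be positive")
        scalars = [
            (self.rq, RQ_RANGE, "RQ"),
            (self.vo2, VO2_RANGE, "VO2"),
            (self.hb, HB_RANGE, "Hb"),
            (self.shunt_anat, SHUNT_RANGE, "Shunt_anat"),
            (self.vd, VD_RANGE, "VD"),
        ]
        for v, (lo, hi), name in scalars:
            if not lo - 1e-9 <= v <= hi + 1e-9:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def healthy_reference(cls, r_b: float = 760.0) -> "VirtualPatient":
        """70-kg reference patient: FRC 2.5 L, compliance 50 mL/cmH2O."""
        n = N_COMPARTMENTS
        return cls(
            p_ext=np.zeros(n),
            k_stiff=np.zeros(n),
            top=np.full(n, 5.0),
            r_b=np.full(n, r_b),
        )


@dataclasses.dataclass
class LungState:
    """Snapshot of the whole-lung state."""

    time: float
    compartments: list          # list[CompartmentState]
    ds_f_o2: np.ndarray         # dead-space slice O2 fractions, mouth first
    ds_f_co2: np.ndarray
    mouth_flow: float           # L/s, inspiratory positive
    p_ao: float                 # airway-opening pressure, cmH2O
    pa_o2: float                # arterial O2 tension, mmHg
    pa_co2: float               # arterial CO2 tension, mmHg
    petco2: float               # end-tidal CO2 tension, mmHg

    @property
    def alveolar_volume(self) -> float:
        return sum(c.volume for c in self.compartments)


def compartment_elastic_pressure(params: CompartmentParams, volume,
                                 config: ModelConfig | None = None):
    """Recoil + extrinsic pressure (cmH2O) of a compartment at ``volume`` (L)."""
    config = config or ModelConfig()
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("compartment volume must be non-negative")
    out = K.elastic_pressure.py_func(
        v, params.p_ext, params.k_stiff, config.beta, config.c0, config.v0
    )
    return float(out) if np.ndim(volume) == 0 else out


def recruitment_update(state: CompartmentState, proximal_pressure: float,
                       params: CompartmentParams,
                       config: ModelConfig | None = None) -> CompartmentState:
    """Apply the recruitment rule to one compartment.

    A closed compartment opens iff the proximal (bronchiolar inlet) pressure
    reaches its threshold opening pressure; an open compartment closes when
    its volume has fallen to the collapse volume.  Idempotent at constant
    pressure.
    """
    config = config or ModelConfig()
    new = dataclasses.replace(state)
    if not state.is_open:
        if proximal_pressure >= params.top:
            new.is_open = True
    else:
        if state.volume <= config.v_close:
            new.is_open = False
    return new


def blood_gas(alv_po2, alv_pco2, perfusion_weights, patient: VirtualPatient,
              shunt_weight: float | None = None, venous=None):
    """Arterial tensions from per-compartment alveolar tensions.

    ``perfusion_weights`` are the fractions of cardiac output reaching each
    exchanging compartment; ``shunt_weight`` is the fraction bypassing gas
    exchange (defaults to 1 - sum(weights)).  Weights + shunt must sum to 1.
    If ``venous`` (CvO2, CvCO2 contents, mL/L) is given, a single mixing pass
    is done; otherwise the mixed-venous composition is solved from the Fick
    steady state VO2 / VCO2 = RQ*VO2.

    Returns (PaO2, PaCO2, (CvO2, CvCO2)).
    """
    if patient.hb <= 0:
        raise ValueError("haemoglobin must be positive")
    w = np.asarray(perfusion_weights, dtype=float)
    po2 = np.broadcast_to(np.asarray(alv_po2, dtype=float), w.shape)
    pco2 = np.broadcast_to(np.asarray(alv_pco2, dtype=float), w.shape)
    if shunt_weight is None:
        shunt_weight = 1.0 - w.sum()
    if abs(w.sum() + shunt_weight - 1.0) > 1e-6:
        raise ValueError("perfusion weights plus shunt must sum to 1")
    cc_o2 = np.array([K.o2_blood_content(p, patient.hb) for p in po2])
    cc_co2 = np.array([K.co2_blood_content(p) for p in pco2])
    q = patient.cardiac_output  # L/min
    vco2 = patient.rq * patient.vo2

    def mix(cv_o2, cv_co2):
        ca_o2 = float(w @ cc_o2 + shunt_weight * cv_o2)
        ca_co2 = float(w @ cc_co2 + shunt_weight * cv_co2)
        return ca_o2, ca_co2

    if venous is not None:
        cv_o2, cv_co2 = venous
        ca_o2, ca_co2 = mix(cv_o2, cv_co2)
    else:
        cv_o2 = K.o2_blood_content(40.0, patient.hb)
        cv_co2 = K.co2_blood_content(46.0)
        for _ in range(200):
            ca_o2, ca_co2 = mix(cv_o2, cv_co2)
            new_cv_o2 = max(0.0, ca_o2 - patient.vo2 / q)
            new_cv_co2 = max(0.0, ca_co2 + vco2 / q)
            if abs(new_cv_o2 - cv_o2) < 1e-8 and abs(new_cv_co2 - cv_co2) < 1e-8:
                cv_o2, cv_co2 = new_cv_o2, new_cv_co2
                break
            cv_o2, cv_co2 = new_cv_o2, new_cv_co2
        ca_o2, ca_co2 = mix(cv_o2, cv_co2)
    pa_o2 = K.o2_tension_from_content(ca_o2, patient.hb)
    pa_co2 = K.co2_tension_from_content(ca_co2)
    return pa_o2, pa_co2, (cv_o2, cv_co2)


class LungSimulator:
    """Stateful time-stepping simulator for one VirtualPatient."""

    def __init__(self, patient: VirtualPatient,
                 config: ModelConfig | None = None):
        self.patient = patient
        self.config = config or ModelConfig()
        self._check_stability()
        self.reset()

    def _check_stability(self):
        # the volume update is semi-implicit and tolerates stiff
        # compartments; the binding constraint is the explicit relaxation
        # at the resting-volume compliance (and dead-space advection)
        cfg = self.config
        p = self.patient
        tau_min = float(np.min(p.r_b * cfg.c0 * np.exp(-p.k_stiff)))
        if cfg.dt > 0.5 * tau_min:
            raise ValueError(
                f"dt={cfg.dt} s unstable: must be <= {0.5 * tau_min:.2e} s "
                f"(half the smallest compartment time constant)"
            )

    # ------------------------------------------------------------------ state
    def reset(self, pressure: float = 0.0, fio2: float = 0.21,
              force_open: bool = False):
        """Initialise to mechanical equilibrium at an airway pressure.

        Compartments start at the volume where their recoil balances
        ``pressure``; a compartment starts open iff its TOP has been reached
        (or unconditionally with ``force_open``).
        """
        cfg = self.config
        p = self.patient
        n = N_COMPARTMENTS
        self.time = 0.0
        self.fio2 = float(fio2)
        self.V = np.empty(n)
        for i in range(n):
            self.V[i] = K.equilibrium_volume(
                pressure, p.p_ext[i], p.k_stiff[i], cfg.beta, cfg.c0, cfg.v0,
                2.0 * cfg.v_close,
            )
        self.is_open = np.where(
            force_open | (p.top <= pressure), 1, 0
        ).astype(np.int8)
        # start with alveolar-ish gas so the transient is short
        f_o2 = max(0.05, fio2 - 0.06)
        f_co2 = 40.0 / K.PB_DRY
        self.vo2 = self.V * f_o2
        self.vco2 = self.V * f_co2
        self.q_comp = np.zeros(n)
        self.q_mouth = 0.0
        nds = cfg.n_ds_slices
        self.ds_o2 = np.full(nds, fio2)
        self.ds_co2 = np.zeros(nds)
        # venous starting point: normal-ish mixed venous blood
        self.cv_o2 = K.o2_blood_content(40.0, p.hb)
        self.cv_co2 = K.co2_blood_content(46.0)
        self.pa_o2 = np.nan
        self.pa_co2 = np.nan
        self.petco2 = np.nan

    def clone_state(self):
        """Snapshot of mutable state, restorable with restore_state."""
        return (
            self.time, self.fio2, self.V.copy(), self.is_open.copy(),
            self.vo2.copy(), self.vco2.copy(), self.q_comp.copy(),
            self.q_mouth, self.ds_o2.copy(), self.ds_co2.copy(),
            self.cv_o2, self.cv_co2, self.pa_o2, self.pa_co2, self.petco2,
        )

    def restore_state(self, snap):
        (self.time, self.fio2, V, is_open, vo2, vco2, q_comp, self.q_mouth,
         ds_o2, ds_co2, self.cv_o2, self.cv_co2,
         self.pa_o2, self.pa_co2, self.petco2) = snap
        self.V = V.copy()
        self.is_open = is_open.copy()
        self.vo2 = vo2.copy()
        self.vco2 = vco2.copy()
        self.q_comp = q_comp.copy()
        self.ds_o2 = ds_o2.copy()
        self.ds_co2 = ds_co2.copy()

    @property
    def total_alveolar_volume(self) -> float:
        return float(self.V.sum())

    def state(self) -> LungState:
        cfg = self.config
        p = self.patient
        comps = []
        for i in range(N_COMPARTMENTS):
            palv = K.elastic_pressure(
                self.V[i], p.p_ext[i], p.k_stiff[i], cfg.beta, cfg.c0, cfg.v0
            )
            comps.append(CompartmentState(
                volume=float(self.V[i]),
                is_open=bool(self.is_open[i]),
                p_alv=float(palv),
                f_o2=float(self.vo2[i] / self.V[i]),
                f_co2=float(self.vco2[i] / self.V[i]),
            ))
        return LungState(
            time=self.time, compartments=comps,
            ds_f_o2=self.ds_o2.copy(), ds_f_co2=self.ds_co2.copy(),
            mouth_flow=self.q_mouth, p_ao=np.nan,
            pa_o2=self.pa_o2, pa_co2=self.pa_co2, petco2=self.petco2,
        )

    # ------------------------------------------------------------- stepping
    def run_segment(self, mode: np.ndarray, val: np.ndarray,
                    meas: np.ndarray | None = None):
        """Advance by one boundary-condition segment (one ventilator cycle).

        Returns (paw, plung, flow, vol) trace arrays sampled every
        ``config.sample_every`` steps, and the measurement accumulator.
        """
        cfg = self.config
        p = self.patient
        n_steps = len(mode)
        if meas is None:
            meas = np.empty(K.N_MEAS)
            K.init_meas(meas)
        nbuf = n_steps // cfg.sample_every + 1
        tr = [np.empty(nbuf) for _ in range(4)]
        q_perf = p.cardiac_output / 60.0 * (1.0 - p.shunt_anat / 100.0) \
            / N_COMPARTMENTS
        self.q_mouth, n_written = K.advance(
            self.V, self.vo2, self.vco2, self.is_open, self.q_comp,
            self.ds_o2, self.ds_co2, p.vd / 1000.0 / cfg.n_ds_slices,
            p.p_ext, p.k_stiff, p.top, p.r_b,
            mode, val,
            cfg.dt, cfg.beta, cfg.c0, cfg.v0, cfg.v_close,
            cfg.r_central, cfg.exp_factor,
            self.fio2, p.hb, self.cv_o2, self.cv_co2, q_perf, cfg.gas_every,
            self.q_mouth,
            tr[0], tr[1], tr[2], tr[3], cfg.sample_every,
            meas,
        )
        self.time += n_steps * cfg.dt
        return tuple(t[:n_written] for t in tr), meas

    def step(self, boundary: tuple[str, float], dt: float | None = None):
        """Advance a single step; ``boundary`` is ('pressure', cmH2O) or
        ('flow', L/s)."""
        cfg = self.config
        dt = cfg.dt if dt is None else dt
        if dt <= 0:
            raise ValueError("dt must be positive")
        if dt > cfg.dt:
            old = cfg.dt
            try:
                cfg.dt = dt
                self._check_stability()
            finally:
                cfg.dt = old
        kind, value = boundary
        mode = np.array([0 if kind == "pressure" else 1], dtype=np.int8)
        val = np.array([float(value)])
        old_dt = cfg.dt
        cfg.dt = dt
        try:
            (paw, plung, flow, vol), meas = self.run_segment(mode, val)
        finally:
            cfg.dt = old_dt
        return {"paw": paw[0], "plung": plung[0], "flow": flow[0],
                "volume": vol[0]}

    def update_venous(self, meas: np.ndarray, duration: float,
                      relax: float = 0.6):
        """Relax the mixed-venous composition toward its Fick steady state
        using the perfusion-weighted end-capillary contents accumulated over
        the last ``duration`` seconds, and refresh arterial tensions."""
        p = self.patient
        qb = p.cardiac_output / 60.0  # L/s
        total = qb * duration
        open_q = meas[K.M_ACC_Q]
        shunted = max(0.0, total - open_q)
        ca_o2 = (meas[K.M_ACC_O2] + shunted * self.cv_o2) / total
        ca_co2 = (meas[K.M_ACC_CO2] + shunted * self.cv_co2) / total
        vco2 = p.rq * p.vo2
        cv_o2_t = max(0.0, ca_o2 - p.vo2 / p.cardiac_output)
        cv_co2_t = ca_co2 + vco2 / p.cardiac_output
        self.cv_o2 += relax * (cv_o2_t - self.cv_o2)
        self.cv_co2 += relax * (cv_co2_t - self.cv_co2)
        self.pa_o2 = K.o2_tension_from_content(ca_o2, p.hb)
        self.pa_co2 = K.co2_tension_from_content(ca_co2)
        if np.isfinite(meas[K.M_PETCO2]):
            self.petco2 = float(meas[K.M_PETCO2])

    def equilibrate(self, pressure: float, duration: float = 10.0):
        """Hold a constant airway pressure until mechanics settle; returns
        the end-expiratory (equilibrium) alveolar volume in L."""
        cfg = self.config
        n = int(round(duration / cfg.dt))
        mode = np.zeros(n, dtype=np.int8)
        val = np.full(n, float(pressure))
        self.run_segment(mode, val)
        return self.total_alveolar_volume


def healthy_frc(config: ModelConfig | None = None) -> float:
    """FRC (L) of the healthy reference patient at zero airway pressure."""
    sim = LungSimulator(VirtualPatient.healthy_reference(), config)
    sim.reset(pressure=0.0, force_open=True)
    return sim.equilibrate(0.0, duration=5.0)
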