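"""Calibration of virtual patients to bedside data with a genetic algorithm.

The fit minimises

    J = sqrt( sum_i ((Yhat_i - Y_i) / Y_i)^2 ),  i = 1..7,

over the data vector Y = [PaO2, PaCO2, Pe'CO2, PIP, P_plat, TOP_mean,
V_frc], where the model outputs Yhat are read from a simulated baseline
constant-flow VCV run at the patient's fixed ventilator settings (VT, FiO2,
PEEP, and RR/DC when recorded; otherwise RR and DC join the optimisation).
TOP_mean is targeted at 30 cmH2O, the population-average alveolar threshold
opening pressure.

Two parameterizations of the search space are available:

* ``mode="full"``: the three compartment features (P_ext, k_stiff, TOP) as
  100 free genes each plus the five whole-body scalars (RQ, VO2, Hb,
  Shunt_anat, VD) -- 305 genes, matching the full parameter table;
* ``mode="reduced"``: the compartment features are generated from
  low-dimensional distributions (mean/spread for P_ext and k_stiff, a
  lognormal-plus-high-mode mixture for TOP, a bronchiolar-resistance scale)
  whose 9 parameters are optimised together with the 5 scalars.  The cohort
  pipeline uses this mode: it converges orders of magnitude faster and the
  acceptance surface is J, not the (non-identifiable) per-compartment
  parameters.

The optimiser is a real-coded GA (tournament selection, blend crossover,
per-gene Gaussian mutation clipped to bounds, elitism), optionally followed
by a Nelder-Mead polish of the best individual in reduced mode.  The search
is fully deterministic given the seed; compartment realisations use fixed
quantile patterns, so the cost is invariant under permutation of
compartment indices.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize, stats

from . import model_core as mc
from .model_core import ModelConfig, VirtualPatient
from .ventilation import MeasurementSet, VCVSettings, extract_measurements, run_vcv

N = mc.N_COMPARTMENTS

# fixed standard-normal quantile patterns; one permutation per compartment
# feature so features are not comonotone across compartments
_Z_BASE = stats.norm.ppf((np.arange(N) + 0.5) / N)
_PATTERNS = {}
for _name, _seed in (("p_ext", 11), ("k_stiff", 12), ("top", 13),
                     ("top_hi", 14), ("r_b", 15)):
    _PATTERNS[_name] = _Z_BASE[np.random.default_rng(_seed).permutation(N)]

R_B_MEDIAN = 880.0   # cmH2O/(L/s); bronchiolar resistance scale
R_B_SIGMA = 0.85     # lognormal spread of bronchiolar resistances


@dataclasses.dataclass
class PatientTargets:
    """Calibration data vector Y plus the fixed ventilator settings."""

    pao2: float       # mmHg
    paco2: float      # mmHg
    peco2: float      # end-tidal CO2, mmHg
    pip: float        # cmH2O
    pplat: float      # cmH2O
    top_mean: float   # cmH2O (30 by construction)
    vfrc: float       # mL
    vt: float         # L
    fio2: float
    peep: float       # cmH2O
    rr: float | None = None   # breaths/min; optimised when None
    dc: float | None = None   # optimised when None
    patient_id: str = ""
    severity: str = ""
    pf: float = np.nan        # PaO2/FiO2, mmHg (bookkeeping)

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.pao2, self.paco2, self.peco2, self.pip,
                         self.pplat, self.top_mean, self.vfrc])

    def validate(self) -> None:
        if np.any(self.vector <= 0):
            raise ValueError("all calibration targets must be positive "
                             "(the cost divides by them)")
        if self.vt <= 0 or not 0 < self.fio2 <= 1 or self.peep < 0:
            raise ValueError("invalid ventilator settings")


@dataclasses.dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters."""

    population: int = 50
    generations: int = 100
    tournament: int = 3
    cx_prob: float = 0.7
    cx_alpha: float = 0.3
    mut_prob: float = 0.15
    mut_sigma: float = 0.10     # fraction of each gene's range
    elitism: int = 1
    mode: str = "full"          # "full" | "reduced"
    polish: bool = True         # Nelder-Mead refinement (reduced mode only)
    polish_maxiter: int = 150
    j_stop: float = 0.02        # early stop once J falls below this
    retry: bool = True          # second GA round (best injected) if J poor
    retry_threshold: float = 0.2
    eval_duration: float = 50.0  # simulated seconds cap per cost evaluation
    eval_min_cycles: int = 6


@dataclasses.dataclass
class CalibrationResult:
    patient: VirtualPatient
    j: float
    y_hat: np.ndarray
    converged: bool
    evaluations: int
    genes: np.ndarray
    history: list            # best J per generation (non-increasing)
    baseline: MeasurementSet | None = None
    mode: str = "reduced"


def cost(y_hat, y) -> float:
    """Root-sum-of-squares of component-wise relative errors."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != (7,) or y_hat.shape != (7,):
        raise ValueError("cost expects 7-component vectors")
    if np.any(y <= 0):
        raise ValueError("all data components must be positive")
    rel = (y_hat - y) / y
    return float(np.sqrt(np.sum(rel * rel)))


# --------------------------------------------------------------- genotypes
REDUCED_BOUNDS = [
    ("p_ext_mean", -20.0, 25.0),
    ("p_ext_spread", 0.0, 15.0),
    ("k_mean", -1.5, 0.9),
    ("k_spread", 0.15, 0.8),
    ("ln_top_med", np.log(2.0), np.log(60.0)),
    ("top_sigma", 0.05, 1.6),
    ("f_hi", 0.0, 0.6),
    ("top_hi", 40.0, 100.0),
    ("r_scale", 0.7, 1.4),
    ("rq", *mc.RQ_RANGE),
    ("vo2", *mc.VO2_RANGE),
    ("hb", *mc.HB_RANGE),
    ("shunt", *mc.SHUNT_RANGE),
    ("vd", *mc.VD_RANGE),
]
_RRDC_BOUNDS = [("rr", 10.0, 35.0), ("dc", 0.25, 0.5)]


def reduced_bounds(optimise_rrdc: bool = False) -> np.ndarray:
    b = REDUCED_BOUNDS + (_RRDC_BOUNDS if optimise_rrdc else [])
    return np.array([[lo, hi] for _, lo, hi in b])


def full_bounds(optimise_rrdc: bool = False) -> np.ndarray:
    b = ([mc.PEXT_RANGE] * N + [mc.KSTIFF_RANGE] * N + [mc.TOP_RANGE] * N
         + [mc.RQ_RANGE, mc.VO2_RANGE, mc.HB_RANGE, mc.SHUNT_RANGE,
            mc.VD_RANGE])
    if optimise_rrdc:
        b += [(10.0, 35.0), (0.25, 0.5)]
    return np.array(b, dtype=float)


def build_patient_reduced(genes) -> VirtualPatient:
    """Realise the 100 compartments from the 14 reduced-mode genes."""
    g = np.asarray(genes, dtype=float)
    (pm, ps, km, ks, ltm, ts, f_hi, top_hi, r_scale,
     rq, vo2, hb, shunt, vd) = g[:14]
    p_ext = np.clip(pm + ps * _PATTERNS["p_ext"], *mc.PEXT_RANGE)
    k = np.clip(km + ks * _PATTERNS["k_stiff"], *mc.KSTIFF_RANGE)
    top = 5.0 + np.clip(np.exp(ltm + ts * _PATTERNS["top"]), 0.0, 95.0)
    n_hi = int(round(f_hi * N))
    if n_hi > 0:
        hi_idx = np.argsort(_PATTERNS["top_hi"])[-n_hi:]
        top = top.copy()
        top[hi_idx] = top_hi
    top = np.clip(top, *mc.TOP_RANGE)
    r_b = R_B_MEDIAN * r_scale * np.exp(R_B_SIGMA * _PATTERNS["r_b"])
    return VirtualPatient(p_ext=p_ext, k_stiff=k, top=top, r_b=r_b,
                          rq=rq, vo2=vo2, hb=hb, shunt_anat=shunt, vd=vd)


def build_patient_full(genes) -> VirtualPatient:
    g = np.asarray(genes, dtype=float)
    return VirtualPatient(
        p_ext=np.clip(g[:N], *mc.PEXT_RANGE),
        k_stiff=np.clip(g[N:2 * N], *mc.KSTIFF_RANGE),
        top=np.clip(g[2 * N:3 * N], *mc.TOP_RANGE),
        r_b=R_B_MEDIAN * np.exp(R_B_SIGMA * _PATTERNS["r_b"]),
        rq=g[3 * N], vo2=g[3 * N + 1], hb=g[3 * N + 2],
        shunt_anat=g[3 * N + 3], vd=g[3 * N + 4],
    )


def build_patient(genes, mode: str) -> VirtualPatient:
    if mode == "reduced":
        return build_patient_reduced(genes)
    if mode == "full":
        return build_patient_full(genes)
    raise ValueError(f"unknown mode {mode!r}")


# ------------------------------------------------------------- evaluation
def simulate_outputs(patient: VirtualPatient, targets: PatientTargets,
                     model_config: ModelConfig | None = None,
                     rr: float | None = None, dc: float | None = None,
                     duration: float = 90.0, min_cycles: int = 6):
    """Model outputs Yhat under the patient's baseline VCV settings.

    Returns (y_hat, baseline MeasurementSet, trace).
    """
    rr = rr if rr is not None else targets.rr
    dc = dc if dc is not None else targets.dc
    if rr is None or dc is None:
        raise ValueError("RR and DC must be supplied (targets or genes)")
    settings = VCVSettings(vt=targets.vt, peep=targets.peep, rr=rr, dc=dc,
                           fio2=targets.fio2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trace = run_vcv(patient, settings, duration=duration,
                        config=model_config, min_cycles=min_cycles)
    ms = extract_measurements(trace)
    y_hat = np.array([
        trace.pa_o2, trace.pa_co2, trace.petco2,
        ms.p_peak, ms.p_plat, patient.top_mean, ms.v_frc,
    ])
    return y_hat, ms, trace


def _make_objective(targets, mode, model_config, bounds, optimise_rrdc,
                    ga: GAConfig):
    y = targets.vector
    counter = {"n": 0}

    def objective(genes):
        counter["n"] += 1
        g = np.clip(genes, bounds[:, 0], bounds[:, 1])
        rr = g[-2] if optimise_rrdc else None
        dc = g[-1] if optimise_rrdc else None
        core = g[:-2] if optimise_rrdc else g
        try:
            patient = build_patient(core, mode)
            y_hat, ms, trace = simulate_outputs(
                patient, targets, model_config, rr=rr, dc=dc,
                duration=ga.eval_duration, min_cycles=ga.eval_min_cycles)
        except (ValueError, FloatingPointError):
            return 1e3, None
        if not np.all(np.isfinite(y_hat)):
            return 1e3, None
        return cost(y_hat, y), (patient, y_hat, ms)

    return objective, counter


# archetype starting points spanning the ARDS severity spectrum; injecting
# them into the initial population speeds convergence without constraining
# the search (they compete like any other individual)
_ARCHETYPES = np.array([
    # pm,  ps,  km,  ks,  ln_top_med,   ts, f_hi, t_hi, r_s,  rq, vo2,  hb, sh, vd
    [15.0, 5.0, 0.6, 0.45, np.log(16.0), 0.5, 0.35, 77.0, 1.0, 0.8, 230.0, 120.0, 1.5, 110.0],
    [11.0, 5.0, 0.4, 0.45, np.log(12.0), 0.85, 0.20, 77.0, 1.0, 0.8, 230.0, 120.0, 1.5, 110.0],
    [7.0, 4.0, 0.2, 0.45, np.log(8.0), 1.2, 0.12, 90.0, 1.0, 0.8, 230.0, 120.0, 1.5, 110.0],
])


def _ga_round(objective, bounds, ga: GAConfig, rng, history,
              init_best=None):
    """One GA round; returns the best (J, genes, payload) triple found."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    pop = lo + rng.random((ga.population, len(lo))) * span
    if len(lo) >= 14 and ga.mode == "reduced":
        for a_i, arch in enumerate(_ARCHETYPES):
            row = 1 + a_i
            if row < ga.population:
                pop[row, :14] = arch
                pop[row] = np.clip(pop[row], lo, hi)
    if init_best is not None:
        pop[0] = init_best
    fits = np.empty(ga.population)
    payloads: list = [None] * ga.population
    for i in range(ga.population):
        fits[i], payloads[i] = objective(pop[i])

    best_idx = int(np.argmin(fits))
    best = (fits[best_idx], pop[best_idx].copy(), payloads[best_idx])
    history.append(best[0])

    for _gen in range(ga.generations):
        if best[0] <= ga.j_stop:
            break
        new_pop = np.empty_like(pop)
        # elitism
        elite_n = min(ga.elitism, ga.population)
        elite_idx = np.argsort(fits)[:elite_n]
        new_pop[:elite_n] = pop[elite_idx]
        elite_fits = fits[elite_idx].copy()
        elite_payloads = [payloads[i] for i in elite_idx]
        # offspring
        for i in range(elite_n, ga.population):
            # tournament selection of two parents
            cand = rng.integers(0, ga.population, ga.tournament)
            p1 = pop[cand[np.argmin(fits[cand])]]
            cand = rng.integers(0, ga.population, ga.tournament)
            p2 = pop[cand[np.argmin(fits[cand])]]
            if rng.random() < ga.cx_prob:
                # BLX-alpha blend crossover
                cmin = np.minimum(p1, p2)
                cmax = np.maximum(p1, p2)
                d = cmax - cmin
                child = (cmin - ga.cx_alpha * d
                         + rng.random(len(lo)) * (1 + 2 * ga.cx_alpha) * d)
            else:
                child = p1.copy()
            mut = rng.random(len(lo)) < ga.mut_prob
            child = np.where(
                mut, child + rng.normal(0.0, ga.mut_sigma, len(lo)) * span,
                child)
            new_pop[i] = np.clip(child, lo, hi)
        pop = new_pop
        for i in range(ga.population):
            if i < elite_n:
                fits[i] = elite_fits[i]
                payloads[i] = elite_payloads[i]
            else:
                fits[i], payloads[i] = objective(pop[i])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best[0]:
            best = (fits[gen_best], pop[gen_best].copy(), payloads[gen_best])
        history.append(best[0])
    return best


def _polish(objective, bounds, ga: GAConfig, best, history):
    lo, hi = bounds[:, 0], bounds[:, 1]

    def scalar_obj(g):
        return objective(g)[0]

    res = optimize.minimize(
        scalar_obj, best[1], method="Nelder-Mead",
        options={"maxiter": ga.polish_maxiter, "xatol": 1e-3,
                 "fatol": 1e-4},
    )
    j_p, payload_p = objective(res.x)
    if j_p < best[0] and payload_p is not None:
        best = (j_p, np.clip(res.x, lo, hi), payload_p)
    history.append(best[0])
    return best


def calibrate(targets: PatientTargets, ga_config: GAConfig | None = None,
              seed: int = 0,
              model_config: ModelConfig | None = None) -> CalibrationResult:
    """Fit a VirtualPatient to a targets record by GA (+ optional polish).

    Deterministic given (targets, config, seed).  When the first GA round
    plus polish leaves J above ``retry_threshold`` a second round is run
    with the incumbent injected into a fresh population.  If no individual
    reaches J <= 0.5 the result is flagged non-converged; it is still
    returned with its diagnostics rather than raising.
    """
    targets.validate()
    ga = ga_config or GAConfig()
    optimise_rrdc = targets.rr is None or targets.dc is None
    bounds = (reduced_bounds(optimise_rrdc) if ga.mode == "reduced"
              else full_bounds(optimise_rrdc))
    rng = np.random.default_rng(seed)
    objective, counter = _make_objective(
        targets, ga.mode, model_config, bounds, optimise_rrdc, ga)
    history: list = []

    best = _ga_round(objective, bounds, ga, rng, history)
    if ga.polish and ga.mode == "reduced" and best[0] > ga.j_stop:
        best = _polish(objective, bounds, ga, best, history)
    if ga.retry and best[0] > ga.retry_threshold:
        retry = _ga_round(objective, bounds, ga, rng, history,
                          init_best=best[1])
        if retry[0] < best[0]:
            best = retry
        if ga.polish and ga.mode == "reduced" and best[0] > ga.j_stop:
            best = _polish(objective, bounds, ga, best, history)

    j, genes, payload = best
    if payload is None:  # every candidate failed to simulate
        patient = build_patient(
            genes[:-2] if optimise_rrdc else genes, ga.mode)
        y_hat = np.full(7, np.nan)
        ms = None
    else:
        patient, y_hat, ms = payload
    return CalibrationResult(
        patient=patient, j=float(j), y_hat=y_hat,
        converged=bool(j <= 0.5 and payload is not None),
        evaluations=counter["n"], genes=genes,
        history=history, baseline=ms, mode=ga.mode,
    )
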