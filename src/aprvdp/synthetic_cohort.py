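"""Synthetic ARDS cohort generator.

The original study calibrated its simulator to 90 adult ARDS patients (26%
severe, 61% moderate, 13% mild by Berlin P/F bands) from the low tidal
volume arm of the ARMA trial; those records are not public.  This module
generates target records with the same structure and severity mixture so
the whole pipeline runs without external data.  The records are explicitly
synthetic: severity counts follow the published mixture via largest-
remainder rounding, P/F ratios are drawn uniformly within the Berlin band,
blood gases from physiologic ranges, and the airway-pressure/FRC targets
(PIP, P_plat, V_frc) are produced by simulating a provisional mechanics
patient of the matching severity and perturbing the result by up to +/-5%,
which guarantees every record is reachable by the model family.

Ventilator settings mirror ARMA's low-VT arm: VT = 6 mL/kg of 70 kg
predicted body weight, PEEP stepped with FiO2, and a TOP_mean target of
30 cmH2O for every patient.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from .calibration import PatientTargets, build_patient_reduced, simulate_outputs
from .model_core import ModelConfig

SEVERITIES = ("severe", "moderate", "mild")
VT_PER_KG = 6.0        # mL/kg predicted body weight (ARMA low-VT arm)
BODY_MASS = 70.0       # kg
TOP_MEAN_TARGET = 30.0  # cmH2O


@dataclasses.dataclass
class CohortSpec:
    """Specification of a synthetic cohort."""

    n_patients: int = 90
    fractions: tuple = (0.26, 0.61, 0.13)   # severe, moderate, mild
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("severity fractions must sum to 1")


def largest_remainder_counts(n: int, fractions) -> list[int]:
    """Integer severity counts summing to n (largest-remainder method)."""
    raw = [n * f for f in fractions]
    counts = [math.floor(r) for r in raw]
    short = n - sum(counts)
    remainders = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i],
                        reverse=True)
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def classify_pf(pf: float) -> str:
    """Berlin severity band from the P/F ratio (mmHg)."""
    if pf <= 100:
        return "severe"
    if pf <= 200:
        return "moderate"
    return "mild"


def peep_for_fio2(fio2: float) -> float:
    """ARMA-style FiO2/PEEP ladder (lower-PEEP table)."""
    for f_max, peep in ((0.4, 5.0), (0.5, 8.0), (0.6, 10.0), (0.7, 12.0),
                        (0.8, 12.0), (0.9, 14.0)):
        if fio2 <= f_max:
            return peep
    return 16.0


# per-severity sampling distributions for the provisional mechanics genes;
# these emulate the clinical picture (small, stiff, poorly recruitable lungs
# in severe disease) and are not the ARMA data
_SEV_PARAMS = {
    "severe": dict(pf=(65.0, 100.0), fio2=(0.70, 1.00),
                   p_ext=(15.0, 2.5), k=(0.60, 0.15),
                   top_sigma=(0.30, 0.70), f_hi=(0.25, 0.45)),
    "moderate": dict(pf=(105.0, 195.0), fio2=(0.45, 0.75),
                     p_ext=(11.0, 2.5), k=(0.40, 0.15),
                     top_sigma=(0.60, 1.10), f_hi=(0.12, 0.30)),
    "mild": dict(pf=(205.0, 290.0), fio2=(0.35, 0.55),
                 p_ext=(7.0, 2.0), k=(0.20, 0.15),
                 top_sigma=(1.00, 1.50), f_hi=(0.02, 0.15)),
}


def _sample_genes(sev: str, rng: np.random.Generator) -> np.ndarray:
    p = _SEV_PARAMS[sev]
    top_sigma = rng.uniform(*p["top_sigma"])
    f_hi = rng.uniform(*p["f_hi"])
    top_hi = rng.uniform(60.0, 95.0)
    # log-median of the low-TOP group keeping the mixture mean near 30 cmH2O
    low_mean_target = max(7.0, (TOP_MEAN_TARGET - f_hi * top_hi)
                          / max(1e-6, 1.0 - f_hi))
    ln_top_med = np.log(low_mean_target - 5.0) - 0.5 * top_sigma ** 2
    ln_top_med = float(np.clip(ln_top_med, np.log(2.0), np.log(60.0)))
    genes = np.array([
        np.clip(rng.normal(*p["p_ext"]), -5.0, 22.0),   # p_ext_mean
        rng.uniform(3.0, 7.0),                          # p_ext_spread
        np.clip(rng.normal(*p["k"]), -1.0, 0.9),        # k_mean
        rng.uniform(0.3, 0.6),                          # k_spread
        ln_top_med,
        top_sigma,
        f_hi,
        top_hi,
        float(np.exp(rng.normal(0.0, 0.15))),           # r_scale
        rng.uniform(0.7, 0.9),                          # RQ
        np.clip(rng.normal(230.0, 30.0), 150.0, 300.0),  # VO2
        np.clip(rng.normal(120.0, 15.0), 90.0, 160.0),  # Hb
        rng.uniform(1.0, 2.0),                          # anatomical shunt %
        rng.uniform(80.0, 140.0),                       # VD mL
    ])
    return genes


def generate_cohort(spec: CohortSpec,
                    model_config: ModelConfig | None = None
                    ) -> list[PatientTargets]:
    """Generate the synthetic cohort target records.

    Deterministic given ``spec.seed``.  Severity is assigned by the sampled
    P/F ratio, which lands in the intended Berlin band by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = largest_remainder_counts(spec.n_patients, spec.fractions)
    sev_list = [s for s, c in zip(SEVERITIES, counts) for _ in range(c)]
    rng.shuffle(sev_list)

    records = []
    for idx, sev in enumerate(sev_list):
        p = _SEV_PARAMS[sev]
        pf = rng.uniform(*p["pf"])
        fio2 = round(rng.uniform(*p["fio2"]), 2)
        pao2 = pf * fio2
        paco2 = float(np.clip(rng.normal(42.0, 4.0), 35.0, 52.0))
        peco2 = paco2 - rng.uniform(3.0, 7.0)
        rr = float(np.round(np.clip(rng.normal(14.0, 2.0), 10.0, 20.0)))
        dc = round(rng.uniform(0.30, 0.42), 2)
        vt = VT_PER_KG * BODY_MASS / 1000.0
        peep = peep_for_fio2(fio2)

        genes = _sample_genes(sev, rng)
        provisional = build_patient_reduced(genes)
        targets0 = PatientTargets(
            pao2=pao2, paco2=paco2, peco2=peco2,
            pip=1.0, pplat=1.0, top_mean=TOP_MEAN_TARGET, vfrc=1.0,
            vt=vt, fio2=fio2, peep=peep, rr=rr, dc=dc,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y_hat, _, _ = simulate_outputs(
                provisional, targets0, model_config,
                duration=50.0, min_cycles=5)
        mech_perturb = 1.0 + rng.uniform(-0.05, 0.05)
        frc_perturb = 1.0 + rng.uniform(-0.05, 0.05)
        records.append(PatientTargets(
            pao2=round(pao2, 1), paco2=round(paco2, 1),
            peco2=round(peco2, 1),
            pip=round(float(y_hat[3]) * mech_perturb, 1),
            pplat=round(float(y_hat[4]) * mech_perturb, 1),
            top_mean=TOP_MEAN_TARGET,
            vfrc=round(float(y_hat[6]) * frc_perturb, 0),
            vt=vt, fio2=fio2, peep=peep, rr=rr, dc=dc,
            patient_id=f"P{idx + 1:03d}", severity=sev, pf=round(pf, 1),
        ))
    return records


_CSV_COLUMNS = {
    "PaO2": "pao2", "PaCO2": "paco2", "PeCO2": "peco2", "PIP": "pip",
    "Pplat": "pplat", "TOPmean": "top_mean", "Vfrc": "vfrc", "VT": "vt",
    "FiO2": "fio2", "PEEP": "peep", "RR": "rr", "DC": "dc",
}


def cohort_to_frame(records: list[PatientTargets]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "severity": r.severity,
               "PF": r.pf}
        row.update({col: getattr(r, attr) for col, attr in
                    _CSV_COLUMNS.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientTargets]:
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"targets table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        kwargs = {attr: float(row[col]) for col, attr in _CSV_COLUMNS.items()
                  if not pd.isna(row[col])}
        for opt in ("rr", "dc"):
            if opt not in kwargs:
                kwargs[opt] = None
        records.append(PatientTargets(
            patient_id=str(row.get("patient_id", f"P{i + 1:03d}")),
            severity=str(row.get("severity", "")),
            pf=float(row.get("PF", np.nan)),
            **kwargs,
        ))
    return records
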