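"""Readers and writers for patient parameter files and targets tables.

Patient files are YAML key/value documents carrying the five whole-body
parameters and the 100 compartment quadruples; targets tables are CSV with
the columns PaO2, PaCO2, PeCO2, PIP, Pplat, TOPmean, Vfrc, VT, FiO2, PEEP,
RR, DC (one row per patient).
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from .calibration import PatientTargets
from .model_core import VirtualPatient
from .synthetic_cohort import cohort_to_frame, frame_to_cohort


def save_patient(patient: VirtualPatient, path) -> None:
    doc = {
        "RQ": float(patient.rq),
        "VO2_mL_min": float(patient.vo2),
        "Hb_g_L": float(patient.hb),
        "Shunt_anat_pct": float(patient.shunt_anat),
        "VD_mL": float(patient.vd),
        "body_mass_kg": float(patient.body_mass),
        "cardiac_output_L_min": float(patient.cardiac_output),
        "compartments": {
            "P_ext_cmH2O": [round(float(x), 6) for x in patient.p_ext],
            "k_stiff": [round(float(x), 6) for x in patient.k_stiff],
            "TOP_cmH2O": [round(float(x), 6) for x in patient.top],
            "R_b_cmH2O_s_L": [round(float(x), 6) for x in patient.r_b],
        },
    }
    pathlib.Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_patient(path, validate: bool = True) -> VirtualPatient:
    doc = yaml.safe_load(pathlib.Path(path).read_text())
    comp = doc["compartments"]
    patient = VirtualPatient(
        p_ext=np.asarray(comp["P_ext_cmH2O"], dtype=float),
        k_stiff=np.asarray(comp["k_stiff"], dtype=float),
        top=np.asarray(comp["TOP_cmH2O"], dtype=float),
        r_b=np.asarray(comp["R_b_cmH2O_s_L"], dtype=float),
        rq=float(doc["RQ"]), vo2=float(doc["VO2_mL_min"]),
        hb=float(doc["Hb_g_L"]), shunt_anat=float(doc["Shunt_anat_pct"]),
        vd=float(doc["VD_mL"]),
        body_mass=float(doc.get("body_mass_kg", 70.0)),
        cardiac_output=float(doc.get("cardiac_output_L_min", 5.0)),
    )
    if validate:
        patient.validate()
    return patient


def save_targets(records: list[PatientTargets], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def load_targets(path) -> list[PatientTargets]:
    return frame_to_cohort(pd.read_csv(path))
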