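# aprvdp

In-silico evaluation of bedside formulas for estimating ventilator driving
pressure during airway pressure release ventilation (APRV).

## The problem

APRV ventilates ARDS patients with a long high-pressure phase (`P_high`
for `T_high`, typically 5 s) and brief releases (`P_low` for `T_low`,
typically 0.5 s).  The short release deliberately traps gas, so the lung
pressure at end expiration (`PEEP_tot`) stays far above `P_low` — and the
driving pressure

    ΔP = P_plat − PEEP_tot,

the best-established mediator of ventilator-induced lung injury, cannot be
read from the ventilator.  Clinicians estimate it with simple formulas;
this package quantifies how accurate those formulas are by applying them
to virtual ARDS patients in which the true ΔP is known exactly from the
simulated lung-pressure waveform.

It is aimed at researchers in computational physiology and mechanical
ventilation who want a self-contained, reproducible test bed: a
multi-compartment lung simulator, patient calibration, the estimators, and
the method-comparison statistics, with no external data required.

## What is inside

* **`model_core`** — a mechanistic lung: 100 alveolar compartments with
  sigmoid pressure-volume curves (extrinsic pressure `P_ext`, stiffness
  `k_stiff`), recruitment gated by threshold opening pressures (`TOP`),
  heterogeneous bronchiolar resistances, series dead space, Severinghaus
  O2 / linearised CO2 gas exchange with shunt, and mixed-venous closure by
  the Fick principle.
* **`ventilation`** — APRV and constant-flow VCV drivers, cyclic
  steady-state detection, and extraction of the full bedside measurement
  set (P_plat, P_peak, PEEP_tot, V_released, PEFR, EEFR, V_frc, R_aw, C,
  E, P/F) from waveforms.
* **`calibration`** — a genetic algorithm that fits a virtual patient to a
  record Y = [PaO2, PaCO2, Pe'CO2, PIP, P_plat, TOP_mean, V_frc] by
  minimising J = sqrt(Σ ((Ŷᵢ−Yᵢ)/Yᵢ)²) over the physiological parameter
  ranges.
* **`dp_estimators`** — the true ΔP and three bedside estimates: the
  expiratory-time-constant method (PEEP_i = [½·nτ·PEFR − V_released]·E,
  with n = 4 or 3), the mono-exponential method
  (PEEP_i = (EEFR/PEFR)·P_high), and the temporary-switch-to-VCV method.
* **`synthetic_cohort`** — an ARMA-like synthetic cohort (default 90
  patients, 26/61/13% severe/moderate/mild by Berlin P/F bands).
* **`evaluation_pipeline`** — the full study: calibrate the cohort,
  ventilate at P_high/P_low = 30/5, 30/0 and 25/0 cmH2O, and compare
  estimators by Bland-Altman bias/limits of agreement and Pearson
  correlations.

`docs/methods.md` documents the model equations, parameter choices and
limitations.

## Worked example

Fit-free demo on a moderate-ARDS archetype patient (see
`calibration.build_patient_reduced` for the 14-parameter genome):

```python
import aprvdp as a

patient = a.build_patient_reduced(
    [11.0, 5.0, 0.4, 0.45, 2.48, 0.85, 0.20, 77.0,
     1.0, 0.8, 230.0, 120.0, 1.5, 110.0])

baseline = a.VCVSettings(vt=0.42, peep=10.0, rr=15.0, dc=0.35, fio2=0.6)
trace_vcv = a.run_vcv(patient, baseline, duration=120.0)
ms_vcv = a.extract_measurements(trace_vcv)

aprv = a.APRVSettings(p_high=30, p_low=5, t_high=5.0, t_low=0.5, fio2=0.6)
trace = a.run_aprv(patient, aprv, duration=1800.0)
ms = a.extract_measurements(trace)
report = a.estimate_all(ms, ms_vcv, aprv, patient=patient,
                        sim=trace._sim, rr=15.0, dc=0.35)
```

Formatting the key quantities of those objects prints:

```
baseline VCV: Pplat 39.9 cmH2O, PEEPtot 11.5 cmH2O, C 14.8 mL/cmH2O, PaO2 83 mmHg
APRV 30/5: PEEPtot 15.0 cmH2O, Vreleased 221 mL, PEFR 57 L/min, EEFR 14 L/min
true dP 15.0 | mono 17.6 | 4-tau 5.4 | 3-tau 14.0 | VCV-switch 16.1 cmH2O
```

Reading this: at `P_high/P_low` = 30/5 the release leaves 10 cmH2O of
intrinsic PEEP above `P_low`, so the true driving pressure is 15.0 cmH2O,
not the 25 cmH2O the set pressures suggest.  The mono-exponential formula
overestimates (+2.6), the 4τ variant of the time-constant formula
underestimates heavily (−9.6), its 3τ variant is nearly unbiased (−1.0),
and the VCV switch reads +1.1 high — the pattern the cohort study
quantifies with Bland-Altman statistics.

The same is available from the shell:

```bash
aprvdp cohort --n 90 --seed 1 --out targets.csv
aprvdp report --targets targets.csv --settings 30:5,30:0,25:0 \
              --out results/ --seed 1 --plots
aprvdp estimate --measurements meas.csv --out dp.csv
```

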