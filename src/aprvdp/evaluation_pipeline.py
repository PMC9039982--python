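"""End-to-end in-silico study: cohort -> calibration -> APRV -> estimators.

For every patient record the pipeline calibrates a virtual patient to its
targets, ventilates it with APRV at each requested (P_high, P_low) setting
(T_high = 5 s, T_low = 0.5 s), computes the true driving pressure from the
lung pressure waveform and the four bedside estimates, and aggregates
method-comparison statistics: Bland-Altman bias and 95% limits of agreement
per estimator and setting, and Pearson correlations of the true driving
pressure against baseline compliance and P/F ratio.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import GAConfig, PatientTargets, calibrate
from .dp_estimators import estimate_all
from .model_core import ModelConfig
from .ventilation import APRVSettings, extract_measurements, run_aprv

logger = logging.getLogger("aprvdp")

DEFAULT_SETTINGS = ((30.0, 5.0), (30.0, 0.0), (25.0, 0.0))
ESTIMATORS = ("vcv", "mono", "tau4", "tau3")


@dataclasses.dataclass
class BlandAltman:
    """Bias and 95% limits of agreement between a method and the truth."""

    bias: float       # mean(estimate - truth)
    sd: float         # sample (n-1) standard deviation of the differences
    loa_low: float    # bias - 1.96 sd
    loa_high: float   # bias + 1.96 sd
    n: int


def bland_altman(truth, estimates) -> BlandAltman:
    """Bland-Altman statistics of ``estimates`` against ``truth``."""
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("truth and estimates must be equal-length vectors")
    if len(t) < 2:
        raise ValueError("need at least two paired values")
    d = e - t
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, sd=sd, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, n=len(d))


def pearson(x, y):
    """Pearson correlation with a two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclasses.dataclass
class CohortResult:
    """All per-patient and aggregate outputs of one study run."""

    reports: pd.DataFrame        # one row per patient x setting
    summary: pd.DataFrame        # per-setting cohort means
    bland_altman: pd.DataFrame   # per-setting x estimator
    correlations: pd.DataFrame   # dp_true vs compliance / PF, + error slopes
    calibration: pd.DataFrame    # per-patient J, evaluations, runtime
    excluded: list               # (patient_id, reason)
    settings: tuple


def pipeline_ga_config(**overrides) -> GAConfig:
    """Reduced-budget GA configuration used for cohort studies."""
    kw = dict(population=16, generations=10, mode="reduced", polish=True,
              polish_maxiter=60, j_stop=0.05)
    kw.update(overrides)
    return GAConfig(**kw)


def run_study(targets: list[PatientTargets],
              settings_list=DEFAULT_SETTINGS,
              seed: int = 0,
              ga_config: GAConfig | None = None,
              model_config: ModelConfig | None = None,
              aprv_duration: float = 1800.0,
              out_dir=None,
              write_waveforms: bool = False,
              plots: bool = False) -> CohortResult:
    """Run the full driving-pressure study over a cohort.

    Deterministic given ``seed`` (one child seed per patient).  Patients
    whose calibration fails are excluded with a logged reason and reported
    in the result.
    """
    ga = ga_config or pipeline_ga_config()
    cfg = model_config or ModelConfig()
    rows = []
    calib_rows = []
    excluded = []
    for idx, tgt in enumerate(targets):
        pid = tgt.patient_id or f"P{idx + 1:03d}"
        child_seed = int(np.random.SeedSequence([seed, idx]
                                                ).generate_state(1)[0]
                         % (2 ** 31))
        t0 = time.perf_counter()
        try:
            result = calibrate(tgt, ga, seed=child_seed, model_config=cfg)
        except ValueError as exc:
            excluded.append((pid, f"calibration error: {exc}"))
            logger.warning("patient %s excluded: %s", pid, exc)
            continue
        dt_cal = time.perf_counter() - t0
        calib_rows.append({
            "patient_id": pid, "severity": tgt.severity, "j": result.j,
            "evaluations": result.evaluations,
            "converged": result.converged, "seconds": round(dt_cal, 2),
            "seed": child_seed,
            "top_mean": result.patient.top_mean,
        })
        logger.info("patient %s calibrated: J=%.3f (%d evals, %.1f s, "
                    "seed %d)", pid, result.j, result.evaluations, dt_cal,
                    child_seed)
        if not result.converged or result.baseline is None:
            excluded.append((pid, f"calibration not converged (J={result.j:.2f})"))
            continue
        baseline_ms = result.baseline
        patient = result.patient
        if out_dir is not None:
            import pathlib

            from . import io as _io
            pdir = pathlib.Path(out_dir) / "patients"
            pdir.mkdir(parents=True, exist_ok=True)
            _io.save_patient(patient, pdir / f"{pid}.yaml")
        for ph, pl in settings_list:
            aprv = APRVSettings(p_high=ph, p_low=pl, t_high=5.0, t_low=0.5,
                                fio2=tgt.fio2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trace = run_aprv(patient, aprv, duration=aprv_duration,
                                 config=cfg)
                aprv_ms = extract_measurements(trace)
                report = estimate_all(
                    aprv_ms, baseline_ms, aprv, patient=patient, config=cfg,
                    sim=trace._sim, rr=tgt.rr or 15.0, dc=tgt.dc or 0.33)
            row = {
                "patient_id": pid, "severity": tgt.severity,
                "setting": f"{ph:g}/{pl:g}", "p_high": ph, "p_low": pl,
                "steady": trace.steady,
                "v_released": aprv_ms.v_released,
                "vt_ml_kg": aprv_ms.v_released * 1000.0 / patient.body_mass,
                "pefr": aprv_ms.pefr, "eefr": aprv_ms.eefr,
                "p_plat": aprv_ms.p_plat, "peep_tot": aprv_ms.peep_tot,
                "baseline_c": baseline_ms.c,
                "baseline_pf": baseline_ms.pf_ratio,
                "j": result.j,
            }
            row.update(report.as_dict())
            rows.append(row)
            if write_waveforms and out_dir is not None:
                import pathlib
                wdir = pathlib.Path(out_dir) / "waveforms"
                wdir.mkdir(parents=True, exist_ok=True)
                trace.to_csv(wdir / f"{pid}_{ph:g}_{pl:g}.csv")

    reports = pd.DataFrame(rows)
    summary, ba, corr = summarize(reports) if len(rows) else (
        pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
    result = CohortResult(
        reports=reports, summary=summary, bland_altman=ba,
        correlations=corr, calibration=pd.DataFrame(calib_rows),
        excluded=excluded, settings=tuple(settings_list),
    )
    if out_dir is not None:
        _write_outputs(result, out_dir, plots=plots)
    return result


def summarize(reports: pd.DataFrame):
    """Aggregate per-patient reports into the study's summary tables."""
    summaries = []
    ba_rows = []
    corr_rows = []
    for setting, grp in reports.groupby("setting", sort=False):
        summaries.append({
            "setting": setting,
            "n": len(grp),
            "dp_true_mean": grp["dp_true"].mean(),
            "dp_true_sd": grp["dp_true"].std(ddof=1) if len(grp) > 1 else 0.0,
            "vt_ml_kg_mean": grp["vt_ml_kg"].mean(),
            "peep_tot_mean": grp["peep_tot"].mean(),
        })
        for est in ESTIMATORS:
            vals = grp[f"dp_{est}"].to_numpy()
            ok = np.isfinite(vals)
            if ok.sum() >= 2:
                ba = bland_altman(grp["dp_true"].to_numpy()[ok], vals[ok])
                ba_rows.append({"setting": setting, "estimator": est,
                                **dataclasses.asdict(ba)})
        for var in ("baseline_c", "baseline_pf"):
            x = grp[var].to_numpy()
            y = grp["dp_true"].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                r, p = pearson(x[ok], y[ok])
                corr_rows.append({"setting": setting, "x": var,
                                  "y": "dp_true", "r": r, "p": p})
            # accuracy-vs-covariate slope (Fig-4-style check, reported only)
            for est in ESTIMATORS:
                err = grp[f"err_{est}"].to_numpy()
                ok2 = np.isfinite(x) & np.isfinite(err)
                if ok2.sum() >= 3 and np.std(x[ok2]) > 0 \
                        and np.std(err[ok2]) > 0:
                    lr = stats.linregress(x[ok2], err[ok2])
                    corr_rows.append({
                        "setting": setting, "x": var, "y": f"err_{est}",
                        "r": lr.rvalue, "p": lr.pvalue,
                        "slope": lr.slope,
                    })
    return (pd.DataFrame(summaries), pd.DataFrame(ba_rows),
            pd.DataFrame(corr_rows))


def _write_outputs(result: CohortResult, out_dir, plots: bool = False):
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.reports.to_csv(out / "dp_reports.csv", index=False)
    result.bland_altman.to_csv(out / "bland_altman.csv", index=False)
    result.correlations.to_csv(out / "correlations.csv", index=False)
    result.calibration.to_csv(out / "calibration.csv", index=False)
    lines = ["Driving-pressure study summary", "=" * 32]
    for _, row in result.summary.iterrows():
        lines.append(
            f"P_high/P_low {row['setting']} (n={int(row['n'])}): "
            f"true dP = {row['dp_true_mean']:.1f} +/- "
            f"{row['dp_true_sd']:.1f} cmH2O, "
            f"VT = {row['vt_ml_kg_mean']:.2f} mL/kg")
    if result.excluded:
        lines.append(f"excluded patients: {len(result.excluded)}")
        for pid, reason in result.excluded:
            lines.append(f"  {pid}: {reason}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    if plots:
        plot_bland_altman(result, out)


def plot_bland_altman(result: CohortResult, out_dir):
    """2x2 Bland-Altman panels (error vs true dP) per APRV setting."""
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(out_dir)
    labels = {"vcv": "VCV switch", "mono": "mono-exponential",
              "tau4": "4-tau", "tau3": "3-tau"}
    for setting, grp in result.reports.groupby("setting", sort=False):
        fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
        for ax, est in zip(axes.ravel(), ESTIMATORS):
            truth = grp["dp_true"].to_numpy()
            err = grp[f"err_{est}"].to_numpy()
            ok = np.isfinite(err)
            ax.scatter(truth[ok], err[ok], s=14, alpha=0.7)
            if ok.sum() >= 2:
                ba = bland_altman(truth[ok], truth[ok] + err[ok])
                ax.axhline(ba.bias, color="k")
                ax.axhline(ba.loa_low, color="k", ls="--")
                ax.axhline(ba.loa_high, color="k", ls="--")
            ax.axhline(0, color="0.7", lw=0.5)
            ax.set_title(labels[est])
            ax.set_xlabel("true dP (cmH2O)")
            ax.set_ylabel("estimate - truth (cmH2O)")
        fig.suptitle(f"P_high/P_low = {setting} cmH2O")
        fig.tight_layout()
        fig.savefig(out / f"bland_altman_{setting.replace('/', '_')}.png",
                    dpi=120)
        plt.close(fig)
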