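"""End-to-end pipeline operations: scenario tables and batch NCA.

``run_scenario_table`` simulates the reference cohort (virtual Fabry
subjects with normal renal function on 123 mg every other day, no dialysis)
and each test scenario's ESRD cohort to steady state, then reports one row
per scenario: geometric mean ratios (ESRD:NRF) with 90% CIs for Cavg and
Cmax, bioequivalence flags against the 0.80-1.25 band, and the percentage of
subjects with Cmax > 10 uM and with Ctrough below the LLOQ.

``run_nca`` consumes the long-format study table (synthetic or external),
applies the below-LLOQ rules, runs plasma/dialysate/urine NCA per subject and
period, and produces median/range summaries by arm and period with the
extrapolation-suppression rules applied.

All randomness flows from explicit seeds; re-running a config reproduces the
output bit for bit.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import (
    cohort_threshold_summary,
    gmr_with_ci,
    interval_metrics,
    micromolar_to_ng_per_ml,
)
from .model import FixedEffects, OmegaSpec, ResidualSpec, ConcentrationProfile
from .nca import blq_preprocess, nca_dialysate, nca_plasma, nca_urine
from .params import PLASMA_LLOQ, default_fixed_effects, default_omega, default_residual
from .population import esrd_cohort_spec, nrf_cohort_spec, sample_cohort
from .regimens import Scenario, enumerate_scenarios, simulate_to_steady_state

logger = logging.getLogger("dialypk")

__all__ = ["RunConfig", "run_scenario_table", "run_nca", "scenario_metrics"]


@dataclass
class RunConfig:
    """Settings for a scenario-table run."""

    n_subjects: int = 100
    seed: int = 2024
    scenarios: list[dict] | None = None  # None = published grid
    fixed: FixedEffects = field(default_factory=default_fixed_effects)
    omega: OmegaSpec = field(default_factory=default_omega)
    lloq: float = PLASMA_LLOQ
    cmax_threshold_um: float = 10.0
    be_band: tuple[float, float] = (0.80, 1.25)
    grid_step: float = 0.25
    rtol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.be_band[0] < self.be_band[1]:
            raise ValueError("bioequivalence band must be increasing")


def scenario_metrics(
    subjects,
    fixed: FixedEffects,
    scenario: Scenario,
    *,
    lloq: float = PLASMA_LLOQ,
    threshold: float | None = None,
    grid_step: float = 0.25,
    rtol: float = 1e-6,
) -> pd.DataFrame:
    """Per-subject steady-state exposure metrics for one scenario."""
    rows = []
    for subject in subjects:
        res = simulate_to_steady_state(subject, fixed, scenario,
                                       grid_step=grid_step, rtol=rtol, lloq=lloq)
        m = interval_metrics(res.profile, res.tau, threshold=threshold)
        rows.append({
            "id": subject.id, "scenario": scenario.label,
            "cmax": m.cmax, "tmax": m.tmax, "ctrough": m.ctrough,
            "auc_tau": m.auc_tau, "cavg": m.cavg,
            "fraction_above": m.fraction_above_threshold,
            "converged": res.converged, "n_cycles": res.n_cycles,
        })
    return pd.DataFrame(rows)


def run_scenario_table(config: RunConfig) -> pd.DataFrame:
    """Simulate the reference and every test scenario; one report row each."""
    scenarios = enumerate_scenarios(config.scenarios)
    reference = next((s for s in scenarios if s.dialysis.pattern == "none"),
                     scenarios[0])
    tests = [s for s in scenarios if s is not reference]

    seeds = np.random.SeedSequence(config.seed).generate_state(2)
    threshold = micromolar_to_ng_per_ml(config.cmax_threshold_um)
    logger.info("scenario table: seed=%s n=%s scenarios=%s",
                config.seed, config.n_subjects,
                [s.label for s in scenarios])

    nrf = sample_cohort(nrf_cohort_spec(config.n_subjects, seed=int(seeds[0])),
                        config.omega)
    esrd = sample_cohort(esrd_cohort_spec(config.n_subjects, seed=int(seeds[1])),
                         config.omega)

    ref_metrics = scenario_metrics(nrf, config.fixed, reference,
                                   lloq=config.lloq, threshold=threshold,
                                   grid_step=config.grid_step, rtol=config.rtol)
    rows = [_scenario_row(reference, ref_metrics, ref_metrics, config, threshold,
                          is_reference=True)]
    for scenario in tests:
        tm = scenario_metrics(esrd, config.fixed, scenario,
                              lloq=config.lloq, threshold=threshold,
                              grid_step=config.grid_step, rtol=config.rtol)
        rows.append(_scenario_row(scenario, tm, ref_metrics, config, threshold))
    return pd.DataFrame(rows)


def _scenario_row(scenario, metrics, ref_metrics, config, threshold,
                  is_reference=False):
    summary = cohort_threshold_summary(
        [m for m in _metrics_objects(metrics)],
        cmax_threshold=threshold, lloq=config.lloq)
    gmr_cavg = gmr_with_ci(metrics["cavg"].to_numpy(),
                           ref_metrics["cavg"].to_numpy(), band=config.be_band)
    gmr_cmax = gmr_with_ci(metrics["cmax"].to_numpy(),
                           ref_metrics["cmax"].to_numpy(), band=config.be_band)
    return {
        "scenario": scenario.label,
        "dialysis": scenario.dialysis.pattern,
        "regimen": f"{scenario.regimen.dose_mg:g} mg {scenario.regimen.interval}",
        "gmr_cavg": gmr_cavg.gmr,
        "gmr_cavg_lo": gmr_cavg.ci_lower,
        "gmr_cavg_hi": gmr_cavg.ci_upper,
        "be_cavg": gmr_cavg.bioequivalent,
        "gmr_cmax": gmr_cmax.gmr,
        "gmr_cmax_lo": gmr_cmax.ci_lower,
        "gmr_cmax_hi": gmr_cmax.ci_upper,
        "be_cmax": gmr_cmax.bioequivalent,
        "pct_cmax_above": summary["pct_cmax_above"],
        "pct_ctrough_blq": summary["pct_ctrough_blq"],
        "n": summary["n"],
        "all_converged": bool(metrics["converged"].all()),
        "is_reference": is_reference,
    }


def _metrics_objects(frame: pd.DataFrame):
    from .exposure import ExposureMetrics

    for _, r in frame.iterrows():
        yield ExposureMetrics(cmax=r["cmax"], tmax=r["tmax"], ctrough=r["ctrough"],
                              auc_tau=r["auc_tau"], cavg=r["cavg"])


# ---------------------------------------------------------------------------
# batch NCA
# ---------------------------------------------------------------------------

_PLASMA_COLUMNS = ["cmax_24h", "tmax", "clast", "auc_0_24", "auc_0_t",
                   "auc_0_inf", "t_half", "cl_f", "vz_f", "pct_extrapolated"]
_DIALYSIS_COLUMNS = ["auc_inlet", "auc_outlet", "ed_pct", "aed_mg", "fed_pct",
                     "cld"]
_URINE_COLUMNS = ["ae_mg", "fe_pct", "clr"]


def run_nca(dataset: pd.DataFrame, *, auc_method: str = "linear") -> dict:
    """Per-subject NCA plus arm x period median/range summaries.

    Returns ``{"subjects": DataFrame, "summary": DataFrame}``.  Parameters
    that depend on the extrapolated AUC are blanked when more than 50% of the
    area is extrapolated or the terminal regression is unreliable.
    """
    required = {"ID", "ARM", "PERIOD", "MATRIX", "TAD", "DV", "BLQ", "LLOQ",
                "DOSE_MG"}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset lacks required columns {sorted(missing)}")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")

    rows = []
    for (sid, period), grp in dataset.groupby(["ID", "PERIOD"], sort=True):
        arm = grp["ARM"].iloc[0]
        dose = float(grp["DOSE_MG"].iloc[0])
        out = {"ID": int(sid), "ARM": arm, "PERIOD": int(period)}

        plasma_rows = grp[grp["MATRIX"] == "plasma"]
        if len(plasma_rows):
            lloq = float(plasma_rows["LLOQ"].iloc[0])
            profile = blq_preprocess(_profile(plasma_rows, lloq), context="parameter")
            try:
                res = nca_plasma(profile, dose, auc_method=auc_method)
            except ValueError:
                res = None
            if res is not None:
                suppress = res.extrapolation_exceeded or not res.lambda_z_reliable
                out.update({
                    "cmax_24h": res.cmax_24h, "tmax": res.tmax,
                    "clast": res.clast, "auc_0_24": res.auc_0_24,
                    "auc_0_t": res.auc_0_t,
                    "auc_0_inf": np.nan if suppress else res.auc_0_inf,
                    "t_half": np.nan if suppress else res.t_half,
                    "cl_f": np.nan if suppress else res.cl_f,
                    "vz_f": np.nan if suppress else res.vz_f,
                    "pct_extrapolated": res.pct_extrapolated,
                    "extrapolation_exceeded": res.extrapolation_exceeded,
                })

        inlet_rows = grp[grp["MATRIX"] == "inlet"]
        outlet_rows = grp[grp["MATRIX"] == "outlet"]
        dial_rows = grp[grp["MATRIX"] == "dialysate"]
        if len(inlet_rows) >= 2 and len(outlet_rows) >= 2:
            lloq = float(inlet_rows["LLOQ"].iloc[0])
            inlet = blq_preprocess(_profile(inlet_rows, lloq), context="parameter")
            outlet = blq_preprocess(_profile(outlet_rows, lloq), context="parameter")
            window = (float(inlet.times.min()), float(inlet.times.max()))
            records = None
            if len(dial_rows):
                records = pd.DataFrame({
                    "conc": dial_rows["DV"].fillna(0.0).to_numpy(),
                    "volume": dial_rows["VOLUME"].to_numpy()})
            dres = nca_dialysate(inlet, outlet, records, dose, window)
            out.update({"auc_inlet": dres.auc_inlet, "auc_outlet": dres.auc_outlet,
                        "ed_pct": dres.ed_pct, "aed_mg": dres.aed_mg,
                        "fed_pct": dres.fed_pct, "cld": dres.cld})

        urine_rows = grp[grp["MATRIX"] == "urine"]
        if len(urine_rows):
            collections = pd.DataFrame({
                "t_start": urine_rows["TSTART"].to_numpy(),
                "t_end": urine_rows["TEND"].to_numpy(),
                "volume": urine_rows["VOLUME"].to_numpy(),
                "conc": urine_rows["DV"].fillna(0.0).to_numpy()})
            plasma_auc_span = None
            if len(plasma_rows):
                try:
                    from .nca import auc as _auc
                    span = (float(urine_rows["TSTART"].min()),
                            float(urine_rows["TEND"].max()))
                    plasma_auc_span = _auc(profile, span[0], span[1],
                                           method=auc_method)
                except (ValueError, UnboundLocalError):
                    plasma_auc_span = None
            ures = nca_urine(collections, dose, plasma_auc_span)
            out.update({"ae_mg": ures.ae_mg, "fe_pct": ures.fe_pct,
                        "clr": ures.clr})
        rows.append(out)

    subjects = pd.DataFrame(rows)
    summary = _summarise(subjects)
    return {"subjects": subjects, "summary": summary}


def _profile(rows: pd.DataFrame, lloq: float) -> ConcentrationProfile:
    rows = rows.sort_values("TAD")
    return ConcentrationProfile(
        times=rows["TAD"].to_numpy(dtype=float),
        values=rows["DV"].to_numpy(dtype=float),
        lloq=lloq, matrix=str(rows["MATRIX"].iloc[0]),
        blq=rows["BLQ"].to_numpy(dtype=int).astype(bool))


def _summarise(subjects: pd.DataFrame) -> pd.DataFrame:
    params = [c for c in _PLASMA_COLUMNS + _DIALYSIS_COLUMNS + _URINE_COLUMNS
              if c in subjects.columns]
    out = []
    for (arm, period), grp in subjects.groupby(["ARM", "PERIOD"], sort=True):
        for p in params:
            vals = grp[p].dropna()
            out.append({
                "ARM": arm, "PERIOD": int(period), "parameter": p,
                "n": int(len(vals)),
                "median": float(vals.median()) if len(vals) else np.nan,
                "min": float(vals.min()) if len(vals) else np.nan,
                "max": float(vals.max()) if len(vals) else np.nan,
            })
    return pd.DataFrame(out)


def frame_hash(frame: pd.DataFrame) -> str:
    """Stable content hash for provenance logging and double-run checks."""
    payload = frame.to_csv(index=False, float_format="%.12g").encode()
    return hashlib.sha256(payload).hexdigest()
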