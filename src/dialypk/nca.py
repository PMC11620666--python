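"""Noncompartmental analysis for plasma, dialyzer inlet/outlet, dialysate, urine.

Implements the standard single-dose NCA parameter set (Cmax within 24 h,
tmax, Clast, AUC0-24h, AUC0-t, AUC0-inf, lambda_z, t1/2, CL/F, Vz/F, percent
of AUC extrapolated) plus the dialysis-specific quantities: the dialyzer
extraction ratio ED = (AUCinlet - AUCoutlet)/AUCinlet x 100 from paired
pre-/post-dialyzer sampling, the mean plasma concentration during the
session P = AUCinlet/duration, the amount recovered in dialysate AeD, the
fraction of dose FeD, and the recovery dialysate clearance
CLD = AeD/(P x duration), and the urinary quantities Ae, Fe, CLR.

Below-LLOQ handling follows the study conventions: for descriptive use every
BLQ value is set to missing; for parameter computation, BLQ values embedded
between quantifiable concentrations and trailing BLQ values are set to
missing while leading pre-first-quantifiable BLQ values anchor the curve at
zero.  Missing data are never imputed.  lambda_z is fit by log-linear
regression on the contiguous terminal subset (>= 3 points, Cmax excluded)
with the best adjusted R-squared; extrapolation-dependent parameters are
flagged when more than 50% of AUC0-inf is extrapolated and when the
regression is unreliable (adjusted R-squared < 0.80).

Units: concentrations ng/mL, times h, volumes L, doses mg, clearances L/h.
Amount arithmetic: ng/mL x L = ug, so Ae [mg] = sum(conc x volume) / 1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ConcentrationProfile

__all__ = [
    "NCAResult",
    "DialysisNCAResult",
    "UrineNCAResult",
    "LambdaZResult",
    "blq_preprocess",
    "auc",
    "lambda_z",
    "nca_plasma",
    "nca_dialysate",
    "nca_urine",
    "MG_PER_CONC_VOLUME",
]

#: (ng/mL * L) -> mg
MG_PER_CONC_VOLUME = 1e-3

#: conversion used for clearances: dose[mg] * this / AUC[ng*h/mL] = CL [L/h]
_MG_TO_NGML_L = 1000.0


@dataclass
class LambdaZResult:
    lambda_z: float | None  # 1/h
    intercept: float | None  # log ng/mL at t = 0
    n_points: int
    adj_r_squared: float | None
    reliable: bool
    t_half: float | None  # h
    times_used: np.ndarray | None = None


@dataclass
class NCAResult:
    cmax_24h: float
    tmax: float
    clast: float
    tlast: float
    auc_0_24: float | None
    auc_0_t: float
    auc_0_inf: float | None
    lambda_z: float | None
    t_half: float | None
    cl_f: float | None  # L/h
    vz_f: float | None  # L
    pct_extrapolated: float | None
    extrapolation_exceeded: bool  # > 50% of AUC0-inf extrapolated
    lambda_z_reliable: bool
    lambda_z_diagnostics: LambdaZResult = field(repr=False, default=None)


@dataclass
class DialysisNCAResult:
    auc_inlet: float  # ng*h/mL over the session window
    auc_outlet: float
    ed_pct: float  # extraction ratio, %
    p_mean: float  # mean plasma concentration during the session (ng/mL)
    aed_mg: float | None  # amount recovered in dialysate
    fed_pct: float | None
    cld: float | None  # recovery clearance, L/h
    duration: float
    outlet_exceeds_inlet: bool  # data-inconsistency warning flag


@dataclass
class UrineNCAResult:
    ae_mg: float
    fe_pct: float
    clr: float | None  # L/h; None when no plasma AUC supplied
    interval_amounts_mg: np.ndarray


# ---------------------------------------------------------------------------
# BLQ handling
# ---------------------------------------------------------------------------


def blq_preprocess(
    profile: ConcentrationProfile,
    lloq: float | None = None,
    context: str = "parameter",
) -> ConcentrationProfile:
    """Apply the study's below-LLOQ rules and return a cleaned profile.

    ``descriptive``: every BLQ value becomes missing (NaN).
    ``parameter``: BLQ values between two quantifiable concentrations and
    trailing BLQ values become missing; leading BLQ values (before the first
    quantifiable sample) become zero, anchoring the AUC at the origin.
    """
    if context not in ("descriptive", "parameter"):
        raise ValueError(f"unknown context {context!r}")
    lloq = profile.lloq if lloq is None else lloq
    if lloq <= 0:
        raise ValueError("lloq must be > 0")
    values = profile.values.copy()
    with np.errstate(invalid="ignore"):
        is_blq = profile.blq | (np.isfinite(values) & (values < lloq))

    if context == "descriptive":
        values[is_blq] = np.nan
    else:
        quant = np.isfinite(values) & ~is_blq
        if np.any(quant):
            first_q = int(np.argmax(quant))
        else:
            first_q = values.size
        for i in range(values.size):
            if not is_blq[i]:
                continue
            values[i] = 0.0 if i < first_q else np.nan
    return ConcentrationProfile(
        times=profile.times.copy(), values=values, lloq=lloq,
        matrix=profile.matrix, dose_mg=profile.dose_mg,
        blq=is_blq,
    )


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def _interp_conc(t: np.ndarray, c: np.ndarray, at: float, method: str) -> float:
    """Concentration at an interior time, linear or log-down interpolation."""
    idx = int(np.searchsorted(t, at))
    if t[idx - 1] == at:
        return float(c[idx - 1])
    t0, t1 = t[idx - 1], t[idx]
    c0, c1 = c[idx - 1], c[idx]
    if method == "linear-up/log-down" and c1 < c0 and c0 > 0 and c1 > 0:
        return float(c0 * (c1 / c0) ** ((at - t0) / (t1 - t0)))
    return float(c0 + (c1 - c0) * (at - t0) / (t1 - t0))


def auc(
    profile: ConcentrationProfile,
    t_start: float,
    t_end: float,
    method: str = "linear",
) -> float:
    """Partial AUC over [t_start, t_end] from non-missing samples.

    ``linear`` uses the trapezoid everywhere; ``linear-up/log-down`` uses a
    log trapezoid on strictly declining positive segments.  Endpoints inside
    the sampled range are interpolated.
    """
    if method not in ("linear", "linear-up/log-down"):
        raise ValueError(f"unknown AUC method {method!r}")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    keep = np.isfinite(profile.values)
    t = profile.times[keep]
    c = profile.values[keep]
    if t.size < 2:
        raise ValueError("need at least two non-missing samples")
    tol = 1e-5 * max(1.0, abs(t_end))
    if t_start < t[0] - tol or t_end > t[-1] + tol:
        raise ValueError(
            f"span [{t_start:g}, {t_end:g}] lies outside the sampled range "
            f"[{t[0]:g}, {t[-1]:g}]"
        )
    t_start = max(t_start, float(t[0]))
    t_end = min(t_end, float(t[-1]))
    inside = (t > t_start) & (t < t_end)
    if not np.any(inside) and not (t_start in t and t_end in t):
        # endpoints interpolated only when interior samples exist
        if not np.any((t >= t_start) & (t <= t_end)):
            raise ValueError("no samples inside the requested span")
    tt = [t_start] + list(t[inside]) + [t_end]
    cc = ([_interp_conc(t, c, t_start, method)] + list(c[inside])
          + [_interp_conc(t, c, t_end, method)])
    total = 0.0
    for (t0, c0), (t1, c1) in zip(zip(tt, cc), zip(tt[1:], cc[1:])):
        dt = t1 - t0
        if dt == 0:
            continue
        if method == "linear-up/log-down" and c1 < c0 and c0 > 0 and c1 > 0:
            total += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            total += dt * 0.5 * (c0 + c1)
    return float(total)


# ---------------------------------------------------------------------------
# terminal slope
# ---------------------------------------------------------------------------


def lambda_z(profile: ConcentrationProfile, min_points: int = 3,
             r2_threshold: float = 0.80) -> LambdaZResult:
    """Terminal log-linear rate constant with automatic point selection.

    Considers contiguous terminal subsets of at least ``min_points``
    quantifiable post-tmax samples (the Cmax sample itself excluded), fits
    log concentration against time, and keeps the subset with the highest
    adjusted R-squared among fits with a negative slope.
    """
    keep = np.isfinite(profile.values) & (profile.values > 0)
    t = profile.times[keep]
    c = profile.values[keep]
    if t.size == 0:
        return LambdaZResult(None, None, 0, None, False, None)
    i_max = int(np.argmax(c))
    t_tail = t[i_max + 1:]
    c_tail = c[i_max + 1:]
    if t_tail.size < min_points:
        return LambdaZResult(None, None, int(t_tail.size), None, False, None)

    best = None
    logc = np.log(c_tail)
    for start in range(t_tail.size - min_points + 1):
        x = t_tail[start:]
        y = logc[start:]
        n = x.size
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        pred = slope * x + intercept
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        if best is None or adj > best[0] + 1e-12:
            best = (adj, slope, intercept, x)
    if best is None:
        return LambdaZResult(None, None, int(t_tail.size), None, False, None)
    adj, slope, intercept, x = best
    lam = -float(slope)
    return LambdaZResult(
        lambda_z=lam,
        intercept=float(intercept),
        n_points=int(x.size),
        adj_r_squared=float(adj),
        reliable=bool(adj >= r2_threshold),
        t_half=math.log(2.0) / lam,
        times_used=x,
    )


# ---------------------------------------------------------------------------
# plasma NCA
# ---------------------------------------------------------------------------


def nca_plasma(
    profile: ConcentrationProfile,
    dose_mg: float,
    *,
    auc_method: str = "linear",
) -> NCAResult:
    """Full single-dose plasma NCA (profile pre-cleaned in parameter context)."""
    keep = np.isfinite(profile.values)
    t = profile.times[keep]
    c = profile.values[keep]
    if t.size < 2:
        raise ValueError("need at least two non-missing samples for NCA")

    # Cmax within 24 h of dosing, first occurrence on ties
    in24 = t <= 24.0 + 1e-9
    if np.any(in24):
        i24 = int(np.argmax(c[in24]))
        cmax24 = float(c[in24][i24])
        tmax = float(t[in24][i24])
    else:
        i_all = int(np.argmax(c))
        cmax24, tmax = float(c[i_all]), float(t[i_all])

    pos = c > 0
    tlast = float(t[pos][-1]) if np.any(pos) else float(t[-1])
    clast = float(c[pos][-1]) if np.any(pos) else 0.0

    auc_0_t = auc(profile, float(t[0]), tlast, method=auc_method)
    auc_0_24 = None
    if t[-1] >= 24.0 - 1e-9:
        auc_0_24 = auc(profile, float(t[0]), 24.0, method=auc_method)

    lz = lambda_z(profile)
    auc_inf = cl_f = vz_f = pct_extrap = t_half = lam = None
    exceeded = False
    if lz.lambda_z is not None:
        lam = lz.lambda_z
        t_half = lz.t_half
        auc_inf = auc_0_t + clast / lam
        pct_extrap = 100.0 * (1.0 - auc_0_t / auc_inf)
        exceeded = pct_extrap > 50.0
        if dose_mg is not None and dose_mg > 0:
            cl_f = dose_mg * _MG_TO_NGML_L / auc_inf
            vz_f = cl_f / lam
    return NCAResult(
        cmax_24h=cmax24, tmax=tmax, clast=clast, tlast=tlast,
        auc_0_24=auc_0_24, auc_0_t=auc_0_t, auc_0_inf=auc_inf,
        lambda_z=lam, t_half=t_half, cl_f=cl_f, vz_f=vz_f,
        pct_extrapolated=pct_extrap,
        extrapolation_exceeded=exceeded,
        lambda_z_reliable=lz.reliable,
        lambda_z_diagnostics=lz,
    )


# ---------------------------------------------------------------------------
# dialysate NCA
# ---------------------------------------------------------------------------


def nca_dialysate(
    inlet: ConcentrationProfile,
    outlet: ConcentrationProfile,
    dialysate_records: pd.DataFrame | None,
    dose_mg: float,
    window: tuple[float, float],
    *,
    auc_method: str = "linear",
) -> DialysisNCAResult:
    """Dialyzer extraction and dialysate recovery over one session window.

    ``dialysate_records`` needs columns ``conc`` (ng/mL) and ``volume`` (L)
    per collection sub-interval; pass None when only extraction is wanted.
    """
    t_start, t_end = window
    for name, prof in (("inlet", inlet), ("outlet", outlet)):
        keep = np.isfinite(prof.values)
        t = prof.times[keep]
        if t.size < 2 or t[0] > t_start + 1e-6 or t[-1] < t_end - 1e-6:
            raise ValueError(
                f"{name} sampling does not cover the session window "
                f"[{t_start:g}, {t_end:g}] h"
            )
    duration = t_end - t_start
    auc_in = auc(inlet, t_start, t_end, method=auc_method)
    auc_out = auc(outlet, t_start, t_end, method=auc_method)
    ed = 100.0 * (auc_in - auc_out) / auc_in
    p_mean = auc_in / duration

    aed = fed = cld = None
    if dialysate_records is not None:
        missing = {"conc", "volume"} - set(dialysate_records.columns)
        if missing:
            raise ValueError(f"dialysate records lack columns {sorted(missing)}")
        conc = dialysate_records["conc"].to_numpy(dtype=float)
        vol = dialysate_records["volume"].to_numpy(dtype=float)
        aed = float(np.nansum(conc * vol)) * MG_PER_CONC_VOLUME
        fed = 100.0 * aed / dose_mg
        cld = aed * _MG_TO_NGML_L / (p_mean * duration)  # == AeD/AUCinlet
    return DialysisNCAResult(
        auc_inlet=auc_in, auc_outlet=auc_out, ed_pct=float(ed),
        p_mean=float(p_mean), aed_mg=aed, fed_pct=fed, cld=cld,
        duration=float(duration),
        outlet_exceeds_inlet=bool(auc_out > auc_in),
    )


# ---------------------------------------------------------------------------
# urine NCA
# ---------------------------------------------------------------------------


def nca_urine(
    collections: pd.DataFrame,
    dose_mg: float,
    plasma_auc: float | None = None,
) -> UrineNCAResult:
    """Urinary recovery from interval collections.

    ``collections`` needs columns ``t_start``, ``t_end`` (h), ``volume`` (L)
    and ``conc`` (ng/mL).  ``plasma_auc`` is the plasma AUC over the matching
    span (ng*h/mL); when provided, CLR = Ae/AUC.
    """
    required = {"t_start", "t_end", "volume", "conc"}
    missing = required - set(collections.columns)
    if missing:
        raise ValueError(f"urine collections lack columns {sorted(missing)}")
    df = collections.sort_values("t_start").reset_index(drop=True)
    starts = df["t_start"].to_numpy(dtype=float)
    ends = df["t_end"].to_numpy(dtype=float)
    if np.any(ends <= starts):
        raise ValueError("collection intervals must have positive duration")
    if np.any(starts[1:] < ends[:-1] - 1e-9):
        raise ValueError("urine collection intervals overlap")
    conc = np.nan_to_num(df["conc"].to_numpy(dtype=float))
    vol = df["volume"].to_numpy(dtype=float)
    amounts = conc * vol * MG_PER_CONC_VOLUME
    ae = float(np.sum(amounts))
    fe = 100.0 * ae / dose_mg
    clr = None
    if plasma_auc is not None:
        if plasma_auc <= 0:
            raise ValueError("plasma AUC must be > 0 for CLR")
        clr = ae * _MG_TO_NGML_L / plasma_auc
    return UrineNCAResult(ae_mg=ae, fe_pct=fe, clr=clr,
                          interval_amounts_mg=amounts)
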