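"""Steady-state exposure metrics, cohort threshold summaries, bioequivalence.

Per-subject metrics are read off the fine-grid terminal dosing interval:
Cmax/tmax (first occurrence on ties), Ctrough (the concentration exactly at
the end of the interval), AUCtau by the trapezoid rule, and
Cavg = AUCtau / tau.  Cohort summaries report the percentage of subjects with
Cmax above a molar threshold (10 uM by default, converted with the migalastat
free-base molar mass 163.17 g/mol -> 1631.7 ng/mL) and the percentage with
Ctrough below the LLOQ.

The geometric mean ratio (test:reference) of a metric is computed on the log
scale with a Welch two-sample t confidence interval (the two cohorts are
independent sets of virtual subjects); bioequivalence is declared when the
90% CI lies entirely within [0.80, 1.25].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import ConcentrationProfile
from .params import MIGALASTAT_MOLAR_MASS, PLASMA_LLOQ

__all__ = [
    "ExposureMetrics",
    "GMRResult",
    "interval_metrics",
    "cohort_threshold_summary",
    "gmr_with_ci",
    "fraction_above",
    "micromolar_to_ng_per_ml",
    "BE_BAND",
]

BE_BAND = (0.80, 1.25)


def micromolar_to_ng_per_ml(um: float, molar_mass: float = MIGALASTAT_MOLAR_MASS) -> float:
    """Convert a molar plasma threshold to ng/mL (uM x g/mol = ng/mL)."""
    return um * molar_mass


@dataclass(frozen=True)
class ExposureMetrics:
    cmax: float  # ng/mL
    tmax: float  # h from interval start
    ctrough: float  # ng/mL at the end of the interval
    auc_tau: float  # ng*h/mL
    cavg: float  # ng/mL
    fraction_above_threshold: float | None = None


@dataclass(frozen=True)
class GMRResult:
    gmr: float
    ci_lower: float
    ci_upper: float
    bioequivalent: bool
    n_test: int
    n_ref: int
    n_excluded: int = 0  # non-positive metric values dropped

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.gmr <= self.ci_upper:
            raise ValueError("GMR must lie within its confidence interval")


def interval_metrics(
    profile: ConcentrationProfile,
    tau: float,
    *,
    threshold: float | None = None,
    max_gap: float = 1.0,
) -> ExposureMetrics:
    """Exposure metrics over exactly one steady-state dosing interval."""
    t, c = profile.times, profile.values
    if t.size < 2:
        raise ValueError("interval profile needs at least two points")
    span = t[-1] - t[0]
    if abs(span - tau) > 1e-6 * max(tau, 1.0):
        raise ValueError(f"profile spans {span:g} h but tau = {tau:g} h")
    if np.max(np.diff(t)) > max_gap:
        raise ValueError(
            f"grid gap {np.max(np.diff(t)):g} h exceeds {max_gap:g} h; "
            "metric accuracy not guaranteed"
        )
    i_max = int(np.argmax(c))  # first occurrence on ties
    auc = float(np.trapezoid(c, t))
    frac = None if threshold is None else fraction_above(profile, threshold)
    return ExposureMetrics(
        cmax=float(c[i_max]),
        tmax=float(t[i_max] - t[0]),
        ctrough=float(c[-1]),
        auc_tau=auc,
        cavg=auc / tau,
        fraction_above_threshold=frac,
    )


def cohort_threshold_summary(
    metrics: list[ExposureMetrics],
    cmax_threshold: float = micromolar_to_ng_per_ml(10.0),
    lloq: float = PLASMA_LLOQ,
) -> dict[str, float]:
    """Percent of subjects with Cmax above threshold and Ctrough below LLOQ."""
    if not metrics:
        raise ValueError("cohort is empty")
    n = len(metrics)
    above = sum(m.cmax > cmax_threshold for m in metrics)
    blq = sum(m.ctrough < lloq for m in metrics)
    return {
        "n": n,
        "pct_cmax_above": 100.0 * above / n,
        "pct_ctrough_blq": 100.0 * blq / n,
    }


def gmr_with_ci(
    test_values: np.ndarray,
    ref_values: np.ndarray,
    alpha: float = 0.10,
    band: tuple[float, float] = BE_BAND,
) -> GMRResult:
    """Geometric mean ratio test:reference with a Welch log-scale CI."""
    test_values = np.asarray(test_values, dtype=float)
    ref_values = np.asarray(ref_values, dtype=float)
    if test_values.size == 0 or ref_values.size == 0:
        raise ValueError("both cohorts must be nonempty")
    n_excluded = int(np.sum(test_values <= 0) + np.sum(ref_values <= 0))
    test = test_values[test_values > 0]
    ref = ref_values[ref_values > 0]
    if test.size == 0 or ref.size == 0:
        raise ValueError("all metric values are non-positive in one cohort")

    lt, lr = np.log(test), np.log(ref)
    diff = float(lt.mean() - lr.mean())
    v1 = float(lt.var(ddof=1)) if lt.size > 1 else 0.0
    v2 = float(lr.var(ddof=1)) if lr.size > 1 else 0.0
    se = math.sqrt(v1 / lt.size + v2 / lr.size)
    if se == 0.0:
        lo = hi = diff
    else:
        num = (v1 / lt.size + v2 / lr.size) ** 2
        den = 0.0
        if lt.size > 1:
            den += (v1 / lt.size) ** 2 / (lt.size - 1)
        if lr.size > 1:
            den += (v2 / lr.size) ** 2 / (lr.size - 1)
        df = num / den if den > 0 else float(lt.size + lr.size - 2)
        tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
        lo, hi = diff - tcrit * se, diff + tcrit * se
    gmr = math.exp(diff)
    ci = (math.exp(lo), math.exp(hi))
    return GMRResult(
        gmr=gmr, ci_lower=ci[0], ci_upper=ci[1],
        bioequivalent=bool(band[0] <= ci[0] and ci[1] <= band[1]),
        n_test=int(test.size), n_ref=int(ref.size), n_excluded=n_excluded,
    )


def fraction_above(profile: ConcentrationProfile, threshold: float) -> float:
    """Time-weighted fraction of the interval with concentration above a threshold.

    Piecewise-linear interpolation locates the crossing time inside each grid
    segment; the result lies in [0, 1].
    """
    t, c = profile.times, profile.values
    if t.size < 2:
        raise ValueError("profile needs at least two points")
    total = t[-1] - t[0]
    if total <= 0:
        raise ValueError("profile must span a positive duration")
    above_time = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        if dt == 0:
            continue
        c0, c1 = c[i] - threshold, c[i + 1] - threshold
        if c0 >= 0 and c1 >= 0:
            above_time += dt
        elif c0 < 0 and c1 < 0:
            continue
        else:
            # single crossing inside the segment
            frac = c0 / (c0 - c1)
            if c0 >= 0:
                above_time += dt * frac
            else:
                above_time += dt * (1.0 - frac)
    return float(min(max(above_time / total, 0.0), 1.0))
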