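"""Two-compartment oral population-PK model with intermittent dialysis clearance.

The structural model is a linear two-compartment disposition (central volume
``V2``, peripheral volume ``V3``, intercompartmental clearance ``Q``) with
first-order oral absorption from a depot, an absorption lag, and a
time-varying absorption rate constant

    Ka(t) = Ka_intercept + Ka_slope * min(TAD, 24 h)

where TAD is the time after the most recent dose.  Elimination is first order
from the central compartment with clearance ``CL`` that is augmented by an
apparent dialysis clearance ``CLD`` while a hemodialysis session is active:

    CL_elim(t) = CL + CLD * 1[dialysis active at t]

The covariate model scales clearances allometrically with body weight capped
at 70 kg (exponent 0.75 on CL and Q, 1 on volumes), applies a piecewise-linear
renal-function effect on CL that is constant above an eGFR of
120 mL/min/1.73 m2, and applies multiplicative Fabry-status effects on CL and
V2.  Inter-individual variability enters as log-normal random effects on CL
and V2 (correlated) and on the Ka slope and intercept.

Two solution paths are provided: an event-driven numerical simulator
(:func:`simulate_profile`) that supports arbitrary dose/dialysis schedules and
keeps cumulative elimination ledgers for mass-balance auditing, and an exact
matrix-exponential solution for a single dose with constant Ka and no dialysis
(:func:`closed_form_single_dose`) that serves as an independent oracle.

Internal canonical units: amounts in mg, volumes in L, clearances in L/h,
times in h.  Concentrations are reported in ng/mL (1 mg/L = 1000 ng/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FixedEffects",
    "OmegaSpec",
    "ResidualSpec",
    "CovariateSet",
    "IndividualParameters",
    "DoseEvent",
    "DialysisSession",
    "EventSchedule",
    "ConcentrationProfile",
    "SimulationResult",
    "FitResult",
    "MG_PER_L_TO_NG_PER_ML",
    "TAD_CAP_H",
    "WEIGHT_CAP_KG",
    "EGFR_CAP",
    "wtco",
    "renal_function_factor",
    "derive_individual_parameters",
    "absorption_rate",
    "simulate_profile",
    "closed_form_single_dose",
    "fit_pooled",
]

MG_PER_L_TO_NG_PER_ML = 1000.0  # 1 mg/L == 1000 ng/mL
TAD_CAP_H = 24.0  # time after dose beyond which Ka is held constant
WEIGHT_CAP_KG = 70.0  # weight capped at and normalised to 70 kg
EGFR_CAP = 120.0  # eGFR above which the renal effect is constant


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedEffects:
    """Population (typical-value) parameters of the structural model.

    ``egfr_intercept``/``egfr_slope`` parameterise the piecewise-linear renal
    effect on CL; the factor is normalised to 1 at ``egfr_ref`` so ``cl`` is
    the typical clearance of a 70 kg non-Fabry subject at the reference eGFR.
    """

    cl: float  # apparent clearance CL/F at reference covariates (L/h)
    v2: float  # central volume V2/F (L)
    q: float  # intercompartmental clearance Q/F (L/h)
    v3: float  # peripheral volume V3/F (L)
    ka_intercept: float  # absorption rate intercept (1/h)
    ka_slope: float  # absorption rate slope (1/h per h of TAD)
    alag: float  # absorption lag (h)
    f1: float = 1.0  # relative bioavailability (dose-independent default)
    egfr_intercept: float = 0.026886
    egfr_slope: float = 0.010812  # per mL/min/1.73 m2
    egfr_ref: float = 90.0  # eGFR at which the renal factor is 1
    fd_cl: float = 1.0  # multiplicative Fabry effect on CL
    fd_v2: float = 1.0  # multiplicative Fabry effect on V2
    allometric_cl: float = 0.75  # fixed, not estimated
    allometric_v: float = 1.0  # fixed, not estimated

    def __post_init__(self) -> None:
        for name in ("cl", "v2", "q", "v3", "ka_intercept", "alag", "f1",
                     "fd_cl", "fd_v2"):
            value = getattr(self, name)
            if name in ("q", "alag"):
                if value < 0:
                    raise ValueError(f"{name} must be >= 0, got {value}")
            elif value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        ref_factor = self.egfr_intercept + self.egfr_slope * min(self.egfr_ref, EGFR_CAP)
        if ref_factor <= 0:
            raise ValueError("renal effect must be positive at the reference eGFR")


@dataclass(frozen=True)
class OmegaSpec:
    """Inter-individual variability: log-scale variances and CL-V2 correlation."""

    var_eta_cl: float = 0.0
    var_eta_v2: float = 0.0
    corr_cl_v2: float = 0.0
    var_eta_ka_slope: float = 0.0
    var_eta_ka_intercept: float = 0.0

    def __post_init__(self) -> None:
        for name in ("var_eta_cl", "var_eta_v2", "var_eta_ka_slope",
                     "var_eta_ka_intercept"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.corr_cl_v2 <= 1.0:
            raise ValueError("corr_cl_v2 must lie in [-1, 1]")

    def cl_v2_covariance(self) -> np.ndarray:
        """2x2 covariance of (eta_CL, eta_V2); raises if not PSD."""
        cov = self.corr_cl_v2 * math.sqrt(self.var_eta_cl * self.var_eta_v2)
        matrix = np.array([[self.var_eta_cl, cov], [cov, self.var_eta_v2]])
        if np.min(np.linalg.eigvalsh(matrix)) < -1e-12:
            raise ValueError("implied eta covariance is not positive semi-definite")
        return matrix


@dataclass(frozen=True)
class ResidualSpec:
    """Residual (within-subject) error model for observed concentrations."""

    proportional_sd: float = 0.20  # fraction of the prediction
    additive_sd: float = 2.94  # ng/mL (default 0.5 * plasma LLOQ)
    kind: str = "combined"  # proportional | additive | combined

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown residual model kind {self.kind!r}")
        if self.proportional_sd < 0 or self.additive_sd < 0:
            raise ValueError("residual sds must be >= 0")

    def perturb(self, conc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        out = conc.copy()
        if self.kind in ("proportional", "combined") and self.proportional_sd > 0:
            out = out * (1.0 + self.proportional_sd * rng.standard_normal(conc.shape))
        if self.kind in ("additive", "combined") and self.additive_sd > 0:
            out = out + self.additive_sd * rng.standard_normal(conc.shape)
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class CovariateSet:
    """Subject covariates entering the fixed-effect model."""

    weight: float  # kg
    egfr: float  # mL/min/1.73 m2
    fabry: int = 0  # 0 = no Fabry disease, 1 = Fabry disease

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        if self.egfr <= 0:
            raise ValueError(f"eGFR must be > 0, got {self.egfr}")
        if self.fabry not in (0, 1):
            raise ValueError("fabry status must be 0 or 1")


@dataclass(frozen=True)
class IndividualParameters:
    """Individual structural parameters after covariates and random effects."""

    cl: float
    v2: float
    q: float
    v3: float
    ka_intercept: float
    ka_slope: float
    alag: float
    f1: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl", "v2", "v3", "ka_intercept", "f1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.q < 0 or self.alag < 0:
            raise ValueError("q and alag must be >= 0")
        # Ka(t) must stay positive over the whole capped TAD range; clamping
        # would silently change the model, so invalid slopes are rejected.
        ka_end = self.ka_intercept + self.ka_slope * TAD_CAP_H
        if ka_end <= 0:
            raise ValueError(
                f"Ka(t) = {self.ka_intercept} + {self.ka_slope}*t is not positive "
                f"over [0, {TAD_CAP_H:g}] h (Ka(24) = {ka_end:g})"
            )


@dataclass(frozen=True)
class DoseEvent:
    time: float  # h
    amount: float  # mg free-base equivalent

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")


@dataclass(frozen=True)
class DialysisSession:
    start: float  # h
    duration: float  # h
    cld: float  # session dialysis clearance (L/h)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("session start must be >= 0")
        if self.duration <= 0:
            raise ValueError("session duration must be > 0")
        if self.cld < 0:
            raise ValueError("session CLD must be >= 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class EventSchedule:
    """Time-ordered dose events and non-overlapping dialysis sessions."""

    doses: tuple[DoseEvent, ...]
    sessions: tuple[DialysisSession, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "sessions", tuple(self.sessions))
        dose_times = [d.time for d in self.doses]
        if any(t2 <= t1 for t1, t2 in zip(dose_times, dose_times[1:])):
            raise ValueError("dose times must be strictly increasing")
        starts = [s.start for s in self.sessions]
        if any(t2 <= t1 for t1, t2 in zip(starts, starts[1:])):
            raise ValueError("session starts must be strictly increasing")
        for s1, s2 in zip(self.sessions, self.sessions[1:]):
            if s2.start < s1.end:
                raise ValueError(
                    f"dialysis sessions overlap: [{s1.start}, {s1.end}) and "
                    f"[{s2.start}, {s2.end})"
                )

    def cld_at(self, t: float) -> float:
        for s in self.sessions:
            if s.start <= t < s.end:
                return s.cld
        return 0.0


@dataclass
class ConcentrationProfile:
    """Sampled concentration-time data for one subject and matrix."""

    times: np.ndarray  # h, non-decreasing
    values: np.ndarray  # ng/mL; NaN where BLQ-withheld or missing
    lloq: float  # ng/mL
    matrix: str = "plasma"  # plasma | inlet | outlet | dialysate | urine
    dose_mg: float | None = None
    blq: np.ndarray | None = None  # True where the sample was below LLOQ

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("sample times must be non-decreasing")
        if self.lloq <= 0:
            raise ValueError("lloq must be > 0")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("concentrations must be >= 0 where present")
        if self.blq is None:
            self.blq = np.zeros(self.times.shape, dtype=bool)
        else:
            self.blq = np.asarray(self.blq, dtype=bool)


# ---------------------------------------------------------------------------
# covariate model
# ---------------------------------------------------------------------------


def wtco(weight: float) -> float:
    """Weight capped at and normalised to 70 kg."""
    return min(weight, WEIGHT_CAP_KG) / WEIGHT_CAP_KG


def renal_function_factor(fixed: FixedEffects, egfr: float) -> float:
    """Piecewise-linear eGFR effect on CL, constant above 120, 1 at the reference."""
    eff = fixed.egfr_intercept + fixed.egfr_slope * min(egfr, EGFR_CAP)
    ref = fixed.egfr_intercept + fixed.egfr_slope * min(fixed.egfr_ref, EGFR_CAP)
    return eff / ref


def derive_individual_parameters(
    fixed: FixedEffects,
    cov: CovariateSet,
    etas: Sequence[float] | dict | None = None,
) -> IndividualParameters:
    """Apply the covariate model and random effects to the fixed effects.

    ``etas`` holds the log-normal random effects as a mapping or sequence
    ordered ``(cl, v2, ka_slope, ka_intercept)``; omitted entries are zero
    (population-typical subject).
    """
    if etas is None:
        eta = {"cl": 0.0, "v2": 0.0, "ka_slope": 0.0, "ka_intercept": 0.0}
    elif isinstance(etas, dict):
        eta = {k: float(etas.get(k, 0.0)) for k in ("cl", "v2", "ka_slope", "ka_intercept")}
    else:
        vals = list(etas) + [0.0] * (4 - len(etas))
        eta = dict(zip(("cl", "v2", "ka_slope", "ka_intercept"), map(float, vals)))

    wt = wtco(cov.weight)
    f_renal = renal_function_factor(fixed, cov.egfr)
    cl = (fixed.cl * wt ** fixed.allometric_cl * f_renal
          * fixed.fd_cl ** cov.fabry * math.exp(eta["cl"]))
    v2 = (fixed.v2 * wt ** fixed.allometric_v
          * fixed.fd_v2 ** cov.fabry * math.exp(eta["v2"]))
    q = fixed.q * wt ** fixed.allometric_cl
    v3 = fixed.v3 * wt ** fixed.allometric_v
    ka_slope = fixed.ka_slope * math.exp(eta["ka_slope"])
    ka_intercept = fixed.ka_intercept * math.exp(eta["ka_intercept"])

    for name, value in (("CL", cl), ("V2", v2), ("V3", v3),
                        ("Ka_intercept", ka_intercept)):
        if value <= 0 or not math.isfinite(value):
            raise ValueError(
                f"derived {name} = {value:g} is not positive; offending inputs: "
                f"weight={cov.weight}, eGFR={cov.egfr}, etas={eta}"
            )
    return IndividualParameters(
        cl=cl, v2=v2, q=q, v3=v3,
        ka_intercept=ka_intercept, ka_slope=ka_slope,
        alag=fixed.alag, f1=fixed.f1,
    )


def absorption_rate(ind: IndividualParameters, time_after_dose: float) -> float:
    """First-order absorption rate Ka at a given time after dose (TAD >= ALAG)."""
    if time_after_dose < ind.alag:
        raise ValueError(
            f"absorption is inactive before the lag ({time_after_dose} < {ind.alag} h)"
        )
    tadco = min(time_after_dose, TAD_CAP_H)
    ka = ind.ka_intercept + ind.ka_slope * tadco
    if ka <= 0:
        raise ValueError(f"Ka({time_after_dose:g} h) = {ka:g} is not positive")
    return ka


# ---------------------------------------------------------------------------
# numerical simulator
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Plasma profile plus compartment amounts and elimination ledgers (mg)."""

    profile: ConcentrationProfile
    times: np.ndarray
    depot: np.ndarray
    central: np.ndarray
    peripheral: np.ndarray
    eliminated_baseline: np.ndarray  # cumulative, via CL
    eliminated_dialysis: np.ndarray  # cumulative, via CLD
    administered: float  # total F1-scaled dose entering the depot by t_end
    dosed: np.ndarray = field(repr=False, default=None)  # cumulative by time
    final_state: np.ndarray = field(repr=False, default=None)

    @property
    def total_mass(self) -> np.ndarray:
        return (self.depot + self.central + self.peripheral
                + self.eliminated_baseline + self.eliminated_dialysis)


def _rhs_factory(ind: IndividualParameters, last_dose: float | None, cld: float):
    k12 = ind.q / ind.v2
    k21 = ind.q / ind.v3 if ind.v3 > 0 else 0.0
    k10 = ind.cl / ind.v2
    kd = cld / ind.v2
    kai, kas = ind.ka_intercept, ind.ka_slope

    def rhs(t: float, y: np.ndarray) -> list[float]:
        if last_dose is None:
            ka = 0.0
        else:
            tad = t - last_dose
            ka = kai + kas * (tad if tad < TAD_CAP_H else TAD_CAP_H)
        a1, a2, a3 = y[0], y[1], y[2]
        absorb = ka * a1
        return [
            -absorb,
            absorb - (k10 + kd + k12) * a2 + k21 * a3,
            k12 * a2 - k21 * a3,
            k10 * a2,
            kd * a2,
        ]

    return rhs


def simulate_profile(
    ind: IndividualParameters,
    schedule: EventSchedule,
    output_times: Sequence[float],
    *,
    lloq: float = 5.88,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    y0: np.ndarray | None = None,
    t0: float = 0.0,
    method: str = "LSODA",
) -> SimulationResult:
    """Event-driven numerical solution of the depot-central-peripheral system.

    Integrates segment-by-segment with hard stops at every dose time, lag
    expiry, TAD-cap kink, and dialysis boundary, so the discontinuous
    clearance and the piecewise-linear Ka never cross an integrator step.
    State vector: (depot, central, peripheral, cum. baseline elim.,
    cum. dialysis elim.), all in mg.
    """
    output_times = np.asarray(output_times, dtype=float)
    if output_times.size == 0:
        raise ValueError("output_times must be nonempty")
    if np.any(np.diff(output_times) < 0):
        raise ValueError("output_times must be non-decreasing")
    if output_times[0] < t0:
        raise ValueError("output_times must start at or after t0")
    t_end = float(output_times[-1])

    # breakpoints: every structural discontinuity in the coefficients
    cuts = {t0, t_end}
    bolus_at: dict[float, float] = {}
    for d in schedule.doses:
        for t in (d.time, d.time + ind.alag, d.time + TAD_CAP_H):
            if t0 < t < t_end:
                cuts.add(t)
        t_in = d.time + ind.alag
        if t0 <= t_in < t_end and d.amount > 0:
            bolus_at[t_in] = bolus_at.get(t_in, 0.0) + d.amount * ind.f1
    for s in schedule.sessions:
        for t in (s.start, s.end):
            if t0 < t < t_end:
                cuts.add(t)
    grid = np.array(sorted(cuts))

    y = np.zeros(5) if y0 is None else np.array(y0, dtype=float)
    administered = float(sum(bolus_at.values()))
    out_t: list[float] = []
    out_y: list[np.ndarray] = []

    def record(t: float, state: np.ndarray) -> None:
        out_t.append(t)
        out_y.append(state.copy())

    dose_times = np.array([d.time for d in schedule.doses])

    for a, b in zip(grid[:-1], grid[1:]):
        if a in bolus_at:
            y[0] += bolus_at[a]
        mask = (output_times >= a) & (output_times < b)
        t_eval = output_times[mask]
        mid = 0.5 * (a + b)
        prior = dose_times[dose_times <= a + 1e-12]
        last_dose = float(prior[-1]) if prior.size else None
        # absorption only runs once the lag of the governing dose has expired
        if last_dose is not None and mid < last_dose + ind.alag:
            last_dose_eff = None
        else:
            last_dose_eff = last_dose
        cld = schedule.cld_at(mid)
        rhs = _rhs_factory(ind, last_dose_eff, cld)
        if y[0] <= 0 and last_dose_eff is None and not np.any(y[:3] > 0):
            # nothing in the system yet: skip integration
            for t in t_eval:
                record(float(t), y)
            continue
        # the segment end is always evaluated so the hand-off state is exact
        t_eval_full = np.append(t_eval, b)
        sol = solve_ivp(rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval_full, dense_output=False)
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{a:g}, {b:g}] h "
                f"(last dose {last_dose}, CLD {cld:g}): {sol.message}"
            )
        for t, col in zip(sol.t[:-1], sol.y.T[:-1]):
            record(float(t), col)
        y = sol.y[:, -1].copy()

    # endpoint samples (t == t_end are excluded by the half-open segments)
    for t in output_times[output_times >= t_end]:
        record(float(t), y)

    out_t_arr = np.array(out_t)
    out_y_arr = np.array(out_y).T
    # output_times may contain duplicates or endpoint values; align exactly
    if out_t_arr.size != output_times.size:
        # interpolate any missed points (duplicated breakpoints)
        out_y_arr = np.vstack([
            np.interp(output_times, out_t_arr, out_y_arr[i]) for i in range(5)
        ])
        out_t_arr = output_times
    conc = out_y_arr[1] / ind.v2 * MG_PER_L_TO_NG_PER_ML
    # integrator noise can leave ~atol-scale negatives around zero
    floor = -1e-6 * max(float(np.max(conc)), 1.0)
    if np.min(conc) < floor:
        raise RuntimeError(f"negative concentration {np.min(conc):g} exceeds tolerance")
    conc = np.clip(conc, 0.0, None)
    profile = ConcentrationProfile(
        times=out_t_arr, values=conc, lloq=lloq, matrix="plasma",
        dose_mg=float(sum(d.amount for d in schedule.doses)) or None,
    )
    bolus_times = np.array(sorted(bolus_at))
    bolus_amounts = np.array([bolus_at[t] for t in sorted(bolus_at)])
    dosed = np.array([float(bolus_amounts[bolus_times <= t].sum())
                      for t in out_t_arr])
    return SimulationResult(
        profile=profile,
        times=out_t_arr,
        depot=out_y_arr[0],
        central=out_y_arr[1],
        peripheral=out_y_arr[2],
        eliminated_baseline=out_y_arr[3],
        eliminated_dialysis=out_y_arr[4],
        administered=administered,
        dosed=dosed,
        final_state=y,
    )


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------


def closed_form_single_dose(
    ind: IndividualParameters,
    dose: float,
    times: Sequence[float],
    *,
    lloq: float = 5.88,
) -> ConcentrationProfile:
    """Exact single-dose solution for constant Ka, no dialysis.

    Solves the linear depot/central/peripheral system by eigendecomposition;
    degenerate spectra (Ka equal to a disposition eigenvalue) are rejected
    rather than silently perturbed.
    """
    if ind.ka_slope != 0.0:
        raise ValueError("closed form requires a constant Ka (ka_slope = 0)")
    times = np.asarray(times, dtype=float)
    ka = ind.ka_intercept
    k10 = ind.cl / ind.v2
    k12 = ind.q / ind.v2
    k21 = ind.q / ind.v3 if ind.v3 > 0 else 0.0
    a_matrix = np.array([
        [-ka, 0.0, 0.0],
        [ka, -(k10 + k12), k21],
        [0.0, k12, -k21],
    ])
    lam, vec = np.linalg.eig(a_matrix)
    if np.min(np.abs(lam[:, None] - lam[None, :]) + np.eye(3)) < 1e-10:
        raise ValueError(
            "degenerate case: Ka coincides with a disposition eigenvalue; "
            "perturb Ka slightly or use the numerical simulator"
        )
    a0 = np.array([dose * ind.f1, 0.0, 0.0])
    coef = np.linalg.solve(vec, a0)
    tprime = np.clip(times - ind.alag, 0.0, None)
    amounts = (vec @ (coef[:, None] * np.exp(lam[:, None] * tprime[None, :]))).real
    central = np.where(times >= ind.alag, amounts[1], 0.0)
    conc = np.clip(central, 0.0, None) / ind.v2 * MG_PER_L_TO_NG_PER_ML
    return ConcentrationProfile(times=times, values=conc, lloq=lloq,
                                matrix="plasma", dose_mg=dose)


def disposition_eigenvalues(ind: IndividualParameters) -> tuple[float, float]:
    """(alpha, beta) macro rate constants of the two-compartment disposition."""
    k10 = ind.cl / ind.v2
    k12 = ind.q / ind.v2
    k21 = ind.q / ind.v3 if ind.v3 > 0 else 0.0
    s = k10 + k12 + k21
    p = k10 * k21
    disc = math.sqrt(max(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return alpha, beta


# ---------------------------------------------------------------------------
# naive-pooled fitting (parameter-recovery testing only)
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    estimate: FixedEffects
    cost: float  # half the pooled sum of squared log residuals
    n_obs: int
    n_iterations: int
    success: bool
    message: str


def fit_pooled(
    datasets: Sequence[tuple[ConcentrationProfile, EventSchedule, CovariateSet]],
    init: FixedEffects,
    *,
    fit_params: Sequence[str] = ("cl", "v2", "q", "v3", "ka_intercept"),
    max_nfev: int = 200,
) -> FitResult:
    """Naive-pooled least squares on log concentrations.

    All subjects share the population parameters (etas are ignored); the
    optimiser works on log-transformed thetas so positivity is structural.
    This is a parameter-recovery testing device, not a mixed-effects
    estimator.
    """
    from scipy.optimize import least_squares

    if len(datasets) == 0:
        raise ValueError("at least one concentration profile is required")
    obs_t, obs_logc, obs_sched, obs_cov = [], [], [], []
    n_obs = 0
    for profile, schedule, cov in datasets:
        keep = np.isfinite(profile.values) & (profile.values > 0)
        if not np.any(keep):
            continue
        obs_t.append(profile.times[keep])
        obs_logc.append(np.log(profile.values[keep]))
        obs_sched.append(schedule)
        obs_cov.append(cov)
        n_obs += int(keep.sum())
    if n_obs < len(fit_params):
        raise ValueError(
            f"insufficient data: {n_obs} observations for {len(fit_params)} parameters"
        )

    x0 = np.log([getattr(init, p) for p in fit_params])

    def residuals(x: np.ndarray) -> np.ndarray:
        fixed = replace(init, **{p: math.exp(v) for p, v in zip(fit_params, x)})
        res = []
        for t, logc, schedule, cov in zip(obs_t, obs_logc, obs_sched, obs_cov):
            ind = derive_individual_parameters(fixed, cov)
            sim = simulate_profile(ind, schedule, t, rtol=1e-8, atol=1e-10)
            pred = np.clip(sim.profile.values, 1e-12, None)
            res.append(np.log(pred) - logc)
        return np.concatenate(res)

    sol = least_squares(residuals, x0, max_nfev=max_nfev, xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RuntimeError(
            f"pooled fit did not converge after {sol.nfev} evaluations: {sol.message}"
        )
    estimate = replace(init, **{p: math.exp(v) for p, v in zip(fit_params, sol.x)})
    return FitResult(
        estimate=estimate,
        cost=float(sol.cost),
        n_obs=n_obs,
        n_iterations=int(sol.nfev),
        success=bool(sol.success),
        message=str(sol.message),
    )
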