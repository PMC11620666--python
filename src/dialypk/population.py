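"""Virtual cohorts for Monte-Carlo regimen evaluation.

Two cohorts of virtual Fabry subjects are simulated: one with normal renal
function (weight ~ Normal(72.5, 15.4) kg, eGFR ~ Normal(87.8, 31.7)
mL/min/1.73 m2) and one with ESRD on dialysis (same weight distribution, eGFR
~ Uniform(5, 15)).  Dialysis clearance varies both between and within
subjects with no predictable pattern, so each ESRD subject carries a vector
of per-session CLD values drawn independently from a uniform range whose
default (6.01-12.3 L/h) spans the observed single-dose study extremes.

Normal covariate draws are truncated by resampling (weight to [40, 130] kg,
NRF eGFR to [30, 200]) so the marginal shape inside the bounds is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CovariateSet, OmegaSpec

__all__ = [
    "CohortSpec",
    "VirtualSubject",
    "nrf_cohort_spec",
    "esrd_cohort_spec",
    "sample_cohort",
    "sample_session_cld",
    "cohort_to_frame",
    "cohort_from_frame",
    "DEFAULT_CLD_RANGE",
]

#: observed per-session dialysis clearance extremes (L/h)
DEFAULT_CLD_RANGE = (6.01, 12.3)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling recipe for one virtual cohort."""

    n: int
    weight_mean: float = 72.5  # kg
    weight_sd: float = 15.4
    weight_bounds: tuple[float, float] = (40.0, 130.0)
    egfr_dist: str = "normal"  # normal | uniform
    egfr_mean: float = 87.8  # normal: mean; uniform: ignored
    egfr_sd: float = 31.7
    egfr_bounds: tuple[float, float] = (30.0, 200.0)  # normal truncation
    egfr_range: tuple[float, float] = (5.0, 15.0)  # uniform support
    fabry: int = 1
    cld_range: tuple[float, float] | None = None  # L/h; None = no dialysis draws
    n_sessions: int = 6  # per-subject CLD draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.weight_sd < 0 or self.egfr_sd < 0:
            raise ValueError("distribution sds must be >= 0")
        if self.egfr_dist not in ("normal", "uniform"):
            raise ValueError(f"unknown eGFR distribution {self.egfr_dist!r}")
        if self.cld_range is not None and not (self.cld_range[0] <= self.cld_range[1]):
            raise ValueError("cld_range low must be <= high")


@dataclass
class VirtualSubject:
    id: int
    covariates: CovariateSet
    etas: dict = field(default_factory=dict)
    cld_draws: np.ndarray | None = None


def nrf_cohort_spec(n: int = 100, seed: int = 0, **overrides) -> CohortSpec:
    """Virtual Fabry subjects with normal renal function (no dialysis)."""
    return CohortSpec(n=n, seed=seed, **overrides)


def esrd_cohort_spec(n: int = 100, seed: int = 0,
                     cld_range: tuple[float, float] = DEFAULT_CLD_RANGE,
                     n_sessions: int = 6, **overrides) -> CohortSpec:
    """Virtual Fabry subjects with ESRD on dialysis (eGFR uniform 5-15)."""
    return CohortSpec(n=n, seed=seed, egfr_dist="uniform",
                      cld_range=cld_range, n_sessions=n_sessions, **overrides)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float], n: int) -> np.ndarray:
    """Resampling-based truncation; preserves the in-bounds shape."""
    if sd == 0:
        if not bounds[0] <= mean <= bounds[1]:
            raise ValueError("degenerate distribution outside truncation bounds")
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        take = keep[: n - filled]
        out[filled: filled + take.size] = take
        filled += take.size
    return out


def sample_cohort(spec: CohortSpec, omega: OmegaSpec) -> list[VirtualSubject]:
    """Draw a reproducible cohort of virtual subjects.

    Random effects on CL and V2 are drawn from the correlated bivariate
    normal implied by ``omega``; Ka slope/intercept etas are independent.
    """
    rng = np.random.default_rng(spec.seed)
    weights = _truncated_normal(rng, spec.weight_mean, spec.weight_sd,
                                spec.weight_bounds, spec.n)
    if spec.egfr_dist == "uniform":
        egfr = rng.uniform(*spec.egfr_range, size=spec.n)
    else:
        egfr = _truncated_normal(rng, spec.egfr_mean, spec.egfr_sd,
                                 spec.egfr_bounds, spec.n)

    cov_matrix = omega.cl_v2_covariance()
    eta_clv2 = rng.multivariate_normal([0.0, 0.0], cov_matrix, size=spec.n,
                                       method="cholesky" if _is_pd(cov_matrix) else "svd")
    eta_kas = rng.normal(0.0, np.sqrt(omega.var_eta_ka_slope), size=spec.n)
    eta_kai = rng.normal(0.0, np.sqrt(omega.var_eta_ka_intercept), size=spec.n)

    subjects = []
    for i in range(spec.n):
        cld = None
        if spec.cld_range is not None:
            cld = rng.uniform(spec.cld_range[0], spec.cld_range[1],
                              size=spec.n_sessions)
        subjects.append(VirtualSubject(
            id=i + 1,
            covariates=CovariateSet(weight=float(weights[i]),
                                    egfr=float(egfr[i]),
                                    fabry=spec.fabry),
            etas={"cl": float(eta_clv2[i, 0]), "v2": float(eta_clv2[i, 1]),
                  "ka_slope": float(eta_kas[i]), "ka_intercept": float(eta_kai[i])},
            cld_draws=cld,
        ))
    return subjects


def _is_pd(matrix: np.ndarray) -> bool:
    return bool(np.min(np.linalg.eigvalsh(matrix)) > 1e-12)


def sample_session_cld(cld_range: tuple[float, float], n_sessions: int,
                       seed: int) -> np.ndarray:
    """Independent uniform per-session dialysis clearances (L/h)."""
    low, high = cld_range
    if not low <= high:
        raise ValueError("cld_range low must be <= high")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=n_sessions)


def cohort_to_frame(subjects: list[VirtualSubject]) -> pd.DataFrame:
    """One row per subject plus one row per session CLD draw."""
    rows = []
    for s in subjects:
        rows.append({
            "id": s.id, "row": "subject", "session": np.nan,
            "weight": s.covariates.weight, "egfr": s.covariates.egfr,
            "fabry": s.covariates.fabry,
            "eta_cl": s.etas.get("cl", 0.0), "eta_v2": s.etas.get("v2", 0.0),
            "eta_ka_slope": s.etas.get("ka_slope", 0.0),
            "eta_ka_intercept": s.etas.get("ka_intercept", 0.0),
            "cld": np.nan,
        })
        if s.cld_draws is not None:
            for j, cld in enumerate(s.cld_draws):
                rows.append({"id": s.id, "row": "session", "session": j + 1,
                             "weight": np.nan, "egfr": np.nan, "fabry": np.nan,
                             "eta_cl": np.nan, "eta_v2": np.nan,
                             "eta_ka_slope": np.nan, "eta_ka_intercept": np.nan,
                             "cld": float(cld)})
    return pd.DataFrame(rows)


def cohort_from_frame(frame: pd.DataFrame) -> list[VirtualSubject]:
    subjects = []
    for sid, grp in frame.groupby("id", sort=True):
        head = grp[grp["row"] == "subject"].iloc[0]
        sess = grp[grp["row"] == "session"].sort_values("session")
        cld = sess["cld"].to_numpy(dtype=float) if len(sess) else None
        subjects.append(VirtualSubject(
            id=int(sid),
            covariates=CovariateSet(weight=float(head["weight"]),
                                    egfr=float(head["egfr"]),
                                    fabry=int(head["fabry"])),
            etas={"cl": float(head["eta_cl"]), "v2": float(head["eta_v2"]),
                  "ka_slope": float(head["eta_ka_slope"]),
                  "ka_intercept": float(head["eta_ka_intercept"])},
            cld_draws=cld,
        ))
    return subjects
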