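# Methods

## Structural model

Drug amounts follow a linear three-state system: an oral depot, a central
compartment (volume V2/F), and a peripheral compartment (V3/F) connected by
intercompartmental clearance Q/F. Absorption is first order with a lag ALAG
and a rate constant that grows linearly with time after dose up to a 24-h
cap:

    Ka(t) = Ka_intercept + Ka_slope · min(TAD, 24 h)

Elimination is first order from the central compartment with clearance

    CL_elim(t) = CL/F + CL_D · 1[dialysis session active at t]

where CL_D is the session-specific apparent dialysis clearance. With multiple
doses, TAD is measured from the most recent dose (the standard convention for
time-varying absorption). Parameter sets for which Ka(t) ≤ 0 anywhere on
[0, 24] h are rejected rather than clamped: clamping would silently change
the model.

### Covariate model

- Weight: allometric scaling on a weight ratio capped at 70 kg,
  WTCO = min(WT, 70)/70, exponent 0.75 on CL/F and Q/F and 1 on V2/F and
  V3/F. Above 70 kg body weight has no further effect.
- Renal function: CL/F is multiplied by a piecewise-linear factor
  f(eGFR) = (a + b·min(eGFR, 120)) normalised to 1 at the reference eGFR of
  90 mL/min/1.73 m². The factor applies to *total* CL/F — non-renal
  elimination declines proportionally with renal function — while the renal
  *fraction* of the eliminated mass is a separate arm-level constant used by
  the study generator (0.77 at normal renal function, 0.03 in ESRD). These
  two choices are deliberately decoupled: total clearance falls ~7-fold from
  eGFR 90 to eGFR 10, far more than the renal fraction alone could explain,
  which is consistent with the observed urinary recoveries.
- Fabry status: binary multiplicative effects on CL/F and V2/F.

Between-subject variability is log-normal on CL/F and V2/F (correlated) and
on the Ka slope and intercept. Residual error is combined
proportional + additive on observed concentrations.

## Default parameters and their calibration

The defaults in `dialypk.params` were fixed once against the published
observed single-dose summaries (medians and ranges of the noncompartmental
parameters) and not revisited:

| parameter | default | unit | anchor |
|---|---|---|---|
| CL/F | 16.3 | L/h | observed NRF median apparent clearance |
| V2/F | 20 | L | with V3, Q: NRF terminal t½ ≈ 4.2 h (observed 2.0–5.9) |
| Q/F | 6 | L/h | — |
| V3/F | 25 | L | ESRD terminal t½ ≈ 16 h (observed 14.7–31) |
| Ka intercept | 0.30 | 1/h | NRF t_max ≈ 2.5 h, ESRD ≈ 4.5 h |
| Ka slope | 0.025 | 1/h per h | — |
| ALAG | 0.7 | h | — |
| eGFR slope/intercept | 0.010812 / 0.026886 | — | CL/F(eGFR 10) ≈ 2.2 L/h |
| FD on CL, V2 | 0.85 / 1.10 | — | modest binary effects; cancel in ESRD:NRF ratios since both cohorts are Fabry |
| ω²(CL), ω²(V2), ρ | 0.09, 0.0625, 0.4 | — | ~30%/25% CV, plausible richly-sampled-model values |
| ω²(Ka slope/int) | 0.09 | — | ~30% CV |
| σ_prop, σ_add | 0.20, 2.94 | —, ng/mL | additive term = LLOQ/2; yields realistic late-sample BLQ rates |
| F1 | 1 | — | dose-independent default; the dose-dependence hook exists but no published values constrain it |

One tension is unresolvable within a two-compartment model: the observed NRF
terminal half-life (~3.5 h) implies essentially complete washout by 48 h, yet
steady-state simulations in the source analysis show an appreciable fraction
of NRF subjects with quantifiable 48-h troughs, which requires a deeper,
slower phase below the assay limit. The defaults honour the printed
noncompartmental values; consequently the simulated reference cohort's
%C_trough-BLQ runs higher than the source analysis reports. Comparative
conclusions across regimens (GMR ordering, which regimens overshoot C_max or
undershoot C_avg) are unaffected.

## Virtual populations

Cohorts of virtual Fabry subjects: weight ~ N(72.5, 15.4) kg truncated to
[40, 130] by resampling; eGFR ~ N(87.8, 31.7) truncated to [30, 200] for the
NRF cohort and U(5, 15) for ESRD. Truncation by resampling preserves the
in-bounds shape; it shifts the weight mean by ≈ +0.7 kg (documented bound
1.5 kg). Etas are drawn once per subject — no inter-occasion variability.
Per-session dialysis clearances are independent U(6.01, 12.3) L/h draws (the
observed extremes), varying both within and between subjects.

## Regimen simulation

Calendars are weekly: dialysis weekday patterns MWF, MTh, SuTu, SuW with 4-h
sessions; dosing intervals QOD, Q3D, Q4D, Q6D, QW, Q12D, QOW. Doses are
anchored 24 h before the session on the pattern's first weekday (the timing
the single-dose study confirmed), so t = 0 is a dose and the anchoring
session starts at +24 h.

Steady state: subjects are simulated cycle by cycle, where a cycle is
lcm(interval, 168 h), until the terminal-interval AUC changes by < 0.1%
between cycles (hard cap 12 cycles; non-attainment flags the result). The
subject's session CLD draws are laid over one cycle and repeated, so the
system is periodic and a steady state exists; with fully independent draws
every cycle the interval AUC would fluctuate a few percent forever and no
criterion could converge. Within-cycle sessions still get distinct CLDs. The
returned terminal interval is on a ≤ 0.25 h grid.

Exposure metrics per subject: C_max and t_max from the grid (first occurrence
on ties), C_trough as the concentration exactly at the interval end, AUC_τ by
trapezoid, C_avg = AUC_τ/τ. Cohort summaries: % of subjects with C_max above
10 μM — converted with the free-base molar mass (C6H13NO4, 163.17 g/mol →
1631.7 ng/mL; the constant is configurable for other salt conventions) — and
% with C_trough below the 5.88 ng/mL LLOQ.

Bioequivalence: GMR (test:reference) on the log scale with a Welch two-sample
90% CI; the cohorts are independent sets of virtual subjects, so a paired
interval would be wrong. BE is declared when the CI lies inside [0.80, 1.25].

## Noncompartmental analysis

- BLQ rules: descriptive context sets every BLQ value to missing; parameter
  context sets embedded (between two quantifiable values) and trailing BLQ to
  missing. Leading pre-dose BLQ anchors the curve at zero — the published
  rules do not cover this case and an AUC needs an origin. Missing values are
  never imputed.
- AUC: linear trapezoid by default, linear-up/log-down by flag; endpoints
  inside the sampled range are interpolated (log-interpolation on declining
  positive segments when the log method is chosen).
- λ_z: log-linear regression on the contiguous terminal subset (≥ 3
  quantifiable post-t_max points, the C_max sample excluded) maximising
  adjusted R²; a fit with adjusted R² < 0.80 is flagged unreliable. Slope ≥ 0
  or < 3 eligible points → not estimable, and downstream parameters are
  reported missing.
- Plasma: AUC_0–∞ = AUC_0–t + C_last/λ_z; when more than 50% of AUC_0–∞ is
  extrapolated, the extrapolation-dependent parameters (AUC_0–∞, t_½, CL/F,
  V_z/F) are suppressed from summaries.
- Dialysis: ED = (AUC_inlet − AUC_outlet)/AUC_inlet × 100 over the session
  window; P = AUC_inlet/duration; A_eD = Σ C_D·volume over dialysate
  collections; F_eD = 100·A_eD/dose; CL_D = A_eD/(P·duration), i.e. the
  recovery clearance A_eD/AUC_inlet — chosen over the flow-based definition
  because it uses only quantities the protocol measures. An outlet AUC above
  the inlet AUC yields a negative ED with a warning flag, not a clipped
  value: that is a data inconsistency the analyst must see.
- Urine: A_e = Σ volume·concentration, F_e = 100·A_e/dose, CL_R = A_e/AUC
  over the matching span.

## Synthetic study generator

The generator reproduces the Phase I design on one continuous timeline per
ESRD subject: dose at t = 0 with dialysis at 24–28 h (period 1), routine
maintenance sessions during the ≥ 8-day washout, and a second dose at 192 h
with dialysis starting 5 min post-dose (period 2) — so the period-2 pre-dose
carry-over arises naturally and is verified to stay below 5% of the
period-1 C_max. Sampling follows the protocol clocks exactly (plasma 0–72 h;
dialyzer inlet/outlet at 5 min after session start, hourly, and 5 min past
session end; daily urine intervals). NRF controls are weight-matched to the
ESRD subjects and dosed once.

Generative rules the protocol does not constrain, exposed as design
parameters:

- Inlet concentration = simulated plasma concentration; outlet =
  inlet·(1 − CL_D/Q_p) with dialyzer plasma-side flow Q_p = 18 L/h. This
  makes the per-pass extraction exactly CL_D/Q_p, consistent with the ODE's
  mass removal, and gives ED values in the tens of percent.
- Dialysate: total spent dialysate pooled per session by default (flow
  18 L/h); finer sub-interval collection is available. With hourly
  sub-collections the trailing hour falls below the 100 ng/mL dialysate
  LLOQ for weak sessions and F_eD is undercounted — a censoring feature of
  the design, not of the analysis, and the reason pooled collection is the
  default.
- Urine volumes: 1.6 L/day (NRF) and 0.25 L/day residual diuresis (ESRD);
  with the renal fractions above this reproduces urinary recoveries of ~77%
  (NRF) and ~1–3% (ESRD).

The truth ledger records each subject's individual parameters, session
clearances, and cumulative renal/metabolic/dialysis mass, so ED, F_eD, F_e
and CL/F can be audited against the generating model (`end_to_end_check`).
The CL/F audit is restricted to NRF subjects: in ESRD periods a dialysis
session removes mass during the profile, so dose/AUC_0–∞ estimates the
average total clearance, not the baseline CL/F — a real property of NCA on
dialysis data, not an implementation artefact.

## Numerical choices

- Integration: segment-wise LSODA with hard stops at every dose time, lag
  expiry, 24-h TAD kink and dialysis boundary; rtol 1e-8/atol 1e-10 for
  oracle-grade work, rtol 1e-6 for Monte-Carlo scenario runs. The segment
  endpoint is always evaluated so the hand-off state is exact.
- The closed-form solution uses the eigendecomposition of the 3×3 system
  matrix; a depot rate equal to a disposition eigenvalue is a degenerate case
  and is rejected (tolerance 1e-10 on eigenvalue separation).
- ~atol-scale negative concentrations from the integrator are clamped to
  zero; anything below −1e-6 of the profile maximum raises an error.
- Pooled fitting works on log-transformed parameters (positivity by
  construction) against log concentrations with `scipy.optimize.least_squares`;
  it is a parameter-recovery device, deliberately not a mixed-effects
  estimator.
- Problem sizes: the scenario grid uses 100 virtual subjects per cohort and
  the synthetic study 12 subjects, matching the source design; property
  checks use single subjects and dense grids.

## Known limitations

- The supplementary parameter estimates of the source popPK model are not
  reproduced here; defaults are calibrated to the printed observed summaries,
  so absolute scenario percentages carry that calibration uncertainty (the
  binomial Monte-Carlo error alone is ~4–5 points at n = 100).
- Two compartments cannot represent the deep tissue phase discussed above;
  late-time troughs are biased low.
- No inter-occasion variability, no dose-dependent F1 by default, no
  within-session time-course of dialyzer efficiency, and no tissue PBPK layer
  (out of scope).
- The synthetic study emulates the stated marginal covariate distributions
  and protocol clocks, not real demographic joint distributions, assay drift,
  or dialyzer membrane physics — passing its audits shows the analysis chain
  is correct on model-generated data, not that the model captures every
  feature of real patients.
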