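"""Structural model, covariate model, simulator and closed-form oracle."""

import math
from dataclasses import replace

import numpy as np
import pytest

from dialypk.model import (
    CovariateSet,
    DialysisSession,
    DoseEvent,
    EventSchedule,
    FixedEffects,
    IndividualParameters,
    OmegaSpec,
    absorption_rate,
    closed_form_single_dose,
    derive_individual_parameters,
    disposition_eigenvalues,
    fit_pooled,
    simulate_profile,
    wtco,
)


class TestCovariateModel:
    def test_weight_capped_before_normalising(self, fixed):
        """Weight above 70 kg contributes exactly the 70 kg factor."""
        assert wtco(80.0) == 1.0
        heavy = derive_individual_parameters(fixed, CovariateSet(weight=80, egfr=90))
        at_cap = derive_individual_parameters(fixed, CovariateSet(weight=70, egfr=90))
        assert heavy.cl == pytest.approx(at_cap.cl)
        assert heavy.v2 == pytest.approx(at_cap.v2)

    def test_renal_effect_constant_above_120(self, fixed):
        hi = derive_individual_parameters(fixed, CovariateSet(weight=70, egfr=150))
        at_cap = derive_individual_parameters(fixed, CovariateSet(weight=70, egfr=120))
        assert hi.cl == pytest.approx(at_cap.cl)

    def test_reference_subject_recovers_theta_cl(self, fixed):
        """Zero etas, no Fabry effect, 70 kg, reference eGFR: CL == theta_CL."""
        ind = derive_individual_parameters(
            fixed, CovariateSet(weight=70, egfr=fixed.egfr_ref, fabry=0))
        assert ind.cl == pytest.approx(fixed.cl, rel=1e-12)
        assert ind.v2 == pytest.approx(fixed.v2, rel=1e-12)

    def test_renal_effect_is_linear_below_cap(self, fixed):
        cl = [derive_individual_parameters(fixed, CovariateSet(weight=70, egfr=g)).cl
              for g in (20.0, 60.0, 100.0)]
        # equal eGFR spacing -> equal CL spacing
        assert cl[1] - cl[0] == pytest.approx(cl[2] - cl[1], rel=1e-9)

    def test_fabry_status_scales_cl_and_v2(self, fixed):
        fd = derive_individual_parameters(fixed, CovariateSet(weight=70, egfr=90, fabry=1))
        no = derive_individual_parameters(fixed, CovariateSet(weight=70, egfr=90, fabry=0))
        assert fd.cl / no.cl == pytest.approx(fixed.fd_cl)
        assert fd.v2 / no.v2 == pytest.approx(fixed.fd_v2)

    def test_eta_enters_lognormally(self, fixed):
        ind = derive_individual_parameters(
            fixed, CovariateSet(weight=70, egfr=90), {"cl": 0.5})
        base = derive_individual_parameters(fixed, CovariateSet(weight=70, egfr=90))
        assert ind.cl / base.cl == pytest.approx(math.exp(0.5))

    def test_invalid_covariates_rejected(self):
        with pytest.raises(ValueError):
            CovariateSet(weight=-1.0, egfr=90.0)
        with pytest.raises(ValueError):
            CovariateSet(weight=70.0, egfr=0.0)


class TestAbsorptionRate:
    def test_slope_intercept_arithmetic(self, nrf_ind):
        ind = replace(nrf_ind, ka_intercept=0.2, ka_slope=0.01)
        assert absorption_rate(ind, 10.0) == pytest.approx(0.3)

    def test_time_after_dose_capped_at_24(self, nrf_ind):
        assert absorption_rate(nrf_ind, 30.0) == pytest.approx(
            absorption_rate(nrf_ind, 24.0))

    def test_zero_slope_is_constant(self, nrf_ind):
        ind = replace(nrf_ind, ka_slope=0.0)
        assert absorption_rate(ind, 2.0) == absorption_rate(ind, 20.0)

    def test_before_lag_rejected(self, nrf_ind):
        with pytest.raises(ValueError):
            absorption_rate(nrf_ind, nrf_ind.alag / 2.0)

    def test_negative_ka_over_window_rejected(self):
        """Parameter sets with Ka <= 0 anywhere on [0, 24] h are invalid."""
        with pytest.raises(ValueError, match="Ka"):
            IndividualParameters(cl=10, v2=20, q=5, v3=20,
                                 ka_intercept=0.2, ka_slope=-0.02, alag=0.3)


class TestOmegaSpec:
    def test_correlation_bounds(self):
        with pytest.raises(ValueError):
            OmegaSpec(var_eta_cl=0.1, var_eta_v2=0.1, corr_cl_v2=1.5)

    def test_covariance_matrix(self):
        om = OmegaSpec(var_eta_cl=0.09, var_eta_v2=0.04, corr_cl_v2=0.5)
        cov = om.cl_v2_covariance()
        assert cov[0, 1] == pytest.approx(0.5 * 0.3 * 0.2)


class TestSimulatorAgainstOracle:
    def test_matches_closed_form_with_constant_ka(self, nrf_ind):
        ind = replace(nrf_ind, ka_slope=0.0, ka_intercept=0.45)
        schedule = EventSchedule(doses=(DoseEvent(0.0, 123.0),))
        t = np.linspace(0.0, 72.0, 289)
        sim = simulate_profile(ind, schedule, t)
        oracle = closed_form_single_dose(ind, 123.0, t)
        mask = oracle.values > 1e-3
        rel = np.abs(sim.profile.values[mask] - oracle.values[mask]) / oracle.values[mask]
        assert np.max(rel) < 1e-6

    def test_zero_before_lag(self, nrf_ind):
        ind = replace(nrf_ind, ka_slope=0.0, alag=1.0)
        t = np.array([0.0, 0.5, 0.99, 1.5, 3.0])
        prof = closed_form_single_dose(ind, 123.0, t)
        assert np.all(prof.values[t < 1.0] == 0.0)
        assert np.all(prof.values[t > 1.0] > 0.0)

    def test_one_compartment_limit(self, fixed):
        """Q = 0 reduces the closed form to the one-compartment Bateman curve."""
        ind = IndividualParameters(cl=10.0, v2=20.0, q=0.0, v3=15.0,
                                   ka_intercept=1.0, ka_slope=0.0, alag=0.0)
        t = np.linspace(0.1, 48.0, 100)
        prof = closed_form_single_dose(ind, 100.0, t)
        k = ind.cl / ind.v2
        ka = ind.ka_intercept
        bateman = (100.0 * ka / (ind.v2 * (ka - k))
                   * (np.exp(-k * t) - np.exp(-ka * t)) * 1000.0)
        np.testing.assert_allclose(prof.values, bateman, rtol=1e-9)

    def test_degenerate_ka_rejected(self, fixed):
        ind = IndividualParameters(cl=10.0, v2=20.0, q=0.0, v3=15.0,
                                   ka_intercept=0.5, ka_slope=0.0, alag=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            closed_form_single_dose(ind, 100.0, np.linspace(0, 10, 5))

    def test_auc_infinity_equals_dose_over_cl(self, nrf_ind):
        ind = replace(nrf_ind, ka_slope=0.0, ka_intercept=0.5)
        t = np.linspace(0.0, 400.0, 8001)
        prof = closed_form_single_dose(ind, 123.0, t)
        auc = np.trapezoid(prof.values, t)
        assert auc == pytest.approx(123.0 * 1000.0 * ind.f1 / ind.cl, rel=2e-4)


class TestMassBalance:
    def test_total_mass_conserved_with_dialysis(self, esrd_ind):
        schedule = EventSchedule(
            doses=(DoseEvent(0.0, 123.0), DoseEvent(48.0, 123.0)),
            sessions=(DialysisSession(24.0, 4.0, 9.0),
                      DialysisSession(72.0, 4.0, 11.0)))
        t = np.linspace(0.0, 120.0, 241)
        sim = simulate_profile(esrd_ind, schedule, t)
        mask = sim.dosed > 0
        np.testing.assert_allclose(sim.total_mass[mask], sim.dosed[mask], rtol=1e-8)

    def test_everything_eventually_eliminated(self, nrf_ind):
        schedule = EventSchedule(doses=(DoseEvent(0.0, 100.0),))
        t = np.linspace(0.0, 600.0, 121)
        sim = simulate_profile(nrf_ind, schedule, t)
        eliminated = sim.eliminated_baseline[-1] + sim.eliminated_dialysis[-1]
        assert eliminated == pytest.approx(sim.administered, rel=1e-7)

    def test_dialysis_ledger_zero_without_sessions(self, nrf_ind):
        schedule = EventSchedule(doses=(DoseEvent(0.0, 100.0),))
        sim = simulate_profile(nrf_ind, schedule, np.linspace(0, 48, 97))
        assert np.all(sim.eliminated_dialysis == 0.0)


class TestDialysisEffects:
    def test_dialysis_strictly_reduces_auc(self, esrd_ind):
        """Adding a session reduces AUC over any window containing it."""
        t = np.linspace(0.0, 72.0, 289)
        doses = (DoseEvent(0.0, 123.0),)
        base = simulate_profile(esrd_ind, EventSchedule(doses=doses), t)
        with_hd = simulate_profile(
            esrd_ind, EventSchedule(doses=doses,
                                    sessions=(DialysisSession(24.0, 4.0, 9.0),)), t)
        window = (t >= 20.0)
        auc_base = np.trapezoid(base.profile.values[window], t[window])
        auc_hd = np.trapezoid(with_hd.profile.values[window], t[window])
        assert auc_hd < auc_base

    def test_auc_monotone_in_cld(self, esrd_ind):
        t = np.linspace(0.0, 72.0, 289)
        aucs = []
        for cld in (0.0, 6.0, 12.0):
            sched = EventSchedule(doses=(DoseEvent(0.0, 123.0),),
                                  sessions=(DialysisSession(24.0, 4.0, cld),)
                                  if cld > 0 else ())
            sim = simulate_profile(esrd_ind, sched, t)
            aucs.append(np.trapezoid(sim.profile.values, t))
        assert aucs[0] > aucs[1] > aucs[2]

    def test_overlapping_sessions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            EventSchedule(doses=(DoseEvent(0.0, 100.0),),
                          sessions=(DialysisSession(24.0, 4.0, 8.0),
                                    DialysisSession(26.0, 4.0, 8.0)))


class TestSuperposition:
    def test_multiple_doses_superpose(self, nrf_ind):
        """Linear kinetics: the multi-dose profile is the sum of shifted
        single-dose profiles."""
        ind = replace(nrf_ind, ka_slope=0.0, ka_intercept=0.5)
        tau, n_dose = 24.0, 4
        schedule = EventSchedule(
            doses=tuple(DoseEvent(k * tau, 123.0) for k in range(n_dose)))
        t = np.linspace(0.0, n_dose * tau, n_dose * 97)
        sim = simulate_profile(ind, schedule, t)
        total = np.zeros_like(t)
        for k in range(n_dose):
            single = closed_form_single_dose(ind, 123.0, np.clip(t - k * tau, 0, None))
            total += np.where(t >= k * tau, single.values, 0.0)
        scale = np.max(total)
        np.testing.assert_allclose(sim.profile.values / scale, total / scale,
                                   atol=1e-5)


@pytest.fixture(scope="module")
def noise_free_data(fixed):
    schedule = EventSchedule(doses=(DoseEvent(0.0, 123.0),))
    t = np.array([0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24, 36, 48, 72], dtype=float)
    data = []
    for w, g in [(70, 90), (60, 50), (80, 110)]:
        cov = CovariateSet(weight=w, egfr=g)
        ind = derive_individual_parameters(fixed, cov)
        sim = simulate_profile(ind, schedule, t)
        data.append((sim.profile, schedule, cov))
    return data


class TestFitPooled:
    def test_recovers_parameters_within_one_percent(self, fixed, noise_free_data):
        init = replace(fixed, cl=12.0, v2=30.0, q=4.0, v3=18.0, ka_intercept=0.5)
        res = fit_pooled(noise_free_data, init)
        assert res.estimate.cl == pytest.approx(fixed.cl, rel=0.01)
        assert res.estimate.v2 == pytest.approx(fixed.v2, rel=0.01)

    def test_init_at_truth_converges_immediately(self, fixed, noise_free_data):
        res = fit_pooled(noise_free_data, fixed)
        assert res.n_iterations <= 2
        assert res.cost < 1e-12

    def test_insufficient_data_rejected(self, fixed, noise_free_data):
        profile, schedule, cov = noise_free_data[0]
        short = replace(profile)
        short.times = profile.times[:3]
        short.values = profile.values[:3]
        short.blq = profile.blq[:3]
        with pytest.raises(ValueError, match="insufficient"):
            fit_pooled([(short, schedule, cov)], fixed)


class TestEigenvalues:
    def test_terminal_half_life_orders_with_clearance(self, nrf_ind, esrd_ind):
        """Renal impairment prolongs the terminal phase severalfold."""
        t_nrf = math.log(2) / disposition_eigenvalues(nrf_ind)[1]
        t_esrd = math.log(2) / disposition_eigenvalues(esrd_ind)[1]
        assert t_esrd > 3.0 * t_nrf
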