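"""Noncompartmental analysis: BLQ rules, AUC, terminal slope, matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dialypk.model import ConcentrationProfile
from dialypk.nca import (
    auc,
    blq_preprocess,
    lambda_z,
    nca_dialysate,
    nca_plasma,
    nca_urine,
)

LLOQ = 5.88


def _profile(times, values, lloq=LLOQ, blq=None):
    return ConcentrationProfile(times=np.asarray(times, dtype=float),
                                values=np.asarray(values, dtype=float),
                                lloq=lloq, blq=blq)


class TestBLQRules:
    def test_embedded_and_trailing_set_to_missing(self):
        """[predose-BLQ, 10, 4, 12, 3] -> [0, 10, missing, 12, missing]."""
        prof = _profile([0, 1, 2, 3, 4], [0.0, 10.0, 4.0, 12.0, 3.0])
        out = blq_preprocess(prof, context="parameter")
        np.testing.assert_array_equal(out.values[[0, 1, 3]], [0.0, 10.0, 12.0])
        assert np.isnan(out.values[2]) and np.isnan(out.values[4])

    def test_trailing_blq_missing(self):
        prof = _profile([0, 1, 2], [10.0, 8.0, 3.0])
        out = blq_preprocess(prof, context="parameter")
        assert np.isnan(out.values[-1])

    def test_all_quantifiable_unchanged(self):
        prof = _profile([0, 1, 2], [10.0, 8.0, 7.0])
        out = blq_preprocess(prof, context="parameter")
        np.testing.assert_array_equal(out.values, prof.values)

    def test_descriptive_context_blanks_all_blq(self):
        prof = _profile([0, 1, 2], [1.0, 8.0, 3.0])
        out = blq_preprocess(prof, context="descriptive")
        assert np.isnan(out.values[0]) and np.isnan(out.values[2])
        assert out.values[1] == 8.0

    def test_withheld_values_respected_via_flag(self):
        """Generators emit BLQ rows with the value withheld (NaN) and a flag."""
        prof = _profile([0, 1, 2], [np.nan, 8.0, np.nan],
                        blq=np.array([True, False, True]))
        out = blq_preprocess(prof, context="parameter")
        assert out.values[0] == 0.0
        assert np.isnan(out.values[2])


class TestAUC:
    def test_trapezoid_example(self):
        prof = _profile([0, 1, 2], [0.0, 10.0, 10.0])
        assert auc(prof, 0.0, 2.0) == pytest.approx(15.0)

    def test_dense_exponential_matches_integral(self):
        t = np.linspace(0, 24, 121)
        c = 100.0 * np.exp(-0.2 * t)
        prof = _profile(t, c)
        exact = 100.0 / 0.2 * (1 - np.exp(-0.2 * 24))
        assert auc(prof, 0.0, 24.0) == pytest.approx(exact, rel=5e-3)

    def test_log_down_is_exact_on_exponential(self):
        t = np.linspace(0, 24, 25)
        c = 100.0 * np.exp(-0.2 * t)
        prof = _profile(t, c)
        exact = 100.0 / 0.2 * (1 - np.exp(-0.2 * 24))
        assert auc(prof, 0.0, 24.0, method="linear-up/log-down") == pytest.approx(
            exact, rel=1e-12)

    def test_partial_span_with_interpolation(self):
        # profile rises 0->10 over [0, 2] then holds; on [1, 3] the
        # interpolated endpoints are 5 and 10
        prof = _profile([0, 2, 4], [0.0, 10.0, 10.0])
        assert auc(prof, 1.0, 3.0) == pytest.approx(7.5 + 10.0)

    def test_single_point_rejected(self):
        prof = _profile([0, 1], [np.nan, 10.0], blq=np.array([True, False]))
        cleaned = blq_preprocess(prof, context="descriptive")
        with pytest.raises(ValueError):
            auc(cleaned, 0.0, 1.0)

    def test_span_outside_range_rejected(self):
        prof = _profile([0, 1, 2], [1.0, 2.0, 3.0], lloq=0.5)
        with pytest.raises(ValueError, match="outside"):
            auc(prof, 0.0, 5.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_additive_over_subspans(self, seed):
        r = np.random.default_rng(seed)
        t = np.sort(r.uniform(0, 24, 10))
        t[0], t[-1] = 0.0, 24.0
        prof = _profile(t, r.uniform(1, 100, 10), lloq=0.5)
        mid = float(r.uniform(1.0, 23.0))
        total = auc(prof, 0.0, 24.0)
        split = auc(prof, 0.0, mid) + auc(prof, mid, 24.0)
        assert split == pytest.approx(total, rel=1e-9)


class TestLambdaZ:
    def test_pure_exponential(self):
        t = np.array([4.0, 8, 12, 16, 20, 24])
        prof = _profile(t, 100.0 * np.exp(-0.1 * t), lloq=0.01)
        res = lambda_z(prof)
        assert res.lambda_z == pytest.approx(0.1, rel=1e-9)
        assert res.t_half == pytest.approx(6.93, abs=0.01)
        assert res.reliable

    def test_rising_profile_not_estimable(self):
        prof = _profile([0, 2, 4, 6, 8], [1.0, 2.0, 4.0, 8.0, 16.0], lloq=0.01)
        res = lambda_z(prof)
        assert res.lambda_z is None

    def test_too_few_tail_points(self):
        prof = _profile([0, 1, 2], [5.0, 10.0, 8.0], lloq=0.01)
        assert lambda_z(prof).lambda_z is None

    def test_biexponential_terminal_within_2pct(self, nrf_ind):
        """Sampling over >= 3 terminal half-lives recovers the slow eigenvalue."""
        from dialypk.model import disposition_eigenvalues, closed_form_single_dose
        from dataclasses import replace
        ind = replace(nrf_ind, ka_slope=0.0, ka_intercept=2.0)
        beta = disposition_eigenvalues(ind)[1]
        t_half = np.log(2) / beta
        t = np.concatenate([np.linspace(0.5, 8, 10),
                            np.linspace(10, 8 * t_half, 12)])
        prof = closed_form_single_dose(ind, 123.0, t)
        prof.lloq = 1e-6
        res = lambda_z(prof)
        assert res.lambda_z == pytest.approx(beta, rel=0.02)


class TestPlasmaNCA:
    def test_one_compartment_recovery(self):
        """Dense noise-free data: CL/F = dose/AUCinf reproduces the truth."""
        cl, v2, ka, dose = 10.0, 20.0, 1.0, 100.0
        k = cl / v2
        t = np.arange(0.0, 60.0, 0.25)
        c = (dose * ka / (v2 * (ka - k))
             * (np.exp(-k * t) - np.exp(-ka * t)) * 1000.0)
        prof = _profile(t, c, lloq=1e-9)
        res = nca_plasma(prof, dose)
        assert res.cl_f == pytest.approx(cl, rel=0.01)
        assert res.t_half == pytest.approx(np.log(2) / k, rel=0.01)
        assert res.vz_f == pytest.approx(v2, rel=0.01)
        assert not res.extrapolation_exceeded

    def test_heavy_extrapolation_flagged(self):
        """Truncated sampling with > 50% of AUC extrapolated raises the
        suppression flag on all extrapolated parameters."""
        t = np.array([0.0, 1, 2, 3, 4, 5, 6])
        c = 100.0 * np.exp(-0.05 * t)  # t1/2 ~ 14 h, sampled 6 h only
        res = nca_plasma(_profile(t, c, lloq=1e-9), 100.0)
        assert res.pct_extrapolated > 50.0
        assert res.extrapolation_exceeded

    def test_tmax_tie_reports_earlier_time(self):
        t = np.arange(0.0, 7.0)
        c = np.array([0, 10, 10, 8, 6, 4, 2], dtype=float)
        res = nca_plasma(_profile(t, c, lloq=0.1), 100.0)
        assert res.tmax == 1.0

    def test_cmax_restricted_to_24h(self):
        t = np.array([0.0, 2, 24, 30])
        c = np.array([0.0, 50, 20, 60])
        res = nca_plasma(_profile(t, c, lloq=0.1), 100.0)
        assert res.cmax_24h == 50.0


class TestDialysateNCA:
    def test_extraction_ratio_formula(self):
        """AUCinlet 2000, AUCoutlet 500 -> ED = 75%."""
        t = np.array([0.0, 1, 2, 3, 4])
        inlet = _profile(t, np.full(5, 500.0), lloq=1.0)
        outlet = _profile(t, np.full(5, 125.0), lloq=1.0)
        res = nca_dialysate(inlet, outlet, None, 123.0, (0.0, 4.0))
        assert res.auc_inlet == pytest.approx(2000.0)
        assert res.ed_pct == pytest.approx(75.0)

    def test_recovery_clearance_units(self):
        """AeD 20 mg over 4 h at mean plasma 1000 ng/mL -> CLD = 5 L/h."""
        t = np.array([0.0, 1, 2, 3, 4])
        inlet = _profile(t, np.full(5, 1000.0), lloq=1.0)
        outlet = _profile(t, np.full(5, 400.0), lloq=1.0)
        # 20 mg in 120 L = 0.1667 mg/L = 166.7 ng/mL
        records = pd.DataFrame({"conc": [20.0 / 120.0 * 1000.0], "volume": [120.0]})
        res = nca_dialysate(inlet, outlet, records, 123.0, (0.0, 4.0))
        assert res.aed_mg == pytest.approx(20.0)
        assert res.cld == pytest.approx(5.0)
        assert res.fed_pct == pytest.approx(100.0 * 20.0 / 123.0)

    def test_outlet_above_inlet_flagged_not_clipped(self):
        t = np.array([0.0, 2, 4])
        inlet = _profile(t, np.full(3, 100.0), lloq=1.0)
        outlet = _profile(t, np.full(3, 120.0), lloq=1.0)
        res = nca_dialysate(inlet, outlet, None, 123.0, (0.0, 4.0))
        assert res.ed_pct < 0
        assert res.outlet_exceeds_inlet

    def test_window_not_covered_rejected(self):
        t = np.array([0.0, 1, 2])
        inlet = _profile(t, np.full(3, 100.0), lloq=1.0)
        outlet = _profile(t, np.full(3, 50.0), lloq=1.0)
        with pytest.raises(ValueError, match="window"):
            nca_dialysate(inlet, outlet, None, 123.0, (0.0, 4.0))


class TestUrineNCA:
    def test_single_interval_arithmetic(self):
        """1 L at 59,400 ng/mL after a 123 mg dose: Ae = 59.4 mg, Fe ~ 48.3%."""
        col = pd.DataFrame({"t_start": [0.0], "t_end": [24.0],
                            "volume": [1.0], "conc": [59_400.0]})
        res = nca_urine(col, 123.0)
        assert res.ae_mg == pytest.approx(59.4)
        assert res.fe_pct == pytest.approx(48.29, abs=0.01)

    def test_zero_concentrations(self):
        col = pd.DataFrame({"t_start": [0.0, 24.0], "t_end": [24.0, 48.0],
                            "volume": [1.5, 1.5], "conc": [0.0, 0.0]})
        res = nca_urine(col, 123.0)
        assert res.ae_mg == 0.0 and res.fe_pct == 0.0

    def test_renal_clearance(self):
        col = pd.DataFrame({"t_start": [0.0], "t_end": [24.0],
                            "volume": [1.0], "conc": [10_000.0]})
        res = nca_urine(col, 123.0, plasma_auc=2000.0)
        assert res.clr == pytest.approx(10.0 * 1000.0 / 2000.0)

    def test_overlapping_intervals_rejected(self):
        col = pd.DataFrame({"t_start": [0.0, 20.0], "t_end": [24.0, 48.0],
                            "volume": [1.0, 1.0], "conc": [1.0, 1.0]})
        with pytest.raises(ValueError, match="overlap"):
            nca_urine(col, 123.0)


class TestParameterAudit:
    def test_every_reported_parameter_has_one_computing_operation(self):
        """Each published PK parameter maps to exactly one result field."""
        from dialypk.nca import NCAResult, DialysisNCAResult, UrineNCAResult

        plasma = {"cmax_24h", "tmax", "clast", "auc_0_24", "auc_0_t",
                  "auc_0_inf", "t_half", "cl_f", "vz_f"}
        dialysis = {"fed_pct", "cld", "auc_inlet", "auc_outlet", "ed_pct"}
        urine = {"ae_mg", "fe_pct", "clr"}
        assert plasma <= set(NCAResult.__dataclass_fields__)
        assert dialysis <= set(DialysisNCAResult.__dataclass_fields__)
        assert urine <= set(UrineNCAResult.__dataclass_fields__)
        # no parameter is computed by more than one engine
        assert not plasma & dialysis and not dialysis & urine and not plasma & urine
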