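"""Noncompartmental PK: AUC, terminal slope, MRT, C0, full composition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hemobind import (
    NCA,
    PKProfile,
    auc_to_infinity,
    auc_trapezoid,
    c0_backextrapolate,
    fit_lambda_z,
    mrt,
)
from hemobind.nca import InsufficientDataError, NoTerminalPhaseError
from hemobind import simulate as sim


def profile(times, concs, dose=2.5, route="intravenous"):
    return PKProfile(times=times, concentrations=concs, dose=dose, route=route)


class TestAUC:
    def test_constant_concentration(self):
        assert auc_trapezoid(profile([0.0, 1.0], [5.0, 5.0])) == 5.0

    def test_triangle(self):
        assert auc_trapezoid(profile([0.0, 2.0], [10.0, 0.0])) == 10.0

    def test_dense_exponential_vs_analytic(self):
        t = np.arange(0.0, 8.01, 0.01)
        p = profile(t, np.exp(-t))
        assert auc_trapezoid(p) == pytest.approx(1 - np.exp(-8), abs=1e-4)

    @given(st.integers(0, 10_000))
    def test_matches_riemann_oracle_on_piecewise_linear(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 10, 6))
        t[0] = 0.0
        c = rng.uniform(0, 5, 6)
        p = profile(t, c)
        # fine midpoint Riemann sum of the piecewise-linear interpolant
        grid = np.linspace(t[0], t[-1], 20001)
        mid = (grid[:-1] + grid[1:]) / 2
        riemann = float(np.sum(np.interp(mid, t, c) * np.diff(grid)))
        assert auc_trapezoid(p) == pytest.approx(riemann, rel=1e-6, abs=1e-6)

    def test_adding_point_never_decreases_auc(self):
        base = profile([0.0, 1.0, 2.0], [1.0, 2.0, 0.5])
        extended = profile([0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 0.5, 0.2])
        assert auc_trapezoid(extended) >= auc_trapezoid(base)

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            auc_trapezoid(profile([0.0], [1.0]))


class TestLambdaZ:
    def test_exact_monoexponential(self):
        t = np.linspace(0, 20, 21)
        p = profile(t, 3.0 * np.exp(-0.2 * t))
        fit = fit_lambda_z(p)
        assert fit.lambda_z == pytest.approx(0.2, rel=1e-9)
        assert fit.t_half == pytest.approx(np.log(2) / 0.2, rel=1e-9)

    def test_rising_profile_has_no_terminal_phase(self):
        p = profile([0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0], route="oral")
        with pytest.raises(NoTerminalPhaseError):
            fit_lambda_z(p)

    def test_oral_profile_recovers_elimination_not_absorption(self):
        t = np.arange(0.0, 30.0, 0.25)
        p = sim.gen_pk_profile("oral_1cpt",
                               {"f_dose_over_v": 0.35, "ka": 1.5, "ke": 0.18},
                               t, dose=400.0)
        fit = fit_lambda_z(p)
        assert fit.t_half == pytest.approx(np.log(2) / 0.18, rel=0.01)

    def test_last_n_selection(self):
        t = np.linspace(0, 20, 21)
        p = profile(t, 3.0 * np.exp(-0.2 * t))
        fit = fit_lambda_z(p, selection="last_n", n_points=5)
        assert fit.n_points == 5
        assert fit.lambda_z == pytest.approx(0.2, rel=1e-9)

    def test_too_few_positive_points_rejected(self):
        p = profile([0.0, 1.0, 2.0], [1.0, 0.5, 0.0])
        with pytest.raises(InsufficientDataError):
            fit_lambda_z(p)


class TestExtrapolationAndMRT:
    def test_zero_clast_is_identity(self):
        auc_inf, frac = auc_to_infinity(6.0, 0.0, 0.2)
        assert auc_inf == 6.0 and frac == 0.0

    def test_hand_value(self):
        auc_inf, _ = auc_to_infinity(6.0, 0.2, 0.2)
        assert auc_inf == pytest.approx(7.0)

    def test_truncated_monoexponential_close_to_analytic(self):
        ke, c0 = 0.2, 3.0
        t_half = np.log(2) / ke
        t = np.arange(0.0, 3 * t_half + 1e-9, 0.01)
        p = profile(t, c0 * np.exp(-ke * t))
        fit = fit_lambda_z(p)
        auc_inf, _ = auc_to_infinity(auc_trapezoid(p), p.concentrations[-1],
                                     fit.lambda_z)
        assert auc_inf == pytest.approx(c0 / ke, rel=0.005)

    def test_iv_mrt_approaches_1_over_ke(self, iv_profile_dense):
        fit = fit_lambda_z(iv_profile_dense)
        assert mrt(iv_profile_dense, fit.lambda_z) == pytest.approx(
            1 / 0.221, rel=0.01)

    def test_symmetric_triangle_mrt_is_midpoint(self):
        p = profile(np.linspace(0, 2, 201),
                    1 - np.abs(np.linspace(0, 2, 201) - 1))
        # brute-force moment integral of the triangle gives exactly 1.0 h
        assert mrt(p, lambda_z=5.0) == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_profile_rejected(self):
        p = profile([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        with pytest.raises(InsufficientDataError):
            mrt(p, 0.2)


class TestC0:
    def test_exact_exponential_returns_c0(self):
        t = np.array([0.0, 0.083, 0.5, 2.0])
        p = profile(t, 2.833 * np.exp(-0.221 * t))
        c0, fallback = c0_backextrapolate(p)
        assert c0 == pytest.approx(2.833, rel=1e-12) and not fallback

    def test_first_sample_after_zero(self):
        t = np.array([0.083, 0.25, 1.0, 4.0])
        p = profile(t, 2.833 * np.exp(-0.221 * t))
        c0, _ = c0_backextrapolate(p)
        assert c0 == pytest.approx(2.833, rel=1e-12)

    def test_flat_leading_points(self):
        p = profile([0.1, 0.2, 1.0], [2.0, 2.0, 1.0])
        c0, fallback = c0_backextrapolate(p)
        assert c0 == 2.0 and not fallback

    def test_zero_first_point_falls_back_with_flag(self):
        p = profile([0.0, 0.5, 1.0, 2.0], [0.0, 1.0, 0.8, 0.5])
        c0, fallback = c0_backextrapolate(p)
        assert fallback


class TestNCAComposition:
    def test_iv_parameters_within_1pct_of_closed_forms(self, iv_profile_dense):
        ke, c0, dose = 0.221, 2.833, 2.5
        res = NCA(iv_profile_dense).fit()
        assert res.c0_or_cmax == pytest.approx(c0, rel=0.01)
        assert res.lambda_z == pytest.approx(ke, rel=0.01)
        assert res.t_half == pytest.approx(np.log(2) / ke, rel=0.01)
        assert res.auc_0_inf == pytest.approx(c0 / ke, rel=0.01)
        assert res.mrt == pytest.approx(1 / ke, rel=0.01)
        assert res.clearance_over_f == pytest.approx(
            dose * 1000 / (c0 / ke), rel=0.01)
        assert res.auc_0_inf >= res.auc_0_t
        assert res.t_half == pytest.approx(np.log(2) / res.lambda_z, rel=1e-12)

    def test_oral_cmax_tmax_from_observed_maximum(self):
        t = [0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0]
        c = [0.0, 0.12, 0.2, 0.26, 0.2, 0.1, 0.03, 0.001]
        res = NCA(profile(t, c, dose=400.0, route="oral")).fit()
        assert res.tmax == 1.0
        assert res.c0_or_cmax == 0.26

    def test_cmax_tie_breaks_to_earliest_time(self):
        t = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
        c = [0.0, 0.26, 0.26, 0.2, 0.1, 0.02]
        res = NCA(profile(t, c, dose=400.0, route="oral")).fit()
        assert res.tmax == 0.5
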