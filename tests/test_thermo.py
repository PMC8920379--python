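"""Double-log binding fits, van't Hoff / Gibbs identities, force calls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hemobind import (
    DoubleLogBindingModel,
    VantHoffModel,
    classify_forces,
    entropy_from_gibbs,
    gibbs_from_enthalpy_entropy,
    gibbs_from_ka,
    vant_hoff_enthalpy,
)
from hemobind.thermo import R_GAS, BindingForce
from hemobind import simulate as sim


class TestDoubleLogFit:
    def test_noiseless_recovery(self):
        series = sim.gen_binding_titration(ka=1e5, n_sites=1.0)
        fit = DoubleLogBindingModel(series).fit()
        assert fit.ka == pytest.approx(1e5, rel=1e-8)
        assert fit.n_sites == pytest.approx(1.0, rel=1e-8)

    @given(st.floats(3, 6), st.floats(0.5, 1.5))
    def test_recovery_over_parameter_plane(self, log_ka, n_sites):
        series = sim.gen_binding_titration(ka=10.0**log_ka, n_sites=n_sites)
        fit = DoubleLogBindingModel(series).fit()
        assert fit.ka == pytest.approx(10.0**log_ka, rel=1e-6)
        assert fit.n_sites == pytest.approx(n_sites, rel=1e-6)

    def test_n_equal_one_matches_1to1_isotherm(self):
        """With n = 1 the generator is the 1:1 isotherm F = F0/(1 + Ka[Q])."""
        ka = 7.7e4
        series = sim.gen_binding_titration(ka=ka, n_sites=1.0, f0=500.0)
        q = series.quencher_conc
        expected = np.where(q > 0, 500.0 / (1 + ka * q), 500.0)
        np.testing.assert_allclose(series.f_observed, expected, rtol=1e-12)
        assert DoubleLogBindingModel(series).fit().ka == pytest.approx(ka,
                                                                       rel=1e-8)

    def test_no_quenching_rejected(self):
        series = sim.gen_quenching_titration(ksv=0.0)  # F == F0 throughout
        with pytest.raises(ValueError, match="no quenching"):
            DoubleLogBindingModel(series)


class TestVantHoff:
    def test_equal_ka_gives_zero_enthalpy(self):
        assert vant_hoff_enthalpy([(293.0, 1e5), (310.0, 1e5)]) == 0.0

    def test_two_point_hand_value(self):
        """Ka doubling from 293 K to 310 K: dH = R ln2 / (1/293 - 1/310)."""
        dh = vant_hoff_enthalpy([(293.0, 1e5), (310.0, 2e5)])
        assert dh == pytest.approx(30.790, abs=0.001)

    def test_three_temperature_recovery(self):
        pairs = sim.gen_temperature_series(dH=-4.7495, dS=72.0,
                                           temperatures=(293.0, 298.0, 310.0))
        assert vant_hoff_enthalpy(pairs) == pytest.approx(-4.7495, rel=1e-6)

    def test_two_point_equals_regression_at_two_points(self):
        pairs = sim.gen_temperature_series(dH=-12.0, dS=40.0,
                                           temperatures=(288.0, 318.0))
        closed = vant_hoff_enthalpy(pairs)
        x = np.array([1 / t for t, _ in pairs])
        y = np.log([k for _, k in pairs])
        slope = np.polyfit(x, y, 1)[0]
        assert closed == pytest.approx(-slope * R_GAS / 1000.0, rel=1e-12)

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            vant_hoff_enthalpy([(293.0, 1e5), (293.0, 2e5)])


class TestGibbs:
    def test_ka_of_one_gives_zero(self):
        for temp in (273.0, 298.0, 310.0):
            assert gibbs_from_ka(1.0, temp) == 0.0

    def test_hand_value(self):
        assert gibbs_from_ka(3.4e4, 298.0) == pytest.approx(-25.8513, abs=1e-3)

    @given(st.floats(2, 8), st.floats(2, 8), st.floats(270, 320))
    def test_larger_ka_more_negative(self, la, lb, temp):
        ka, kb = 10.0**la, 10.0**lb
        if ka == kb:
            return
        lo, hi = sorted((ka, kb))
        assert gibbs_from_ka(hi, temp) < gibbs_from_ka(lo, temp)

    def test_reference_row_identity(self):
        """dH - T dS at 310 K reproduces the tabulated -26.984 kJ/mol."""
        assert gibbs_from_enthalpy_entropy(-4.7495, 71.724, 310.0) == \
            pytest.approx(-26.984, abs=5e-4)

    def test_293_row_computes_minus_25_879(self):
        # the source table prints -25.900 here; the identity itself gives -25.879
        assert gibbs_from_enthalpy_entropy(-4.7495, 72.113, 293.0) == \
            pytest.approx(-25.8786, abs=1e-3)

    def test_entropy_inverts_gibbs(self):
        assert entropy_from_gibbs(-4.7495, -26.984, 310.0) == \
            pytest.approx(71.724, abs=2e-3)

    @given(st.floats(-50, 50), st.floats(-200, 200), st.floats(270, 330))
    def test_algebraic_inverse_pair(self, dh, ds, temp):
        dg = gibbs_from_enthalpy_entropy(dh, ds, temp)
        assert entropy_from_gibbs(dh, dg, temp) == pytest.approx(ds, abs=1e-9)

    @given(st.floats(-40, 40), st.floats(-150, 150), st.floats(275, 320),
           st.floats(275, 320))
    def test_round_trip_through_ka(self, dh, ds, t1, t2):
        """Ka built from (dH, dS) returns both parameters through the fits."""
        if abs(t1 - t2) < 5:
            return
        pairs = sim.gen_temperature_series(dH=dh, dS=ds,
                                           temperatures=(t1, t2))
        dh_hat = vant_hoff_enthalpy(pairs)
        assert dh_hat == pytest.approx(dh, rel=1e-6, abs=1e-6)
        for temp, ka in pairs:
            ds_hat = entropy_from_gibbs(dh, gibbs_from_ka(ka, temp), temp)
            assert ds_hat == pytest.approx(ds, rel=1e-6, abs=1e-6)


class TestForceClassification:
    @pytest.mark.parametrize("dh,ds,expected", [
        (-4.7495, 72.113, BindingForce.ELECTROSTATIC),
        (-10.0, -50.0, BindingForce.VDW_HBOND),
        (20.0, 80.0, BindingForce.HYDROPHOBIC),
        (0.0, 0.0, BindingForce.AMBIGUOUS),
        (10.0, -50.0, BindingForce.AMBIGUOUS),  # unexplained quadrant
    ])
    def test_sign_rules(self, dh, ds, expected):
        assert classify_forces(dh, ds).force is expected

    @given(st.floats(-100, 100, allow_nan=False),
           st.floats(-500, 500, allow_nan=False))
    def test_total_and_deterministic(self, dh, ds):
        first = classify_forces(dh, ds)
        assert first == classify_forces(dh, ds)
        assert first.force in BindingForce

    def test_zero_band_is_configurable(self):
        assert classify_forces(-0.5, 30.0).force is BindingForce.AMBIGUOUS
        assert classify_forces(-0.5, 30.0,
                               zero_band=(0.1, 5.0)).force is \
            BindingForce.ELECTROSTATIC


class TestVantHoffModel:
    def test_full_fit_reproduces_structure(self):
        pairs = sim.gen_temperature_series(dH=-4.7495, dS=72.113)
        params = VantHoffModel(pairs).fit()
        assert params.dH == pytest.approx(-4.7495, rel=1e-6)
        assert params.force.force is BindingForce.ELECTROSTATIC
        # construction invariant: dG = dH - T dS/1000 at every temperature
        for temp, ds, dg in zip(params.temperatures, params.dS_by_T,
                                params.dG_by_T):
            assert dg == pytest.approx(params.dH - temp * ds / 1000.0,
                                       abs=1e-9)

    def test_constant_entropy_variant(self):
        pairs = sim.gen_temperature_series(dH=-4.7495, dS=72.113)
        params = VantHoffModel(pairs, constant_entropy=True).fit()
        assert len(set(params.dS_by_T)) == 1
        assert params.dS_by_T[0] == pytest.approx(72.113, rel=1e-6)
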