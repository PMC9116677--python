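import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbpnoise.deterministic import (BoundaryExtremumError, dose_response_table,
                                    effective_theta_x, evaluate_condition,
                                    growth_rate, locate_extremum,
                                    mean_regulator, mean_target,
                                    regulator_limits, relative_sr_curve,
                                    sensitivity_scan, target_limits,
                                    translation_scale)
from rbpnoise.params import Condition


class TestGrowthRate:
    def test_maximal_at_zero_tc(self, gp):
        assert growth_rate(0.0, gp) == pytest.approx(1.2)

    def test_half_inhibition_at_theta_c(self, gp):
        assert growth_rate(gp.theta_c, gp) == pytest.approx(gp.mu0 / 2)

    def test_value_at_max_tc(self, gp):
        # 1.2 / (1 + 1000/526), evaluated by hand
        assert growth_rate(1000.0, gp) == pytest.approx(0.413630, abs=1e-5)

    def test_strictly_decreasing(self, gp):
        tc = np.linspace(0.0, 1000.0, 500)
        mu = growth_rate(tc, gp)
        assert np.all(np.diff(mu) < 0)

    def test_negative_tc_rejected(self, gp):
        with pytest.raises(ValueError):
            growth_rate(-1.0, gp)


class TestTranslationScale:
    def test_unity_at_reference(self, gp):
        assert translation_scale(1.2, gp.eps1_x, gp.eps2_x, 1.2) == pytest.approx(1.0)

    def test_hand_value(self, gp):
        # ((0.196-0.414)/(0.299-0.414)) / ((0.196-1.2)/(0.299-1.2)) by hand
        got = translation_scale(0.414, gp.eps1_x, gp.eps2_x, 1.2)
        assert got == pytest.approx(1.7012, abs=2e-4)

    def test_increases_as_growth_slows(self, gp):
        assert translation_scale(0.5, gp.eps1_x, gp.eps2_x, 1.2) > \
            translation_scale(0.8, gp.eps1_x, gp.eps2_x, 1.2)

    def test_pole_rejected(self, gp):
        with pytest.raises(ValueError, match="pole"):
            translation_scale(gp.eps2_x, gp.eps1_x, gp.eps2_x, 1.2)


class TestEffectiveThetaX:
    def test_identity_at_mu0(self, dp, gp):
        assert effective_theta_x(gp.mu0, dp.theta_x, gp.delta, gp.mu0) == 610.0

    def test_volume_correction_value(self, dp, gp):
        # exp(0.85*(1.2-0.414))*610 by hand
        got = effective_theta_x(0.414, dp.theta_x, gp.delta, gp.mu0)
        assert got == pytest.approx(1189.8, rel=1e-3)

    def test_no_correction_when_delta_zero(self, dp, gp):
        assert effective_theta_x(0.5, dp.theta_x, 0.0, gp.mu0) == 610.0


class TestTransferFunctions:
    def test_regulator_uninduced(self, dp, gp):
        assert mean_regulator(0.0, dp, gp) == pytest.approx(1890 * 0.225)

    def test_regulator_half_saturation(self, dp, gp):
        got = mean_regulator(dp.theta_i, dp, gp)
        assert got == pytest.approx(1890 * (0.225 + 1) / 2)

    def test_regulator_saturation_limit(self, dp, gp):
        lo, hi = regulator_limits(dp, gp)
        assert (lo, hi) == (pytest.approx(425.25), pytest.approx(1890.0))

    def test_target_unrepressed(self, dp, gp):
        assert mean_target(0.0, dp, gp) == pytest.approx(29000.0)

    def test_target_at_theta_x(self, dp, gp):
        got = mean_target(dp.theta_x, dp, gp)
        assert got == pytest.approx(29000 * (1 + 0.016) / 2)

    def test_target_full_repression_limit(self, dp, gp):
        lo, hi = target_limits(dp, gp)
        assert (lo, hi) == (pytest.approx(464.0), pytest.approx(29000.0))

    def test_monotonicity_on_grid(self, dp, gp):
        iptg = np.linspace(0.0, 1000.0, 1000)
        e = mean_regulator(iptg, dp, gp)
        assert np.all(np.diff(e) > 0)
        g = mean_target(e, dp, gp)
        assert np.all(np.diff(g) < 0)

    @settings(max_examples=50, derandomize=True)
    @given(iptg=st.floats(0.0, 1e4), mu=st.floats(0.36, 1.2))
    def test_bounds_hold_everywhere(self, iptg, mu):
        from rbpnoise.params import default_params
        dp, gp, _ = default_params()
        lo_e, hi_e = regulator_limits(dp, gp, mu)
        e = mean_regulator(iptg, dp, gp, mu)
        assert lo_e - 1e-9 <= e <= hi_e + 1e-9
        lo_g, hi_g = target_limits(dp, gp, mu)
        g = mean_target(e, dp, gp, mu)
        assert lo_g - 1e-9 <= g <= hi_g + 1e-9

    def test_negative_inputs_rejected(self, dp, gp):
        with pytest.raises(ValueError):
            mean_regulator(-1.0, dp, gp)
        with pytest.raises(ValueError):
            mean_target(-1.0, dp, gp)


class TestEvaluateCondition:
    def test_reference_condition(self, dp, gp):
        st_ = evaluate_condition(Condition(iptg=0.0, tc=0.0), dp, gp)
        assert st_.e_mean == pytest.approx(425.25)
        assert st_.g_mean == pytest.approx(24965.7, rel=1e-4)

    def test_full_induction_represses_target(self, dp, gp):
        st_ = evaluate_condition(Condition(iptg=1000.0, tc=0.0), dp, gp)
        assert st_.g_mean == pytest.approx(565.9, rel=1e-3)

    @pytest.mark.parametrize("iptg,tc", [(0, 0), (100, 300), (1000, 1000)])
    def test_synthesis_rate_identity(self, dp, gp, iptg, tc):
        st_ = evaluate_condition(Condition(iptg=iptg, tc=tc), dp, gp)
        assert st_.sr_e == pytest.approx(st_.e_mean * st_.mu)
        assert st_.sr_g == pytest.approx(st_.g_mean * st_.mu)

    def test_table_columns(self, dp, gp, tmp_path):
        df = dose_response_table([Condition(0, 0), Condition(100, 500)],
                                 dp, gp, path=tmp_path / "t.csv")
        assert list(df.columns) == ["iptg_uM", "tc_ng_mL", "mu", "e_mean",
                                    "g_mean", "sr_e", "sr_g"]
        assert (tmp_path / "t.csv").exists()


class TestRelativeSynthesisRate:
    def test_unity_at_mu0(self, dp, gp):
        for gene in ("regulator", "target"):
            r = relative_sr_curve(gene, 100.0, [gp.mu0], dp, gp)
            assert r[0] == pytest.approx(1.0)

    def test_regulator_curve_iptg_independent(self, dp, gp):
        mu = np.linspace(0.32, 1.2, 50)
        r0 = relative_sr_curve("regulator", 0.0, mu, dp, gp)
        r1 = relative_sr_curve("regulator", 1000.0, mu, dp, gp)
        np.testing.assert_allclose(r0, r1)

    def test_target_interior_maximum_above_one(self, dp, gp):
        mu = np.linspace(0.36, 1.2, 400)
        r = relative_sr_curve("target", 100.0, mu, dp, gp)
        k = int(np.argmax(r))
        assert 0 < k < len(mu) - 1 and r[k] > 1.0


class TestLocateExtremum:
    def test_regulator_minimum_matches_closed_form(self, dp, gp):
        # stationary point of mu*(eps1-mu)/(eps2-mu):
        # mu* = eps2 + sqrt(eps2*(eps2-eps1))
        analytic = gp.eps2_x + math.sqrt(gp.eps2_x * (gp.eps2_x - gp.eps1_x))
        f = lambda m: float(relative_sr_curve("regulator", 0.0, [m], dp, gp)[0])
        found = locate_extremum(f, (0.31, 1.2), mode="min")
        assert found == pytest.approx(analytic, abs=1e-3)
        assert analytic == pytest.approx(0.4745, abs=5e-4)

    def test_target_maximum_location(self, dp, gp):
        f = lambda m: float(relative_sr_curve("target", 100.0, [m], dp, gp)[0])
        found = locate_extremum(f, (gp.eps2_y + 0.011, 1.2), mode="max")
        assert found == pytest.approx(0.648, abs=0.005)

    def test_monotone_curve_flagged(self, dp, gp):
        with pytest.raises(BoundaryExtremumError):
            locate_extremum(lambda m: m, (0.4, 1.0), mode="min")


class TestSensitivityScan:
    def test_alpha_x_scales_regulator_linearly(self, dp, gp):
        df = sensitivity_scan("alpha_x", [0, 50, 1000], dp, gp)
        base = df[df.perturbation == "base"].e_mean.to_numpy()
        up = df[df.perturbation == "x2"].e_mean.to_numpy()
        np.testing.assert_allclose(up, 2 * base)

    def test_theta_i_shifts_half_saturation(self, dp, gp):
        df = sensitivity_scan("theta_i", [2 * dp.theta_i], dp, gp)
        up = df[df.perturbation == "x2"].e_mean.iloc[0]
        # at iptg = 2*theta_i, the x2 curve sits at its half-saturation value
        assert up == pytest.approx(1890 * (0.225 + 1) / 2)

    def test_rho_y_scales_repressed_plateau(self, dp, gp):
        from dataclasses import replace
        doubled = replace(dp, rho_y=2 * dp.rho_y)
        assert target_limits(doubled, gp)[0] == \
            pytest.approx(2 * target_limits(dp, gp)[0])

    def test_unknown_parameter_rejected(self, dp, gp):
        with pytest.raises(KeyError):
            sensitivity_scan("nonsense", [0.0], dp, gp)
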