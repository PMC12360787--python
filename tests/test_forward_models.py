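"""Forward-model unit and property tests: lag grid, kernels, Siegert, oracles."""

import math

import numpy as np
import pytest

from dcs2l.forward_models import (
    AcfCurve,
    IntegrationError,
    InvalidParameterError,
    LayerOptics,
    TwoLayerMedium,
    effective_reflection_coefficient,
    g1_semiinfinite,
    g1_tilde_twolayer,
    g1_twolayer,
    g2_curve,
    g2_from_g1,
    lag_grid,
)


class TestLagGrid:
    def test_default_grid_spans_hardware_window(self):
        lags = lag_grid(31, 1.28e-6)
        assert lags[0] == pytest.approx(1.28e-6)
        assert lags[-1] == pytest.approx(39.68e-6)
        assert np.allclose(np.diff(lags), 1.28e-6)

    def test_trivial_two_point_grid(self):
        assert np.allclose(lag_grid(2, 1.0), [1.0, 2.0])

    def test_integration_span_of_4096_iterations(self):
        # 4096 correlator iterations of the 1.28 µs clock span 5.24 ms
        assert 4096 * 1.28e-6 == pytest.approx(5.24e-3, rel=1e-3)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            lag_grid(31, -1.0)
        with pytest.raises(InvalidParameterError):
            lag_grid(1, 1.0)


class TestBoundaryQuantities:
    def test_reff_for_standard_tissue_index(self):
        assert effective_reflection_coefficient(1.4) == pytest.approx(0.493, abs=0.002)

    def test_source_depth_from_extracerebral_optics(self, baseline_medium):
        assert baseline_medium.z0 == pytest.approx(1.0 / (0.019 + 0.86), rel=1e-12)

    def test_wavenumber_definition(self, baseline_medium):
        assert baseline_medium.k0 == pytest.approx(
            2 * math.pi * 1.4 / (785e-6), rel=1e-12)


class TestTwoLayerKernel:
    def test_static_limit_matches_zero_db(self, baseline_medium):
        s = np.linspace(0.0, 5.0, 20)
        static = baseline_medium.with_Db(Db1=0.0, Db2=0.0)
        np.testing.assert_allclose(
            g1_tilde_twolayer(s, 0.0, baseline_medium),
            g1_tilde_twolayer(s, 1e-3, static), rtol=1e-12)

    def test_identical_layers_reduce_to_semiinfinite_kernel(self, brain_optics):
        m = TwoLayerMedium(
            layer1=LayerOptics(0.02, 1.21, 6e-6, thickness=10.0),
            layer2=brain_optics, rho=35.0)
        s = np.linspace(0.0, 10.0, 50)
        tau = 10e-6
        D = brain_optics.D
        K2 = (3 * 1.21 * 0.02
              + 6 * 1.21 ** 2 * m.k0 ** 2 * 6e-6 * tau)
        alpha = np.sqrt(s ** 2 + K2)
        semi = (np.exp(-alpha * m.z0)
                - np.exp(-alpha * (m.z0 + 2 * m.zb))) / (2 * D * alpha)
        np.testing.assert_allclose(
            g1_tilde_twolayer(s, tau, m), semi, rtol=1e-10)

    def test_no_overflow_at_large_spatial_frequency(self, midpoint_medium):
        val = g1_tilde_twolayer(np.array([200.0]), 40e-6, midpoint_medium)
        assert np.isfinite(val).all()


class TestSemiInfiniteOracle:
    def test_normalization_at_zero_lag(self, brain_optics):
        assert g1_semiinfinite(brain_optics, 25.0, 0.0) == pytest.approx(1.0)

    def test_static_medium_never_decorrelates(self):
        static = LayerOptics(0.02, 1.21, 0.0)
        tau = np.linspace(0, 1e-3, 7)
        np.testing.assert_allclose(g1_semiinfinite(static, 25.0, tau), 1.0)

    def test_db_time_scaling_identity(self, lags):
        # K²(τ) depends on Db and τ only through their product, so
        # doubling Db is exactly equivalent to doubling τ
        fast = LayerOptics(0.02, 1.21, 1.2e-5)
        slow = LayerOptics(0.02, 1.21, 6e-6)
        np.testing.assert_allclose(
            g1_semiinfinite(fast, 35.0, lags),
            g1_semiinfinite(slow, 35.0, 2 * lags), rtol=1e-12)


class TestTwoLayerG1:
    def test_self_normalization(self, midpoint_medium):
        assert g1_twolayer(midpoint_medium, 0.0) == pytest.approx(1.0, abs=1e-10)

    def test_identical_layers_match_semiinfinite_closed_form(self, brain_optics, lags):
        m = TwoLayerMedium(
            layer1=LayerOptics(0.02, 1.21, 6e-6, thickness=10.0),
            layer2=brain_optics, rho=35.0)
        got = g1_twolayer(m, lags)
        want = g1_semiinfinite(brain_optics, 35.0, lags)
        mask = want > 1e-5
        assert np.max(np.abs(got - want)[mask] / want[mask]) < 1e-5

    def test_midpoint_medium_strictly_decreasing(self, midpoint_medium, lags):
        g1 = g1_twolayer(midpoint_medium, lags)
        assert np.all(g1 > 0)
        assert np.all(np.diff(g1) < 0)

    def test_thickness_limit_converges_to_extracerebral_solution(self, lags):
        layer1 = LayerOptics(0.019, 0.86, 2e-6, thickness=60.0)
        m = TwoLayerMedium(layer1=layer1,
                           layer2=LayerOptics(0.02, 1.21, 6e-6), rho=35.0)
        want = g1_semiinfinite(LayerOptics(0.019, 0.86, 2e-6), 35.0, lags)
        got = g1_twolayer(m, lags)
        mask = want > 1e-4
        np.testing.assert_allclose(got[mask], want[mask], rtol=1e-4)

    def test_quadrature_robust_to_order_doubling(self, midpoint_medium, lags):
        a = g1_twolayer(midpoint_medium, lags, order=8, check=False)
        b = g1_twolayer(midpoint_medium, lags, order=16, check=False)
        assert np.max(np.abs(a - b)) < 1e-6

    def test_unconverged_quadrature_raises(self, midpoint_medium, lags):
        with pytest.raises(IntegrationError) as exc:
            g1_twolayer(midpoint_medium, lags, order=2, rtol=1e-12)
        assert exc.value.achieved > 0


class TestSiegert:
    @pytest.mark.parametrize("g1,beta,expected", [
        (1.0, 0.5, 1.5),
        (0.0, 0.5, 1.0),
        (0.6, 0.5, 1.18),
    ])
    def test_pointwise_values(self, g1, beta, expected):
        assert g2_from_g1(g1, beta) == pytest.approx(expected)

    def test_curve_roundtrip_kind(self, lags):
        g1 = AcfCurve(lags, np.exp(-lags / 10e-6), kind="g1")
        g2 = g2_from_g1(g1, 0.5)
        assert g2.kind == "g2"
        assert np.all(g2.values <= 1.5 + 1e-12)
        assert np.all(g2.values >= 1.0)

    def test_invalid_beta_rejected(self):
        with pytest.raises(InvalidParameterError):
            g2_from_g1(0.5, 0.0)


class TestG2Curve:
    def test_siegert_bounds_hold(self, midpoint_medium, lags):
        curve = g2_curve(midpoint_medium, lags)
        assert curve.kind == "g2"
        assert np.all(curve.values > 1.0)
        assert curve.values[0] <= 1.5

    def test_faster_brain_flow_lowers_curve_pointwise(self, baseline_medium, lags):
        slow = g2_curve(baseline_medium.with_Db(Db2=2e-6), lags).values
        mid = g2_curve(baseline_medium.with_Db(Db2=6e-6), lags).values
        fast = g2_curve(baseline_medium.with_Db(Db2=1.8e-5), lags).values
        assert np.all(mid <= slow)
        assert np.all(fast <= mid)
        assert np.any(fast < mid) and np.any(mid < slow)

    def test_grid_extremes_visibly_distinct(self, baseline_medium, lags):
        slow = g2_curve(baseline_medium.with_Db(Db1=5e-7 * 0.15, Db2=5e-7), lags)
        fast = g2_curve(baseline_medium.with_Db(Db1=5e-5 * 0.15, Db2=5e-5), lags)
        assert np.max(np.abs(slow.values - fast.values)) > 0.1


class TestOracleEquivalenceSweep:
    def test_identical_layer_media_across_parameter_box(self, table_media_sample, lags):
        """Two-layer quadrature vs closed form on 10 sampled parameter sets."""
        for m in table_media_sample:
            brain = m.layer2
            same = TwoLayerMedium(
                layer1=LayerOptics(brain.mua, brain.musp, brain.Db,
                                   thickness=m.layer1.thickness),
                layer2=brain, rho=35.0)
            got = g1_twolayer(same, lags)
            want = g1_semiinfinite(brain, 35.0, lags)
            mask = want > 1e-5
            assert np.max(np.abs(got - want)[mask] / want[mask]) < 1e-5
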