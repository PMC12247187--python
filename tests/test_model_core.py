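"""Closed-form quantities: values, limits, identities and domain errors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertigrow import (
    GrowthParams,
    TransportParams,
    arcsech,
    characteristic_length,
    dhdt_active,
    dhdt_interface,
    growth_profile,
    hstar,
    peclet,
    resource_coefficients,
    resource_profile,
    steady_state_height,
)

finite_pos = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestCharacteristicLength:
    @pytest.mark.parametrize(
        "D_R,eps,R,alpha,expected",
        [(1, 1, 1, 1, 1.0), (400, 1, 1, 1, 20.0), (100, 0.5, 2, 4, 5.0)],
    )
    def test_values(self, D_R, eps, R, alpha, expected):
        tr = TransportParams(D_R=D_R, epsilon=eps, R_star=R)
        assert characteristic_length(tr, alpha) == pytest.approx(expected)

    def test_measured_colony_implies_transport_product(self, measured_params):
        # inverting L = sqrt(D eps R*/alpha) for the measured colony
        product = measured_params.L**2 * measured_params.alpha
        assert product == pytest.approx(149.17, abs=0.05)
        tr = TransportParams(D_R=product, epsilon=1.0, R_star=1.0)
        assert characteristic_length(tr, measured_params.alpha) == pytest.approx(
            measured_params.L, rel=1e-12
        )

    def test_monotonicity(self, unit_transport):
        assert characteristic_length(unit_transport, 2.0) < characteristic_length(
            unit_transport, 1.0
        )

    def test_identifiability_epsilon_rstar_tradeoff(self):
        # only the product epsilon * R_star matters for L
        a = TransportParams(D_R=50.0, epsilon=2.0, R_star=3.0)
        b = TransportParams(D_R=50.0, epsilon=6.0, R_star=1.0)
        assert characteristic_length(a, 0.7) == pytest.approx(
            characteristic_length(b, 0.7), rel=1e-14
        )

    def test_rejects_nonpositive(self, unit_transport):
        with pytest.raises(ValueError):
            characteristic_length(unit_transport, 0.0)
        with pytest.raises(ValueError):
            TransportParams(D_R=-1.0)


class TestResourceCoefficients:
    def test_flat_colony_splits_evenly(self):
        c = resource_coefficients(0.0, 5.0, 2.0)
        assert c.C1 == pytest.approx(1.0) and c.C2 == pytest.approx(1.0)

    def test_tall_colony_kills_growing_term(self):
        c = resource_coefficients(1e4, 1.0, 1.0)
        assert c.C1 == pytest.approx(0.0, abs=1e-300)
        assert c.C2 == pytest.approx(1.0, rel=1e-12)

    @given(h=st.floats(0, 500), L=finite_pos, R=finite_pos)
    @settings(max_examples=200, deadline=None)
    def test_sum_identity_and_ordering(self, h, L, R):
        c = resource_coefficients(h, L, R)
        assert c.C1 + c.C2 == pytest.approx(R, rel=1e-12)
        assert 0 <= c.C1 <= R / 2 * (1 + 1e-12)
        assert R / 2 * (1 - 1e-12) <= c.C2 < R * (1 + 1e-12)

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            resource_coefficients(-1.0, 1.0, 1.0)


class TestResourceProfile:
    def test_base_is_clamped(self):
        assert resource_profile(0.0, 7.0, 2.0, 3.5) == pytest.approx(3.5)

    def test_short_colony_boundary_boost(self):
        # at depth L in a colony of height L the no-flux roof keeps the
        # concentration at R*/cosh(1), well above the tall-colony e^-1 level
        assert resource_profile(1.0, 1.0, 1.0, 1.0) == pytest.approx(
            1 / math.cosh(1), rel=1e-12
        )
        assert 1 / math.cosh(1) == pytest.approx(0.6481, abs=1e-4)

    def test_tall_colony_exponential_decay(self):
        v = resource_profile(1.0, 10.0, 1.0, 1.0)
        assert v == pytest.approx(math.cosh(9) / math.cosh(10), rel=1e-12)
        assert v == pytest.approx(math.exp(-1), rel=1e-7)

    @given(
        hL=st.floats(1e-3, 50), frac=st.floats(0, 1), L=finite_pos, R=finite_pos
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exponential_form(self, hL, frac, L, R):
        h = hL * L
        z = frac * h
        c = resource_coefficients(h, L, R)
        expected = c.C1 * math.exp(z / L) + c.C2 * math.exp(-z / L)
        assert resource_profile(z, h, L, R) == pytest.approx(expected, rel=1e-10)

    def test_profile_non_increasing_with_zero_roof_gradient(self):
        h, L = 5.0, 2.0
        z = np.linspace(0, h, 2001)
        R = resource_profile(z, h, L, 1.0)
        assert np.all(np.diff(R) <= 1e-15)
        # analytic gradient sinh((z-h)/L) vanishes exactly at the roof
        dz = 1e-6
        top_grad = (R[-1] - resource_profile(h - dz, h, L, 1.0)) / dz
        assert abs(top_grad) < 1e-5

    def test_no_overflow_for_extreme_columns(self):
        v = resource_profile(500.0, 1000.0, 1.0, 1.0)
        assert np.isfinite(v) and v >= 0

    def test_out_of_column_rejected(self):
        with pytest.raises(ValueError):
            resource_profile(3.0, 2.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            resource_profile(-0.1, 2.0, 1.0, 1.0)


class TestGrowthProfile:
    def test_base_growth_is_alpha_minus_beta(self, measured_params):
        g = growth_profile(0.0, 40.0, measured_params)
        assert g == pytest.approx(measured_params.alpha - measured_params.beta)

    def test_deep_interior_tends_to_minus_beta(self, measured_params):
        g = growth_profile(1.0, 1e4 * measured_params.L, measured_params)
        assert g == pytest.approx(-measured_params.beta, rel=1e-12)

    def test_zero_crossing_separates_growth_from_decay(self):
        p = GrowthParams(alpha=1.0, beta=0.1, L=1.0)
        h = 3.0
        from scipy.optimize import brentq

        zc = brentq(lambda zp: growth_profile(zp, h, p), 0.0, 1.0)
        # cosh((h/L)(zc-1)) = (beta/alpha) cosh(h/L) at the crossing
        assert math.cosh(h * (zc - 1)) == pytest.approx(0.1 * math.cosh(h), rel=1e-9)
        assert growth_profile(zc / 2, h, p) > 0 > growth_profile((1 + zc) / 2, h, p)

    def test_non_increasing_in_height(self, measured_params):
        zp = np.linspace(0, 1, 500)
        g = growth_profile(zp, 50.0, measured_params)
        assert np.all(np.diff(g) <= 1e-15)

    def test_domain_error(self, measured_params):
        with pytest.raises(ValueError):
            growth_profile(1.5, 10.0, measured_params)


class TestHeightRates:
    def test_both_models_anchored_at_zero(self, measured_params):
        assert dhdt_active(0.0, measured_params) == 0.0
        assert dhdt_interface(0.0, measured_params) == 0.0

    def test_saturation_without_decay(self):
        p = GrowthParams(alpha=1.0, beta=0.0, L=1.0)
        assert dhdt_active(10.0, p) == pytest.approx(1.0, rel=1e-8)

    def test_measured_colony_rate_at_L(self, measured_params):
        # alpha L tanh(1) - beta L for the measured parameter triple
        assert dhdt_active(measured_params.L, measured_params) == pytest.approx(
            7.954, abs=2e-3
        )

    def test_interface_branches_agree_at_L(self, measured_params):
        p = measured_params
        from_below = (p.alpha - p.beta) * p.L
        from_above = p.alpha * p.L - p.beta * p.L
        assert from_below == pytest.approx(from_above)
        assert dhdt_interface(p.L, p) == pytest.approx(from_below)

    @given(
        hL=st.floats(1e-3, 30),
        alpha=st.floats(0.1, 3),
        ratio=st.floats(0.0, 0.95),
        L=st.floats(1, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_active_rate_never_exceeds_interface_rate(self, hL, alpha, ratio, L):
        p = GrowthParams(alpha=alpha, beta=ratio * alpha, L=L)
        h = hL * L
        assert dhdt_active(h, p) <= dhdt_interface(h, p) + 1e-12

    def test_small_height_limit_law(self, measured_params):
        p = measured_params
        h = 1e-3 * p.L
        approx = (p.alpha - p.beta) * h
        exact = dhdt_active(h, p)
        assert abs(approx - exact) / abs(exact) < 1e-4

    def test_tall_colony_limit_law(self, measured_params):
        p = measured_params
        h = 10 * p.L
        approx = p.alpha * p.L - p.beta * h
        exact = dhdt_active(h, p)
        assert abs(approx - exact) / abs(exact) < 1e-4

    def test_negative_height_rejected(self, measured_params):
        with pytest.raises(ValueError):
            dhdt_active(-1.0, measured_params)
        with pytest.raises(ValueError):
            dhdt_interface(-1.0, measured_params)


class TestPeakHeight:
    def test_arcsech_endpoints(self):
        assert arcsech(1.0) == 0.0
        assert arcsech(0.5) == pytest.approx(math.log(2 + math.sqrt(3)), rel=1e-14)

    def test_quarter_ratio_closed_form(self):
        p = GrowthParams(alpha=1.0, beta=0.25, L=1.0)
        assert hstar(p) == pytest.approx(math.log(2 + math.sqrt(3)), rel=1e-12)
        assert hstar(p) == pytest.approx(1.3170, abs=1e-4)

    def test_measured_colony_peak_exceeds_L(self, measured_params):
        hs = hstar(measured_params)
        assert hs == pytest.approx(27.53, abs=0.02)
        assert hs > measured_params.L  # the boundary effect pushes h* above L

    @pytest.mark.parametrize("ratio", np.geomspace(0.011, 0.97, 12).tolist())
    def test_matches_numeric_argmax(self, ratio):
        from scipy.optimize import minimize_scalar

        p = GrowthParams(alpha=1.3, beta=1.3 * ratio, L=7.7)
        res = minimize_scalar(
            lambda h: -dhdt_active(h, p),
            bounds=(1e-9, 40 * p.L),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert hstar(p) == pytest.approx(res.x, rel=1e-6)

    def test_ratio_collapse(self):
        # h*/L depends on beta/alpha only, not on L or alpha separately
        r = 0.07
        vals = {
            hstar(GrowthParams(alpha=a, beta=a * r, L=L)) / L
            for a in (0.3, 1.0, 2.5)
            for L in (4.0, 13.17, 60.0)
        }
        assert max(vals) - min(vals) < 1e-12

    def test_degenerate_ratios_rejected(self):
        with pytest.raises(ValueError):
            hstar(GrowthParams(alpha=1.0, beta=1.0, L=1.0))
        with pytest.raises(ValueError):
            hstar(GrowthParams(alpha=1.0, beta=0.0, L=1.0))


class TestSteadyState:
    def test_interface_plateau(self):
        p = GrowthParams(alpha=1.0, beta=0.5, L=10.0)
        assert steady_state_height(p, "interface") == pytest.approx(20.0)

    def test_active_root_measured_colony(self, measured_params):
        h_ss = steady_state_height(measured_params, "active")
        assert h_ss == pytest.approx(222.1, abs=0.1)
        assert abs(dhdt_active(h_ss, measured_params)) < 1e-9

    @given(alpha=st.floats(0.2, 2), ratio=st.floats(0.02, 0.9), L=st.floats(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_active_below_interface_and_above_peak(self, alpha, ratio, L):
        p = GrowthParams(alpha=alpha, beta=alpha * ratio, L=L)
        h_a = steady_state_height(p, "active")
        assert hstar(p) < h_a <= steady_state_height(p, "interface") + 1e-9

    def test_no_steady_state_without_decay(self):
        with pytest.raises(ValueError):
            steady_state_height(GrowthParams(alpha=1.0, beta=0.0, L=1.0), "active")


class TestPeclet:
    def test_measured_regime_is_deep_quasi_static(self):
        scales = peclet(alpha=1.0, h0=1.0, D_R=1e4)
        assert scales.Pe == pytest.approx(1e-4)
        assert scales.alpha_prime == scales.Pe
        assert scales.T_adv == 1.0 and scales.T_diff == pytest.approx(1e-4)

    def test_quadratic_in_initial_height(self):
        assert peclet(1.0, 2.0, 1.0).Pe == pytest.approx(4 * peclet(1.0, 1.0, 1.0).Pe)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            peclet(1.0, 0.0, 1.0)
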