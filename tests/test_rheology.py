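"""Casson rheology: yield stress, viscosity limits, shear-rate invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coilflow import RheologyParams, casson_viscosity, shear_rate_magnitude, yield_stress


class TestYieldStress:
    def test_printed_formula_values(self):
        assert yield_stress(0.45) == pytest.approx((0.625 * 0.45) ** 3, rel=1e-15)
        assert yield_stress(0.35) == pytest.approx((0.625 * 0.35) ** 3, rel=1e-15)
        assert yield_stress(0.0) == 0.0

    def test_strictly_increasing(self):
        H = np.linspace(0.0, 0.9, 100)
        tau = np.array([yield_stress(h) for h in H])
        assert np.all(np.diff(tau) > 0)

    @pytest.mark.parametrize("H", [-0.1, 1.0, 1.5])
    def test_domain(self, H):
        with pytest.raises(ValueError):
            yield_stress(H)


class TestCassonViscosity:
    def test_yield_free_limit_is_newtonian(self):
        p = RheologyParams(H=0.0)
        g = np.logspace(-6, 6, 20)
        mu = casson_viscosity(g, p)
        assert np.allclose(mu, 0.1 * p.eta, rtol=1e-15)

    def test_infinite_shear_limit(self):
        p = RheologyParams(H=0.45)
        # the yield term decays as 1/gdot; far enough out it is below 1e-6
        assert casson_viscosity(1e13, p) == pytest.approx(0.1 * p.eta, rel=1e-6)

    def test_zero_shear_limit_closed_form(self):
        p = RheologyParams(H=0.45)
        expected = 0.1 * (np.sqrt(p.eta) + np.sqrt(p.tau_y * p.m)) ** 2
        assert casson_viscosity(1e-8, p) == pytest.approx(expected, rel=1e-6)
        assert casson_viscosity(0.0, p) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_shear(self):
        p = RheologyParams(H=0.45)
        g = np.logspace(-4, 5, 100)
        mu = casson_viscosity(g, p)
        assert np.all(np.diff(mu) < 0)

    def test_increasing_in_hematocrit(self):
        g = np.logspace(-3, 4, 100)
        lo = casson_viscosity(g, RheologyParams(H=0.35))
        hi = casson_viscosity(g, RheologyParams(H=0.45))
        assert np.all(hi > lo)

    def test_bounded_by_zero_shear_value(self):
        p = RheologyParams(H=0.45)
        g = np.logspace(-8, 6, 200)
        assert np.all(casson_viscosity(g, p) <= p.mu_zero * (1 + 1e-12))

    def test_rejects_negative_shear(self):
        with pytest.raises(ValueError):
            casson_viscosity(-1.0, RheologyParams())


class TestShearRateMagnitude:
    def test_simple_shear(self):
        assert shear_rate_magnitude(0.0, 3.0, 0.0, 0.0) == pytest.approx(3.0)
        assert shear_rate_magnitude(0.0, -3.0, 0.0, 0.0) == pytest.approx(3.0)

    def test_rigid_rotation_is_zero(self):
        assert shear_rate_magnitude(0.0, 2.0, -2.0, 0.0) == 0.0

    def test_pure_extension(self):
        assert shear_rate_magnitude(1.5, 0.0, 0.0, -1.5) == pytest.approx(3.0)

    @given(
        st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10),
        st.floats(-10, 10), st.floats(0, 2 * np.pi),
    )
    @settings(max_examples=100, deadline=None)
    def test_frame_invariance(self, a, b, c, d, theta):
        G = np.array([[a, b], [c, d]])
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Gr = R @ G @ R.T
        g1 = shear_rate_magnitude(G[0, 0], G[0, 1], G[1, 0], G[1, 1])
        g2 = shear_rate_magnitude(Gr[0, 0], Gr[0, 1], Gr[1, 0], Gr[1, 1])
        assert g2 == pytest.approx(g1, abs=1e-9 * (1 + g1))
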