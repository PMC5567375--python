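"""Temperature field: boundary/initial behaviour, gradient, PDE consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellentropy import (
    DomainError,
    GridSpec,
    SeriesControl,
    cosine_series,
    intercellular_temperature,
    temperature,
    temperature_gradient,
)
from cellentropy.verification import heat_pde_oracle, mirror_displacements


class TestTemperature:
    def test_walls_are_cold_at_all_times(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        t = np.logspace(-6, -3, 20)
        assert np.all(temperature(0.0, t, g, e, ctrl) == 0.0)
        assert np.all(temperature(g.L, t, g, e, ctrl) == 0.0)

    def test_initial_profile_is_square(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        x = np.array([0.0, 0.2 * g.L, 0.5 * g.L, 0.9 * g.L, g.L])
        T = temperature(x, 0.0, g, e, ctrl)
        assert T[0] == 0.0 and T[-1] == 0.0
        assert np.all(T[1:-1] == e.T0)

    def test_centre_stays_warm_at_one_microsecond(self, cases, ctrl):
        # the thermal boundary layer (~sqrt(4 kappa t) ~ 0.08 L) has not
        # reached the mid-cell region yet
        for case in cases.values():
            g, e = case.geometry, case.env
            x = np.linspace(0.3 * g.L, 0.7 * g.L, 30)
            T = temperature(x, 1e-6, g, e, ctrl)
            assert np.all(np.abs(T - e.T0) < 1e-3 * e.T0)

    def test_centre_decay_after_hundred_microseconds(self, normal, ctrl):
        # first-mode dominance: T(L/2, t) -> (4/pi) e^{-kappa pi^2 t/L^2} T0
        g, e = normal.geometry, normal.env
        first_mode = 4 / np.pi * np.exp(-e.kappa * np.pi**2 * 1e-4 / g.L**2) * e.T0
        got = temperature(g.L / 2, 1e-4, g, e, ctrl)
        assert got == pytest.approx(0.3104 * e.T0, rel=1e-3)
        assert got == pytest.approx(first_mode, rel=2e-5)

    def test_domain_errors(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        with pytest.raises(DomainError):
            temperature(-1e-9, 1e-5, g, e, ctrl)
        with pytest.raises(DomainError):
            temperature(2 * g.L, 1e-5, g, e, ctrl)
        with pytest.raises(DomainError):
            temperature(g.L / 2, -1e-5, g, e, ctrl)
        # the formal flag admits negative times for time-reversal probing
        small = SeriesControl(n_terms=3)
        temperature(g.L / 2, -1e-5, g, e, small, formal_time=True)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(xf=st.floats(0.02, 0.98), tf=st.floats(-6, -3))
    def test_bounded_between_zero_and_t0(self, cases, ctrl, xf, tf):
        # no Gibbs overshoot survives for t >= 1 us at these cell sizes
        for case in cases.values():
            g, e = case.geometry, case.env
            T = temperature(xf * g.L, 10.0**tf, g, e, ctrl)
            assert -1e-12 * e.T0 <= T <= e.T0 * (1 + 1e-12)

    def test_series_agrees_with_crank_nicolson(self, normal):
        # fast version of the full PDE cross-check: default step size, but
        # a shorter horizon and coarser mesh
        rep = heat_pde_oracle(normal.geometry, normal.env,
                              GridSpec(nx=41, nt=10, t_max=2e-4),
                              nx=1201, dt=1e-7, n_times=5, tolerance=1e-3)
        assert rep.passed, str(rep)

    def test_refining_the_oracle_improves_agreement(self, normal):
        coarse = heat_pde_oracle(normal.geometry, normal.env, nx=401, dt=2e-6,
                                 n_times=4)
        fine = heat_pde_oracle(normal.geometry, normal.env, nx=801, dt=1e-6,
                               n_times=4)
        assert fine.max_rel_error < coarse.max_rel_error


class TestGradient:
    def test_zero_at_centre(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        t = np.logspace(-6, -3, 10)
        assert np.all(temperature_gradient(0.5 * g.L, t, g, e, ctrl) == 0.0)

    def test_antisymmetric_about_centre(self, cases, ctrl):
        for case in cases.values():
            g, e = case.geometry, case.env
            d = mirror_displacements(np.linspace(0.05, 0.45, 20) * g.L, g.L)
            t = np.logspace(-6, -3, 15)
            left = temperature_gradient(0.5 * g.L - d[:, None], t, g, e, ctrl)
            right = temperature_gradient(0.5 * g.L + d[:, None], t, g, e, ctrl)
            np.testing.assert_array_equal(left, -right)

    def test_matches_finite_difference_of_temperature(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        x, t, h = g.L / 4, 1e-4, 1e-9
        fd = (temperature(x + h, t, g, e, ctrl)
              - temperature(x - h, t, g, e, ctrl)) / (2 * h)
        grad = temperature_gradient(x, t, g, e, ctrl)
        assert grad == pytest.approx(fd, rel=1e-6)
        assert grad == pytest.approx(2.14e7, rel=1e-2)  # frozen spot value

    def test_gradient_refused_at_t0(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        with pytest.raises(DomainError):
            temperature_gradient(g.L / 4, 0.0, g, e, ctrl)


class TestCosineSeries:
    def test_image_and_spectral_forms_agree_at_crossover(self, cases):
        # kappa pi^2 t / L^2 = 1/2 is the representation switch; both forms
        # must agree across it
        ctrl = SeriesControl(n_terms=400)
        for case in cases.values():
            g, e = case.geometry, case.env
            t_star = 0.5 * g.L**2 / (e.kappa * np.pi**2)
            x = np.linspace(0.05, 0.95, 19) * g.L
            below = cosine_series(x, t_star * 0.999, g, e, ctrl)
            above = cosine_series(x, t_star * 1.001, g, e, ctrl)
            # smooth in t: values at +-0.1% in t differ by O(0.3%); the
            # centre point is an odd-symmetry zero compared absolutely
            np.testing.assert_allclose(below, above, rtol=2e-2, atol=1e-14)

    def test_single_sign_on_each_half_cell(self, cases, ctrl):
        # dT/dx >= 0 on the left half at all times (monotone temperature)
        for case in cases.values():
            g, e = case.geometry, case.env
            x = np.linspace(0.02, 0.48, 47) * g.L
            t = np.logspace(-6, -3, 40)
            C = cosine_series(x[:, None], t[None, :], g, e, ctrl)
            assert np.all(C > 0)


class TestIntercellular:
    def test_gaussian_peak_value_at_wall(self, normal):
        g, e = normal.geometry, normal.env
        t = 1e-4
        expect = e.T0 * g.x0 / np.sqrt(4 * np.pi * e.kappa * t)
        assert intercellular_temperature(g.L, t, g, e) == pytest.approx(expect, rel=1e-14)

    def test_decreasing_away_from_wall(self, normal):
        g, e = normal.geometry, normal.env
        x = g.L + np.linspace(0, g.gap, 30)
        T = intercellular_temperature(x, 5e-5, g, e)
        assert np.all(np.diff(T) < 0)
        assert np.all(T > 0)

    def test_inside_cell_is_domain_error(self, normal):
        g, e = normal.geometry, normal.env
        with pytest.raises(DomainError):
            intercellular_temperature(0.9 * g.L, 1e-5, g, e)

    def test_exchange_exponential_is_inverse_kernel(self, normal):
        # the growing exponential in the matter-exchange term is 1/T_ic up
        # to the constant (4 pi kappa)^{1/2}/(x0 T0) folded into its prefactor
        g, e = normal.geometry, normal.env
        x, t = g.L + 0.2e-6, 7e-5
        T_ic = intercellular_temperature(x, t, g, e)
        eta_form = np.sqrt(t) * np.exp((x - g.L) ** 2 / (4 * e.kappa * t))
        identity = T_ic * eta_form * np.sqrt(4 * np.pi * e.kappa) / (g.x0 * e.T0)
        assert identity == pytest.approx(1.0, rel=1e-12)
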