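"""Internal entropy-rate components against arithmetic and mpmath oracles."""

import dataclasses

import mpmath as mp
import numpy as np
import pytest

from cellentropy import (
    SeriesControl,
    mixture_rate,
    rate_internal_diffusion,
    rate_internal_heat,
    rate_internal_reaction,
    standard_affinity,
    temperature,
    temperature_gradient,
)
from cellentropy.verification import mirror_displacements

mp.mp.dps = 50


def _mp_cosine_series(x, t, L, kappa, terms=4000):
    s = mp.mpf(0)
    for m in range(1, 2 * terms, 2):
        s += mp.cos(m * mp.pi * x / L) * mp.exp(-kappa * m**2 * mp.pi**2 * t / L**2)
    return s


def _mp_temperature(x, t, L, kappa, T0, terms=4000):
    s = mp.mpf(0)
    for m in range(1, 2 * terms, 2):
        s += mp.sin(m * mp.pi * x / L) / m * mp.exp(-kappa * m**2 * mp.pi**2 * t / L**2)
    return 4 * T0 / mp.pi * s


def _mp_riD(case, reaction, x, t):
    """Arbitrary-precision re-evaluation of the diffusion entropy term."""
    g, e = case.geometry, case.env
    L, V = mp.mpf(g.L), mp.mpf(g.L) ** 3
    kappa, T0, tau = mp.mpf(e.kappa), mp.mpf(e.T0), mp.mpf(e.tau)
    x, t = mp.mpf(x), mp.mpf(t)
    d = x - L / 2
    species_sum = mp.mpf(0)
    for name, nu in reaction.stoich.items():
        sp = case.species[name]
        species_sum += (mp.mpf(sp.mu0) * mp.mpf(reaction.n_moles[name])
                        / (4 * mp.sqrt(mp.mpf(sp.D)))
                        * mp.exp(-d**2 / (4 * mp.mpf(sp.D) * t)))
    beta = T0 / (mp.sqrt(mp.pi) * V)
    C = _mp_cosine_series(x, t, L, kappa)
    T = _mp_temperature(x, t, L, kappa, T0)
    return (beta * d * mp.exp(-t / tau) / t**mp.mpf(1.5)
            * species_sum * C * mp.exp(-abs(d) / L) / T**2)


class TestHeatTerm:
    def test_zero_at_centre(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        t = np.logspace(-6, -3, 12)
        assert np.all(rate_internal_heat(0.5 * g.L, t, g, e, ctrl) == 0.0)

    def test_force_flow_identity_pointwise(self, cases, ctrl):
        # alpha C^2 e^{-t/tau} / T^2 == p K e^{-t/tau} (dT/dx)^2 / T^2
        for case in cases.values():
            g, e = case.geometry, case.env
            x = np.linspace(0.02, 0.98, 49) * g.L
            t = np.logspace(-6, -3, 25)
            lhs = rate_internal_heat(x[:, None], t[None, :], g, e, ctrl)
            grad = temperature_gradient(x[:, None], t[None, :], g, e, ctrl)
            T = temperature(x[:, None], t[None, :], g, e, ctrl)
            rhs = e.p_heat * e.K_th * np.exp(-t[None, :] / e.tau) * grad**2 / T**2
            np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_spot_value_against_gradient_oracle(self, normal, ctrl):
        # independent reconstruction from finite differences of T
        g, e = normal.geometry, normal.env
        x, t, h = g.L / 4, 1e-4, 1e-10
        fd_grad = (temperature(x + h, t, g, e, ctrl)
                   - temperature(x - h, t, g, e, ctrl)) / (2 * h)
        T = temperature(x, t, g, e, ctrl)
        oracle = e.p_heat * e.K_th * np.exp(-t / e.tau) * fd_grad**2 / T**2
        got = rate_internal_heat(x, t, g, e, ctrl)
        assert got == pytest.approx(oracle, rel=1e-5)
        assert got == pytest.approx(1.85e10, rel=1e-2)  # frozen spot value

    def test_nonnegative_everywhere(self, cancer, ctrl):
        g, e = cancer.geometry, cancer.env
        x = np.linspace(0.02, 0.98, 30) * g.L
        t = np.logspace(-6, -3, 20)
        assert np.all(rate_internal_heat(x[:, None], t[None, :], g, e, ctrl) >= 0)


class TestDiffusionTerm:
    def test_zero_at_centre(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        r = normal.reaction("respiration")
        t = np.logspace(-6, -3, 12)
        out = rate_internal_diffusion(0.5 * g.L, t, r, normal.species, g, e, ctrl)
        assert np.all(out == 0.0)

    def test_even_about_centre(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        r = normal.reaction("fermentation")
        d = mirror_displacements(np.linspace(0.05, 0.45, 30) * g.L, g.L)
        t = np.logspace(-6, -3, 15)
        left = rate_internal_diffusion(0.5 * g.L - d[:, None], t, r,
                                       normal.species, g, e, ctrl)
        right = rate_internal_diffusion(0.5 * g.L + d[:, None], t, r,
                                        normal.species, g, e, ctrl)
        np.testing.assert_array_equal(left, right)

    @pytest.mark.parametrize("case_name,reaction,xf,t", [
        ("normal", "respiration", 0.25, 1e-4),
        ("normal", "fermentation", 0.6, 3e-4),
        ("cancer", "respiration", 0.75, 1e-3),
        ("cancer", "fermentation", 0.35, 6e-4),
    ])
    def test_against_arbitrary_precision_oracle(self, cases, case_name,
                                                reaction, xf, t):
        case = cases[case_name]
        g, e = case.geometry, case.env
        r = case.reaction(reaction)
        x = xf * g.L
        got = rate_internal_diffusion(x, t, r, case.species, g, e,
                                      SeriesControl(n_terms=400))
        ref = float(_mp_riD(case, r, x, t))
        assert got == pytest.approx(ref, rel=1e-10)

    def test_nonnegative_for_glucose_reactions(self, cases, ctrl):
        for case in cases.values():
            g, e = case.geometry, case.env
            x = np.linspace(0.02, 0.98, 41) * g.L
            t = np.logspace(-6, -3, 25)
            for r in case.reactions:
                out = rate_internal_diffusion(x[:, None], t[None, :], r,
                                              case.species, g, e, ctrl)
                assert np.all(out >= 0)


class TestReactionTerm:
    def test_origin_value_equals_affinity_form(self, normal, ctrl):
        # r_ir(L/2, 0) = (4/pi) k_kin A / (V_cell T0) for a first-order step
        g, e = normal.geometry, normal.env
        r = normal.reaction("respiration")
        a = standard_affinity(r, normal.species)
        oracle = 4 / np.pi * r.k_kin * a / (g.V_cell * e.T0)
        got = rate_internal_reaction(g.L / 2, 0.0, r, normal.species, g, e, ctrl)
        assert got == pytest.approx(oracle, rel=1e-12)
        assert oracle == pytest.approx(1.20e15, rel=1e-2)

    def test_zero_affinity_reaction_is_silent(self, normal, ctrl):
        # H+ has zero standard potential: a fictitious H+ <-> H+ shuffle
        g, e = normal.geometry, normal.env
        r = dataclasses.replace(normal.reaction("fermentation"),
                                stoich={"H+": -1.0, "lactate": 0.0},
                                n_moles={"H+": 1.0, "lactate": 0.0},
                                reagent_a="H+", n_pr_moles=None)
        out = rate_internal_reaction(0.3 * g.L, 1e-5, r, normal.species, g, e, ctrl)
        assert out == 0.0

    def test_fermentation_to_respiration_ratio_is_affinity_ratio(self, normal, ctrl):
        # at equal k_kin the fields differ only by the affinities
        g, e = normal.geometry, normal.env
        resp = normal.reaction("respiration")
        ferm = dataclasses.replace(normal.reaction("fermentation"),
                                   k_kin=resp.k_kin)
        x, t = 0.4 * normal.geometry.L, 2e-5
        ratio = (rate_internal_reaction(x, t, ferm, normal.species, g, e, ctrl)
                 / rate_internal_reaction(x, t, resp, normal.species, g, e, ctrl))
        assert ratio == pytest.approx(116.00 / 2920.232, rel=1e-9)

    def test_proportional_to_damped_affinity(self, cancer, ctrl):
        from cellentropy import affinity

        g, e = cancer.geometry, cancer.env
        r = cancer.reaction("respiration")
        x = np.linspace(0.1, 0.9, 9) * g.L
        t = 5e-5
        vals = rate_internal_reaction(x, t, r, cancer.species, g, e, ctrl)
        aff = affinity(r, cancer.species, x, t, g, e)
        T = temperature(x, t, g, e, ctrl)
        expect = 4 / np.pi * e.T0 * r.k_kin * aff / (g.V_cell * T**2)
        np.testing.assert_allclose(vals, expect, rtol=1e-12)


class TestMixture:
    def test_degenerate_weights_reduce_to_single_reaction(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        resp = dataclasses.replace(normal.reaction("respiration"), weight=1.0)
        only = dataclasses.replace(
            normal, reactions=(resp,),
            exchange={"respiration": normal.exchange["respiration"]})
        x, t = 0.3 * g.L, 1e-4
        assert mixture_rate(only, "rir", x, t, ctrl) == pytest.approx(
            rate_internal_reaction(x, t, resp, normal.species, g, e, ctrl),
            rel=1e-14)

    def test_mixture_is_weighted_sum(self, normal, ctrl):
        g, e = normal.geometry, normal.env
        x, t = 0.7 * g.L, 5e-5
        parts = [r.weight * rate_internal_reaction(x, t, r, normal.species,
                                                   g, e, ctrl)
                 for r in normal.reactions]
        assert mixture_rate(normal, "rir", x, t, ctrl) == pytest.approx(
            sum(parts), rel=1e-14)

    def test_reaction_order_is_irrelevant(self, normal, ctrl):
        swapped = dataclasses.replace(normal,
                                      reactions=tuple(reversed(normal.reactions)))
        x, t = 0.25 * normal.geometry.L, 2e-4
        for comp in ("riD", "rir"):
            assert mixture_rate(swapped, comp, x, t, ctrl) == pytest.approx(
                mixture_rate(normal, comp, x, t, ctrl), rel=1e-14)

    def test_unknown_component_label(self, normal):
        with pytest.raises(ValueError, match="component"):
            mixture_rate(normal, "bogus", 0.5e-5, 1e-5)

    def test_total_is_sum_of_parts(self, cancer, ctrl):
        g = cancer.geometry
        x = np.linspace(0.1, 0.9, 9) * g.L
        t = 1e-4
        total = mixture_rate(cancer, "ri_total", x, t, ctrl)
        parts = sum(mixture_rate(cancer, c, x, t, ctrl)
                    for c in ("riQ", "riD", "rir"))
        np.testing.assert_allclose(total, parts, rtol=1e-14)
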