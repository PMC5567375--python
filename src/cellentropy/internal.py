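"""Internal entropy-production rate components (heat, diffusion, reaction).

Each component is a force x flow product of Prigogine's local entropy
balance, evaluated in closed form on the interior of the cell:

* heat:      r_iQ = alpha C(x,t)^2 e^{-t/tau} / T^2,  alpha = 16 p K T0^2/L^2,
  identically equal to p K e^{-t/tau} (dT/dx)^2 / T^2;
* diffusion: r_iD = beta (x-L/2) e^{-t/tau} t^{-3/2}
  [sum_k u_k N_mk e^{-(x-L/2)^2/4 D_k t} / (4 sqrt(D_k))]
  C(x,t) e^{-|x-L/2|/L} / T^2,  beta = T0 / (sqrt(pi) V_cell);
* reaction:  r_ir = -(4/pi) T0 k_kin [sum_k nu_k mu_k(x,t)]
  N_A^p N_B^q / (V_cell^{p+q} T^2),

with ``C`` the damped cosine series shared with the temperature gradient.
All values are entropy density rates, J K^-1 m^-3 s^-1.  Multi-reaction
cases combine per-reaction fields linearly with the process weights w
(the heat term instead carries the single occurrence weight p).
"""

from __future__ import annotations

import numpy as np

from . import external
from .config import CaseStudy, CellGeometry, ChemicalSpecies, ConfigError, Reaction, ThermalEnv
from .thermal import DEFAULT_CONTROL, SeriesControl, cosine_series, temperature

COMPONENTS = ("riQ", "riD", "rir", "ri_total", "reQ", "re_exch", "re_total")


def rate_internal_heat(x, t, geom: CellGeometry, env: ThermalEnv,
                       ctrl: SeriesControl = DEFAULT_CONTROL, *,
                       formal_time: bool = False) -> np.ndarray:
    """Heat-flow entropy rate r_iQ(x,t); nonnegative (squared gradient).

    Vanishes at the cell centre, diverges at the walls where T -> 0 — use
    interior lattice margins.
    """
    alpha = 16.0 * env.p_heat * env.K_th * env.T0**2 / geom.L**2
    C = cosine_series(x, t, geom, env, ctrl, formal_time=formal_time)
    T = temperature(x, t, geom, env, ctrl, formal_time=formal_time)
    t = np.asarray(t, dtype=float)
    out = alpha * np.asarray(C) ** 2 * np.exp(-t / env.tau) / np.asarray(T) ** 2
    return out if np.ndim(out) else float(out)


def _diffusion_species_sum(reaction: Reaction, species, x, t):
    """sum_k u_k N_mk e^{-(x-L/2)^2/(4 D_k t)} / (4 sqrt(D_k)) over the
    species involved in the reaction (reactants and products alike)."""
    total = 0.0
    for name in reaction.stoich:
        sp = species[name]
        n_mk = reaction.n_moles[name]
        total = total + sp.mu0 * n_mk / (4.0 * np.sqrt(sp.D)) * np.exp(-(x**2) / (4.0 * sp.D * t))
    return total


def rate_internal_diffusion(x, t, reaction: Reaction,
                            species: dict[str, ChemicalSpecies],
                            geom: CellGeometry, env: ThermalEnv,
                            ctrl: SeriesControl = DEFAULT_CONTROL, *,
                            formal_time: bool = False) -> np.ndarray:
    """Matter-diffusion entropy rate r_iD(x,t) for one reaction.

    Zero at the centre (odd displacement factor), even about it (the sign
    flips of ``x - L/2`` and of the cosine series cancel); nonnegative for
    the glucose reactions, whose species-weighted potential sum is negative.
    """
    for name in reaction.stoich:
        if name not in species:
            raise ConfigError(f"reaction {reaction.name!r}: unknown species {name!r}")
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    d = x - geom.L / 2.0
    beta = env.T0 / (np.sqrt(np.pi) * geom.V_cell)
    C = cosine_series(x, t, geom, env, ctrl, formal_time=formal_time)
    T = temperature(x, t, geom, env, ctrl, formal_time=formal_time)
    tpow = np.asarray(t, dtype=complex) ** 1.5 if formal_time and np.any(t < 0) else t**1.5
    # the formal -t probe drives the Gaussian factors to overflow; that is
    # the point (the closed form has no real backward-time continuation)
    with np.errstate(over="ignore", invalid="ignore"):
        out = (
            beta * d * np.exp(-t / env.tau) / tpow
            * _diffusion_species_sum(reaction, species, d, t)
            * np.asarray(C) * np.exp(-np.abs(d) / geom.L) / np.asarray(T) ** 2
        )
    if np.ndim(out):
        return out
    return complex(out) if np.iscomplexobj(out) else float(out)


def rate_internal_reaction(x, t, reaction: Reaction,
                           species: dict[str, ChemicalSpecies],
                           geom: CellGeometry, env: ThermalEnv,
                           ctrl: SeriesControl = DEFAULT_CONTROL, *,
                           formal_time: bool = False) -> np.ndarray:
    """Chemical-reaction entropy rate r_ir(x,t) for one reaction.

    Proportional to the affinity, hence nonnegative for spontaneous
    reactions; the reagent molar concentrations enter as N_A^p N_B^q /
    V_cell^{p+q} with the reaction orders p, q.
    """
    if reaction.p_ord + reaction.q_ord not in (1, 2):
        raise ConfigError(f"reaction {reaction.name!r}: p_ord+q_ord must be 1 or 2")
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    # signed sum nu_k mu_k(x,t) = -A(x,t)
    damp = np.exp(-(np.abs(x - geom.L / 2.0) / geom.L + t / env.tau))
    nu_mu = sum(nu * species[k].mu0 for k, nu in reaction.stoich.items()
                if k in species or _raise_unknown(reaction, k)) * damp
    conc = (reaction.n_moles[reaction.reagent_a] ** reaction.p_ord)
    if reaction.q_ord:
        if reaction.reagent_b is None:
            raise ConfigError(f"reaction {reaction.name!r}: q_ord > 0 needs reagent_b")
        conc *= reaction.n_moles[reaction.reagent_b] ** reaction.q_ord
    gamma = 4.0 / np.pi * env.T0
    T = temperature(x, t, geom, env, ctrl, formal_time=formal_time)
    out = (
        -gamma * reaction.k_kin * nu_mu * conc
        / (geom.V_cell ** (reaction.p_ord + reaction.q_ord) * np.asarray(T) ** 2)
    )
    return out if np.ndim(out) else float(out)


def _raise_unknown(reaction, name):
    raise ConfigError(f"reaction {reaction.name!r}: unknown species {name!r}")


def mixture_rate(case: CaseStudy, component: str, x, t,
                 ctrl: SeriesControl | None = None, *,
                 formal_time: bool = False) -> np.ndarray:
    """Weighted-mixture entropy rate of one component for a full case study.

    Per-reaction fields (riD, rir, reQ, re_exch) are combined linearly with
    the process weights w; riQ carries the single heat weight p and does not
    mix over reactions.  ``ri_total`` and ``re_total`` are the pointwise sums
    of their components.
    """
    if ctrl is None:
        ctrl = SeriesControl(n_terms=case.grid.n_terms, tail_tol=case.grid.tol)
    geom, env, species = case.geometry, case.env, case.species
    kw = dict(formal_time=formal_time)
    if component == "riQ":
        return rate_internal_heat(x, t, geom, env, ctrl, **kw)
    if component == "riD":
        return _wsum(case, lambda r: rate_internal_diffusion(
            x, t, r, species, geom, env, ctrl, **kw), x)
    if component == "rir":
        return _wsum(case, lambda r: rate_internal_reaction(
            x, t, r, species, geom, env, ctrl, **kw), x)
    if component == "ri_total":
        return (mixture_rate(case, "riQ", x, t, ctrl, **kw)
                + mixture_rate(case, "riD", x, t, ctrl, **kw)
                + mixture_rate(case, "rir", x, t, ctrl, **kw))
    if component == "reQ":
        return _wsum(case, lambda r: external.rate_external_heat(
            x, t, r, geom, env, **kw), x)
    if component == "re_exch":
        return _wsum(case, lambda r: external.rate_external_exchange(
            x, t, r, case.exchange[r.name], species, geom, env, **kw), x)
    if component == "re_total":
        return (mixture_rate(case, "reQ", x, t, ctrl, **kw)
                + mixture_rate(case, "re_exch", x, t, ctrl, **kw))
    raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")


def _wsum(case: CaseStudy, fn, x):
    total = 0.0
    for r in case.reactions:
        total = total + r.weight * np.asarray(fn(r))
    if not case.reactions:
        total = np.zeros(np.broadcast(np.asarray(x, float)).shape)
    out = np.asarray(total)
    return out if out.ndim else out.item()
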