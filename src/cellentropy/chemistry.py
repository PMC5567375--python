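"""Chemical potential field, reaction affinity, concentration and mass flux.

Each species carries a damped space-time chemical potential

    mu_k(x,t) = u_k * exp[-( |x - L/2| / L + t / tau )]

anchored at the standard-state value ``u_k`` at the reaction origin
``x = L/2`` at ``t = 0``.  The affinity ``A = -sum_k nu_k mu_k`` (De Donder)
is the thermodynamic force of the reaction term; species spreading from the
origin follows the 1D point-source Gaussian of Fick's law, and the diffusive
flux is its exact spatial derivative times ``-D_k``.
"""

from __future__ import annotations

import numpy as np

from .config import CellGeometry, ChemicalSpecies, ConfigError, Reaction, ThermalEnv

#: Unit length (m) carried by the Gaussian concentration kernel so that the
#: flux -D dn/dx has the closed form N_mk (x-L/2) e^{-(x-L/2)^2/4Dt} /
#: (4 sqrt(pi D) V_cell t^{3/2}) used by the diffusion entropy term.
KERNEL_LENGTH = 1.0


def _damping(x, t, geom: CellGeometry, env: ThermalEnv):
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    return np.exp(-(np.abs(x - geom.L / 2.0) / geom.L + t / env.tau))


def chemical_potential(species: ChemicalSpecies, x, t,
                       geom: CellGeometry, env: ThermalEnv) -> np.ndarray:
    """mu_k(x,t) in J/mol: standard value damped away from (L/2, 0).

    The same form continues into the intercellular region (x > L); the
    membrane is thin enough to be neglected.
    """
    out = species.mu0 * _damping(x, t, geom, env)
    return out if np.ndim(out) else float(out)


def affinity(reaction: Reaction, species: dict[str, ChemicalSpecies], x, t,
             geom: CellGeometry, env: ThermalEnv) -> np.ndarray:
    """Reaction affinity A(x,t) = -sum_k nu_k mu_k(x,t), J/mol.

    Positive everywhere for spontaneous reactions; inherits the common
    exponential damping, so A(x,t) = A(L/2, 0) * e^{-(|x-L/2|/L + t/tau)}.
    """
    a0 = 0.0
    for name, nu in reaction.stoich.items():
        if name not in species:
            raise ConfigError(f"reaction {reaction.name!r}: unknown species {name!r}")
        a0 -= nu * species[name].mu0
    out = a0 * _damping(x, t, geom, env)
    return out if np.ndim(out) else float(out)


def standard_affinity(reaction: Reaction, species: dict[str, ChemicalSpecies]) -> float:
    """A(L/2, 0): the undamped affinity from standard chemical potentials, J/mol."""
    return float(affinity(reaction, species, 0.5, 0.0,
                          CellGeometry(L=1.0, gap=1.0, x0=1.0), ThermalEnv()))


def concentration_profile(species: ChemicalSpecies, n_moles: float, x, t,
                          geom: CellGeometry) -> np.ndarray:
    """Point-source Gaussian concentration n_k(x,t), mol/m^3.

    ``n_k = (N_mk / V_cell) (4 pi D_k t)^{-1/2} e^{-(x-L/2)^2/(4 D_k t)} * l``
    with unit length ``l`` = :data:`KERNEL_LENGTH`; peaked and symmetric about
    the reaction origin L/2.  Requires t > 0.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("concentration_profile requires t > 0")
    D = species.D
    out = (
        n_moles / geom.V_cell * KERNEL_LENGTH
        / np.sqrt(4.0 * np.pi * D * t)
        * np.exp(-((x - geom.L / 2.0) ** 2) / (4.0 * D * t))
    )
    return out if np.ndim(out) else float(out)


def mass_flux(species: ChemicalSpecies, n_moles: float, x, t,
              geom: CellGeometry) -> np.ndarray:
    """Diffusive flux J_Dk = -D_k dn_k/dx = (x - L/2)/(2t) * n_k, mol m^-2 s^-1.

    Zero at the origin, antisymmetric about it (outward transport on both
    sides, matching the sign of x - L/2).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    out = (x - geom.L / 2.0) / (2.0 * t) * concentration_profile(
        species, n_moles, x, t, geom
    )
    return out if np.ndim(out) else float(out)
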