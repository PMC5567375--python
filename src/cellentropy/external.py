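"""External entropy-production rate components in the intercellular gap.

Two channels carry entropy out of the cell into the gap ``L <= x <= L+g``:

* released heat:    r_eQ = (3/8) (k_B N_A / V_cell) N_mpr (x-L)^2 / (kappa t^2),
  from the ideal-gas internal energy of the (mostly water) cell contents and
  the free-space heat kernel in the gap;
* matter export:    r_e,exch = -eta t^{1/2} e^{(x-L)^2/(4 kappa t)}
  sum_{k in products} u_k e^{-(|x-L/2|/L + t/tau)} dN_mk/dtau1,
  eta = (4 pi kappa)^{1/2} / (V_cell x0 T0),

where the positive exponential is the inverse of the intercellular
heat-kernel temperature (the 1/T_ic weight of the exported chemical-potential
flux).  Default export rates are |nu_k| N_m,glucose k_kin per product.
"""

from __future__ import annotations

import numpy as np
from scipy.constants import R as GAS_CONSTANT  # k_B * N_A

from .config import CellGeometry, ChemicalSpecies, ConfigError, ExchangeSpec, Reaction, ThermalEnv
from .thermal import DomainError


def _check_gap(x, t, geom: CellGeometry, *, formal_time: bool):
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(x < geom.L):
        raise DomainError("external rates require x >= L (intercellular region)")
    if not formal_time and np.any(t <= 0):
        raise DomainError("t must be > 0 (pass formal_time=True to probe -t)")
    return x, t


def rate_external_heat(x, t, reaction: Reaction, geom: CellGeometry,
                       env: ThermalEnv, *, formal_time: bool = False) -> np.ndarray:
    """Heat-release entropy rate r_eQ(x,t) for one reaction, J K^-1 m^-3 s^-1.

    Nonnegative, zero at the wall, growing as (x-L)^2 at fixed t and
    decaying as 1/t^2.  Scales with the total product moles N_mpr.
    """
    x, t = _check_gap(x, t, geom, formal_time=formal_time)
    delta = 3.0 / 8.0 * GAS_CONSTANT / geom.V_cell
    out = delta * reaction.n_pr_moles * (x - geom.L) ** 2 / (env.kappa * t**2)
    return out if np.ndim(out) else float(out)


def rate_external_exchange(x, t, reaction: Reaction, exchange: ExchangeSpec,
                           species: dict[str, ChemicalSpecies],
                           geom: CellGeometry, env: ThermalEnv, *,
                           formal_time: bool = False) -> np.ndarray:
    """Matter-exchange entropy rate r_e,exch(x,t) for one reaction.

    Positive when the exported products carry negative chemical potentials
    (the leading minus sign flips the negative sum); linear in the export
    rates.  Export rates may only be given for product species.
    """
    x, t = _check_gap(x, t, geom, formal_time=formal_time)
    for k in exchange.export_rate:
        if reaction.stoich.get(k, 0) <= 0:
            raise ConfigError(
                f"reaction {reaction.name!r}: export rate for non-product {k!r}"
            )
    eta = np.sqrt(4.0 * np.pi * env.kappa) / (geom.V_cell * geom.x0 * env.T0)
    total = 0.0
    for k, rate in exchange.export_rate.items():
        if k not in species:
            raise ConfigError(f"reaction {reaction.name!r}: unknown species {k!r}")
        u_k = species[k].mu0
        total = total + u_k * rate * np.exp(
            -(np.abs(x - geom.L / 2.0) / geom.L + t / env.tau)
        )
    if formal_time and np.any(t < 0):
        tpow = np.sqrt(np.asarray(t, dtype=complex))
    else:
        tpow = np.sqrt(t)
    out = -eta * tpow * np.exp((x - geom.L) ** 2 / (4.0 * env.kappa * t)) * total
    if np.ndim(out):
        return out
    return complex(out) if np.iscomplexobj(out) else float(out)
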