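"""Domain types, unit normalization, config I/O and built-in case studies.

The model describes a single cubic cell of side ``L`` in which irreversible
glucose catabolism starts at the cell centre ``x = L/2`` and drives three
internal entropy sources (heat conduction, matter diffusion, chemical
reaction) plus two external ones (heat release and matter export into the
intercellular gap).  All quantities are stored internally in SI units
(J, mol, m, s, K); configuration files use kJ/mol and micrometres for
readability and are converted on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml


class ConfigError(ValueError):
    """A configuration value violates a model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemicalSpecies:
    """One chemical species: standard chemical potential and diffusivity.

    Parameters
    ----------
    name : str
        Species identifier (e.g. ``"C6H12O6"``).
    mu0 : float
        Standard chemical potential (partial molar Gibbs energy), J/mol.
    D : float
        Mass diffusion coefficient in water, m^2/s.
    """

    name: str
    mu0: float
    D: float

    def __post_init__(self):
        if not self.name:
            raise ConfigError("species.name must be non-empty")
        if not (self.D > 0):
            raise ConfigError(f"species {self.name!r}: D must be > 0, got {self.D}")
        import math

        if not math.isfinite(self.mu0):
            raise ConfigError(f"species {self.name!r}: mu0 must be finite")


@dataclass(frozen=True)
class Reaction:
    """A single irreversible reaction step with first/second-order kinetics.

    ``stoich`` uses the De Donder sign convention: products positive,
    reactants negative, so the affinity ``A = -sum(nu_k mu_k)`` is positive
    for spontaneous reactions.  ``n_moles[k]`` is the number of moles of
    species *k* processed per event (defaults to ``|nu_k|`` times one mole of
    glucose); ``n_pr_moles`` is the total moles of products.  ``p_ord`` and
    ``q_ord`` are the reaction-order exponents of reagents A and B.
    """

    name: str
    stoich: Mapping[str, float]
    k_kin: float
    reagent_a: str
    reagent_b: str | None = None
    p_ord: int = 1
    q_ord: int = 0
    n_moles: Mapping[str, float] = field(default_factory=dict)
    n_pr_moles: float | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.p_ord not in (0, 1, 2) or self.q_ord not in (0, 1, 2):
            raise ConfigError(f"reaction {self.name!r}: p_ord, q_ord must be in {{0,1,2}}")
        if self.p_ord + self.q_ord not in (1, 2):
            raise ConfigError(
                f"reaction {self.name!r}: p_ord+q_ord must be 1 or 2 "
                f"(got {self.p_ord + self.q_ord})"
            )
        if not (0.0 <= self.weight <= 1.0):
            raise ConfigError(f"reaction {self.name!r}: weight must be in [0,1]")
        if self.k_kin <= 0:
            raise ConfigError(f"reaction {self.name!r}: k_kin must be > 0")
        if self.reagent_a not in self.stoich:
            raise ConfigError(f"reaction {self.name!r}: reagent_a {self.reagent_a!r} not in stoich")
        if self.reagent_b is not None and self.reagent_b not in self.stoich:
            raise ConfigError(f"reaction {self.name!r}: reagent_b {self.reagent_b!r} not in stoich")
        # default mole numbers: |nu_k| x 1 mol of glucose-equivalent
        n_moles = dict(self.n_moles) if self.n_moles else {
            k: abs(nu) for k, nu in self.stoich.items()
        }
        for k, n in n_moles.items():
            if n < 0:
                raise ConfigError(f"reaction {self.name!r}: n_moles[{k!r}] must be >= 0")
        object.__setattr__(self, "n_moles", n_moles)
        pr = sum(n_moles[k] for k, nu in self.stoich.items() if nu > 0)
        if self.n_pr_moles is None:
            object.__setattr__(self, "n_pr_moles", pr)
        elif abs(self.n_pr_moles - pr) > 1e-9 * max(1.0, pr):
            raise ConfigError(
                f"reaction {self.name!r}: n_pr_moles={self.n_pr_moles} does not equal "
                f"the sum of product-side n_moles ({pr})"
            )

    @property
    def products(self) -> list[str]:
        return [k for k, nu in self.stoich.items() if nu > 0]

    @property
    def reactants(self) -> list[str]:
        return [k for k, nu in self.stoich.items() if nu < 0]


@dataclass(frozen=True)
class CellGeometry:
    """Cubic-cell geometry: side ``L``, volume ``L**3``, intercellular gap."""

    L: float
    gap: float
    x0: float

    def __post_init__(self):
        for name in ("L", "gap", "x0"):
            if not (getattr(self, name) > 0):
                raise ConfigError(f"geometry.{name} must be > 0")

    @property
    def V_cell(self) -> float:
        """Cell volume ``L**3`` (m^3)."""
        return self.L ** 3


@dataclass(frozen=True)
class ThermalEnv:
    """Thermal parameters: T0, conductivity K, diffusivity kappa, decay time tau.

    ``p_heat`` is the occurrence-frequency weight of the heat term and enters
    only the heat-flow prefactor; it is distinct from the per-reaction process
    weights.
    """

    T0: float = 310.0
    K_th: float = 0.600
    kappa: float = 0.143e-6
    tau: float = 1e-4
    p_heat: float = 0.85

    def __post_init__(self):
        for name in ("T0", "K_th", "kappa", "tau"):
            if not (getattr(self, name) > 0):
                raise ConfigError(f"thermal.{name} must be > 0")
        if not (0.0 <= self.p_heat <= 1.0):
            raise ConfigError("thermal.p_heat must be in [0,1]")


@dataclass(frozen=True)
class GridSpec:
    """Space-time evaluation lattice with interior margins.

    The walls (T -> 0) and t = 0 (Gaussian kernels singular) are excluded:
    x spans ``[x_min_frac*L, x_max_frac*L]`` and t spans ``[t_min, t_max]``
    log-spaced.  ``n_terms`` truncates the Fourier series.
    """

    x_min_frac: float = 0.02
    x_max_frac: float = 0.98
    nx: int = 201
    t_min: float = 1e-6
    t_max: float = 1e-3
    nt: int = 200
    n_terms: int = 200
    tol: float = 1e-16

    def __post_init__(self):
        if not (0.0 < self.x_min_frac < self.x_max_frac < 1.0):
            raise ConfigError("grid: need 0 < x_min_frac < x_max_frac < 1")
        if not (self.t_min > 0 and self.t_max > self.t_min):
            raise ConfigError("grid: need 0 < t_min < t_max")
        if self.n_terms < 1:
            raise ConfigError("grid.n_terms must be >= 1")
        if self.nx < 2 or self.nt < 2:
            raise ConfigError("grid.nx and grid.nt must be >= 2")


@dataclass(frozen=True)
class ExchangeSpec:
    """Export rates of product species to the intercellular space.

    ``export_rate[k]`` is d_eN_mk/dtau1 in mol/s; ``dtau1`` is the
    characteristic exchange time, of the order of ``1/k_kin``.
    """

    export_rate: Mapping[str, float]
    dtau1: float

    def __post_init__(self):
        if not (self.dtau1 > 0):
            raise ConfigError("exchange.dtau1 must be > 0")


@dataclass(frozen=True)
class CaseStudy:
    """A fully parameterized cell: species table, reactions, geometry, thermal env."""

    label: str
    species: Mapping[str, ChemicalSpecies]
    reactions: tuple[Reaction, ...]
    geometry: CellGeometry
    env: ThermalEnv
    exchange: Mapping[str, ExchangeSpec]
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self):
        object.__setattr__(self, "reactions", tuple(self.reactions))
        names = [s.name for s in self.species.values()]
        if len(set(names)) != len(names):
            raise ConfigError("species names must be unique")
        wsum = sum(r.weight for r in self.reactions)
        if self.reactions and abs(wsum - 1.0) > 1e-12:
            raise ConfigError(
                f"reaction weights must sum to 1 (got {wsum!r}); "
                "set each reaction's 'weight'"
            )
        for r in self.reactions:
            for k in r.stoich:
                if k not in self.species:
                    raise ConfigError(
                        f"reaction {r.name!r}: species {k!r} missing from species table"
                    )
        for rname, ex in self.exchange.items():
            reac = self.reaction(rname)
            for k in ex.export_rate:
                if reac.stoich.get(k, 0) <= 0:
                    raise ConfigError(
                        f"exchange for reaction {rname!r}: export_rate given for "
                        f"{k!r}, which is not a product"
                    )

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise ConfigError(f"no reaction named {name!r}")

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for output provenance."""
        payload = json.dumps(_to_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# built-in case studies (glucose catabolism, breast cell)
# ---------------------------------------------------------------------------

#: Standard chemical potentials (kJ/mol) and diffusion coefficients in water
#: (m^2/s) at 298 K, 1 atm for the glucose-catabolism species.
SPECIES_TABLE = {
    "C6H12O6": (-917.44, 6.73e-10),
    "O2": (16.442, 1.00e-10),
    "CO2": (-385.99, 19.20e-10),
    "H2O": (-237.18, 21.00e-10),
    "lactate": (-516.72, 9.00e-10),
    "H+": (0.0, 45.00e-10),
}

RESPIRATION_STOICH = {"C6H12O6": -1.0, "O2": -6.0, "CO2": 6.0, "H2O": 6.0}
FERMENTATION_STOICH = {"C6H12O6": -1.0, "lactate": 2.0, "H+": 2.0}

K_KIN_RESP = 1e-4  # 1/s, respiration pathway kinetic constant
K_KIN_FERM = 1e-5  # 1/s, lactic fermentation pathway kinetic constant


def _species_map() -> dict[str, ChemicalSpecies]:
    return {
        name: ChemicalSpecies(name, mu0_kj * 1e3, D)
        for name, (mu0_kj, D) in SPECIES_TABLE.items()
    }


def _reactions(w_resp: float, w_ferm: float) -> tuple[Reaction, Reaction]:
    resp = Reaction(
        name="respiration",
        stoich=RESPIRATION_STOICH,
        k_kin=K_KIN_RESP,
        reagent_a="C6H12O6",
        p_ord=1,
        q_ord=0,
        weight=w_resp,
    )
    ferm = Reaction(
        name="fermentation",
        stoich=FERMENTATION_STOICH,
        k_kin=K_KIN_FERM,
        reagent_a="C6H12O6",
        p_ord=1,
        q_ord=0,
        weight=w_ferm,
    )
    return resp, ferm


def _default_exchange(reactions: tuple[Reaction, ...]) -> dict[str, ExchangeSpec]:
    # export rate |nu_k| * N_m,glucose * k_kin for each product; dtau1 = 1/k_kin
    out = {}
    for r in reactions:
        rates = {k: abs(r.stoich[k]) * r.k_kin for k in r.products}
        out[r.name] = ExchangeSpec(export_rate=rates, dtau1=1.0 / r.k_kin)
    return out


def builtin_cases(T0: float = 310.0) -> dict[str, CaseStudy]:
    """The two built-in breast-cell configurations (normal and cancer).

    Normal cell: L = 10 um, gap 0.25 um, 80% respiration / 20% fermentation,
    heat weight 0.85.  Cancer cell: L = 20 um, gap 1.5 um, 10% respiration /
    90% fermentation (Warburg shift), heat weight 0.90.  ``T0`` is the
    reference (maximum intercellular) temperature; it only rescales the
    fields and defaults to body temperature.
    """
    species = _species_map()
    cases = {}
    for label, L, gap, w_resp, w_ferm, p_heat in (
        ("normal", 10e-6, 0.25e-6, 0.8, 0.2, 0.85),
        ("cancer", 20e-6, 1.5e-6, 0.1, 0.9, 0.90),
    ):
        reactions = _reactions(w_resp, w_ferm)
        cases[label] = CaseStudy(
            label=label,
            species=species,
            reactions=reactions,
            geometry=CellGeometry(L=L, gap=gap, x0=10e-6),
            env=ThermalEnv(T0=T0, K_th=0.600, kappa=0.143e-6, tau=1e-4, p_heat=p_heat),
            exchange=_default_exchange(reactions),
        )
    return cases


# ---------------------------------------------------------------------------
# config file I/O (YAML; kJ/mol and um accepted, normalized to SI)
# ---------------------------------------------------------------------------


def _require(mapping, key, where):
    if key not in mapping:
        raise ConfigError(f"missing field {key!r} in {where}")
    return mapping[key]


def _scaled_for_write(value: float, unit: float) -> float:
    """Value expressed in ``unit`` such that multiplying back by ``unit``
    reproduces the SI value bit-exactly (config round-trip invariant)."""
    import math

    v = value / unit
    if v * unit == value:
        return v
    for w in (math.nextafter(v, math.inf), math.nextafter(v, -math.inf)):
        if w * unit == value:
            return w
    return v


def load_config(path: str | Path) -> CaseStudy:
    """Read a case-study configuration file and validate all invariants.

    Units in the file are human-readable (kJ/mol, um); the returned
    :class:`CaseStudy` is in SI.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")

    species = {}
    for entry in _require(doc, "species", "config"):
        name = _require(entry, "name", "species entry")
        mu0 = _require(entry, "mu0_kJ_per_mol", f"species {name!r}") * 1e3
        D = _require(entry, "D_m2_per_s", f"species {name!r}")
        species[name] = ChemicalSpecies(name=name, mu0=mu0, D=D)

    g = _require(doc, "geometry", "config")
    geometry = CellGeometry(
        L=_require(g, "L_um", "geometry") * 1e-6,
        gap=_require(g, "gap_um", "geometry") * 1e-6,
        x0=_require(g, "x0_um", "geometry") * 1e-6,
    )

    th = _require(doc, "thermal", "config")
    env = ThermalEnv(
        T0=_require(th, "T0_K", "thermal"),
        K_th=_require(th, "K_w_per_mK", "thermal"),
        kappa=_require(th, "kappa_m2_per_s", "thermal"),
        tau=_require(th, "tau_s", "thermal"),
        p_heat=_require(th, "p_heat", "thermal"),
    )

    reactions = []
    exchange = {}
    for entry in _require(doc, "reactions", "config"):
        name = _require(entry, "name", "reaction entry")
        r = Reaction(
            name=name,
            stoich={k: float(v) for k, v in _require(entry, "stoich", f"reaction {name!r}").items()},
            k_kin=_require(entry, "k_kin_per_s", f"reaction {name!r}"),
            reagent_a=_require(entry, "reagent_a", f"reaction {name!r}"),
            reagent_b=entry.get("reagent_b"),
            p_ord=entry.get("p_ord", 1),
            q_ord=entry.get("q_ord", 0),
            n_moles={k: float(v) for k, v in entry.get("n_moles", {}).items()},
            n_pr_moles=entry.get("n_pr_moles"),
            weight=_require(entry, "weight", f"reaction {name!r}"),
        )
        reactions.append(r)
        if "export_rate_mol_per_s" in entry:
            exchange[name] = ExchangeSpec(
                export_rate={k: float(v) for k, v in entry["export_rate_mol_per_s"].items()},
                dtau1=entry.get("dtau1_s", 1.0 / r.k_kin),
            )
    reactions = tuple(reactions)
    for r in reactions:
        if r.name not in exchange:
            exchange[r.name] = _default_exchange((r,))[r.name]

    grid = GridSpec(**doc.get("grid", {}))

    return CaseStudy(
        label=doc.get("label", path.stem),
        species=species,
        reactions=reactions,
        geometry=geometry,
        env=env,
        exchange=exchange,
        grid=grid,
    )


def write_config(case: CaseStudy, path: str | Path) -> None:
    """Write a :class:`CaseStudy` back to YAML (kJ/mol, um units).

    ``load_config(write_config(case))`` reproduces the case field-by-field.
    """
    doc = {
        "label": case.label,
        "species": [
            {"name": s.name, "mu0_kJ_per_mol": _scaled_for_write(s.mu0, 1e3),
             "D_m2_per_s": s.D}
            for s in case.species.values()
        ],
        "geometry": {
            "L_um": _scaled_for_write(case.geometry.L, 1e-6),
            "gap_um": _scaled_for_write(case.geometry.gap, 1e-6),
            "x0_um": _scaled_for_write(case.geometry.x0, 1e-6),
        },
        "thermal": {
            "T0_K": case.env.T0,
            "K_w_per_mK": case.env.K_th,
            "kappa_m2_per_s": case.env.kappa,
            "tau_s": case.env.tau,
            "p_heat": case.env.p_heat,
        },
        "reactions": [
            {
                "name": r.name,
                "stoich": dict(r.stoich),
                "k_kin_per_s": r.k_kin,
                "reagent_a": r.reagent_a,
                **({"reagent_b": r.reagent_b} if r.reagent_b else {}),
                "p_ord": r.p_ord,
                "q_ord": r.q_ord,
                "n_moles": dict(r.n_moles),
                "n_pr_moles": r.n_pr_moles,
                "weight": r.weight,
                "export_rate_mol_per_s": dict(case.exchange[r.name].export_rate),
                "dtau1_s": case.exchange[r.name].dtau1,
            }
            for r in case.reactions
        ],
        "grid": asdict(case.grid),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj
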