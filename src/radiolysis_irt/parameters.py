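"""Temperature- and pH-dependent chemical parameters for the chemical stage.

This module evaluates every physico-chemical input the reaction-time sampler
needs — rate constants, diffusion coefficients, the Onsager radius, water
density along the liquid–vapour coexistence curve, background concentrations
and scavenging capacities — and assembles them into a self-consistent
:class:`ChemicalTable` for one (temperature, pH) condition.

Conventions
-----------
* Temperatures are degrees Celsius in the public API unless a function says
  Kelvin.  The validated domain of the tabulated fits is [25, 150] °C; outside
  it a :class:`ParameterDomainError` is raised.
* Diffusion coefficients are reported in 1e-9 m²/s, which conveniently equals
  nm²/ns — the engine's internal unit.
* Bimolecular rate constants are M⁻¹ s⁻¹; background-scavenging channels get a
  pseudo-first-order *scavenging capacity* in s⁻¹ (rate constant times the
  background concentration).
* Reaction radii follow the Smoluchowski relation R = k / (4 π N_A D), with k
  the *observed* rate constant (re-dissociation folded in) and D the sum of
  the reactant diffusion coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "ParameterDomainError",
    "ParameterFileError",
    "Species",
    "Reaction",
    "WaterProperties",
    "ResolvedReaction",
    "ChemicalTable",
    "water_density",
    "relative_permittivity",
    "onsager_radius",
    "rate_constant",
    "diffusion_coefficient",
    "reaction_radius",
    "concentrations_from_ph",
    "scavenging_capacity",
    "water_concentration",
    "load_species",
    "load_reactions",
    "build_chemical_table",
]

# Physical constants (SI, CODATA 2018)
BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214076e23
ELEMENTARY_CHARGE_C = 1.602176634e-19
VACUUM_PERMITTIVITY = 8.8541878128e-12
GAS_CONSTANT_J_PER_MOL_K = 8.31446261815324

#: conversion of a molar rate constant (M^-1 s^-1) to particle-pair units
#: (nm^3 ns^-1): 1 L/mol/s = 1e24 nm^3 / N_A / 1e9 ns.
K_MOLAR_TO_NM3_PER_NS = 1.0e24 / AVOGADRO_PER_MOL / 1.0e9

#: water ion product at 25 degC, (mol/L)^2; held fixed for all pH scaling
#: (the temperature dependence of the water self-dissociation is deliberately
#: not modelled — see the methods note).
KW_25C = 1.0e-14

WATER_MOLAR_MASS_G_PER_MOL = 18.01528

TEMPERATURE_RANGE_C = (25.0, 150.0)

KINETICS_CLASSES = (
    "fully_diffusion_controlled",
    "partially_diffusion_controlled",
    "background_scavenging",
)

#: species allowed to act as homogeneously distributed background scavengers
BACKGROUND_CAPABLE = ("H3O+", "OH-", "H2O")

# atomic composition used by the stoichiometry validator; the hydrated
# electron carries charge but no atoms
_COMPOSITION = {
    "e_aq": (0, 0, -1),
    "OH": (1, 1, 0),
    "H": (1, 0, 0),
    "H2": (2, 0, 0),
    "H2O2": (2, 2, 0),
    "H3O+": (3, 1, +1),
    "OH-": (1, 1, -1),
    "HO2": (1, 2, 0),
    "H2O": (2, 1, 0),
}


class ParameterDomainError(ValueError):
    """An input lies outside the validated range of the parameter fits."""


class ParameterFileError(ValueError):
    """A species/reaction table file could not be parsed."""


def _check_temperature(t: float) -> None:
    lo, hi = TEMPERATURE_RANGE_C
    if not (lo <= t <= hi):
        raise ParameterDomainError(
            f"temperature {t} degC outside the validated range [{lo}, {hi}] degC"
        )


# ---------------------------------------------------------------------------
# water properties
# ---------------------------------------------------------------------------

def water_density(t: float) -> float:
    """Density of liquid water (g/ml) along the liquid–vapour coexistence curve.

    Quartic fit in t (°C), valid on [0, 150] °C; ~0.9975 at 25 °C and ~0.916
    at 150 °C.
    """
    if not (0.0 <= t <= 150.0):
        raise ParameterDomainError(
            f"temperature {t} degC outside the density fit range [0, 150] degC"
        )
    return (
        0.999
        + 1.094e-4 * t
        - 7.397e-6 * t**2
        + 2.693e-8 * t**3
        - 4.714e-11 * t**4
    )


def relative_permittivity(t: float) -> float:
    """Static relative permittivity of saturated liquid water at t (°C).

    Cubic correlation of the Malmberg–Maryott form, with the constant term
    anchored so that epsilon(25 °C) = 78.386, the value that makes the Onsager
    radius exactly 0.715 nm at 25 °C.
    """
    if not (0.0 <= t <= 150.0):
        raise ParameterDomainError(
            f"temperature {t} degC outside the permittivity fit range [0, 150] degC"
        )
    return 87.823 - 0.40008 * t + 9.398e-4 * t**2 - 1.410e-6 * t**3


def onsager_radius(temperature_k: float, epsilon: float) -> float:
    """Onsager radius r_c = e² / (4 π ε0 ε k_B T), in nm.

    The separation at which the Coulomb energy of two elementary charges
    equals the thermal energy; ~0.715 nm for water at 298.15 K.
    """
    if temperature_k <= 0:
        raise ParameterDomainError("absolute temperature must be positive")
    if epsilon <= 0:
        raise ParameterDomainError("relative permittivity must be positive")
    rc_m = ELEMENTARY_CHARGE_C**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY * epsilon
        * BOLTZMANN_J_PER_K * temperature_k
    )
    return rc_m * 1.0e9


def water_concentration(t: float) -> float:
    """Molar concentration of liquid water (mol/L) at t (°C) on the coexistence curve."""
    return water_density(t) * 1000.0 / WATER_MOLAR_MASS_G_PER_MOL


# ---------------------------------------------------------------------------
# temperature laws
# ---------------------------------------------------------------------------

def _evaluate_law(form: str, value25: float, p1: float, t: float) -> float:
    if form == "arrhenius":
        t_k = t + 273.15
        ea_j = p1 * 1.0e3
        return value25 * math.exp(
            (ea_j / GAS_CONSTANT_J_PER_MOL_K) * (1.0 / 298.15 - 1.0 / t_k)
        )
    if form == "linlog":
        return 10.0 ** (math.log10(value25) + p1 * (t - 25.0))
    if form == "none":
        return value25
    raise ParameterFileError(f"unknown temperature-law form {form!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """A chemical species of the scheme."""

    name: str
    charge: int
    is_background: bool
    d25: float          # diffusion coefficient at 25 C, 1e-9 m^2/s
    d_form: str = "arrhenius"
    d_p1: float = 0.0   # Arrhenius activation energy, kJ/mol

    def diffusion_coefficient(self, t: float) -> float:
        """D(t) in 1e-9 m²/s (== nm²/ns)."""
        _check_temperature(t)
        return _evaluate_law(self.d_form, self.d25, self.d_p1, t)


@dataclass(frozen=True)
class Reaction:
    """One reaction of the scheme with its temperature law."""

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    type_tag: int
    kinetics_class: str
    background: str | None  # which reactant is the background one (type 6)
    k_form: str = "arrhenius"
    k25: float = 0.0
    k_p1: float = 0.0

    def rate_constant(self, t: float) -> float:
        """Observed rate constant k(t) in M⁻¹ s⁻¹."""
        _check_temperature(t)
        return _evaluate_law(self.k_form, self.k25, self.k_p1, t)


@dataclass(frozen=True)
class WaterProperties:
    """Bulk water properties at one condition."""

    temperature_c: float
    temperature_k: float
    density_g_per_ml: float
    relative_permittivity: float
    onsager_radius_nm: float
    kw: float = KW_25C


@dataclass(frozen=True)
class ResolvedReaction:
    """A reaction with every condition-dependent quantity evaluated.

    For pair channels ``radius_nm`` is the Smoluchowski radius and
    ``mutual_diffusion`` the summed D (nm²/ns); for background-scavenging
    channels ``capacity_per_s`` is the pseudo-first-order rate.
    """

    reaction: Reaction
    rate_constant: float                 # M^-1 s^-1 at this temperature
    mutual_diffusion: float | None       # nm^2/ns (pair channels)
    radius_nm: float | None              # Smoluchowski radius (pair channels)
    charge_product: int                  # product of reactant charges
    capacity_per_s: float | None         # background channels only
    scavenged_species: str | None        # the non-background reactant

    @property
    def id(self) -> str:
        return self.reaction.id

    @property
    def is_background(self) -> bool:
        return self.reaction.kinetics_class == "background_scavenging"


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def rate_constant(reaction: Reaction, t: float) -> float:
    """Observed rate constant of ``reaction`` at t (°C), M⁻¹ s⁻¹."""
    return reaction.rate_constant(t)


def diffusion_coefficient(species: Species, t: float) -> float:
    """Diffusion coefficient of ``species`` at t (°C), 1e-9 m²/s."""
    return species.diffusion_coefficient(t)


def reaction_radius(k: float, d_mutual: float) -> float:
    """Smoluchowski reaction radius R = k / (4 π N_A D) in nm.

    ``k`` in M⁻¹ s⁻¹, ``d_mutual`` (sum of the two reactant diffusion
    coefficients) in 1e-9 m²/s.
    """
    if k < 0:
        raise ParameterDomainError("rate constant must be non-negative")
    if d_mutual <= 0:
        raise ParameterDomainError("mutual diffusion coefficient must be positive")
    return (k * K_MOLAR_TO_NM3_PER_NS) / (4.0 * math.pi * d_mutual)


def concentrations_from_ph(ph: float, t: float = 25.0) -> tuple[float, float]:
    """([H3O+], [OH-]) in mol/L for a given pH.

    [H3O+] = 10^-pH and [OH-] = Kw / [H3O+], with Kw held at its 25 °C value
    (1e-14) at every temperature.
    """
    if not (0.0 < ph < 14.0):
        raise ParameterDomainError(f"pH {ph} outside the supported open range (0, 14)")
    _check_temperature(t)
    h3o = 10.0 ** (-ph)
    return h3o, KW_25C / h3o


def scavenging_capacity(k_obs: float, conc: float) -> float:
    """Scavenging capacity k_obs × concentration, in s⁻¹.

    The pseudo-first-order rate at which a spur species is removed by a
    homogeneously distributed background solute.
    """
    if k_obs < 0 or conc < 0:
        raise ParameterDomainError("rate constant and concentration must be non-negative")
    return k_obs * conc


# ---------------------------------------------------------------------------
# table files
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("radiolysis_irt").joinpath("data", name)))


def _read_rows(path: Path, columns: Sequence[str]) -> Iterable[tuple[int, dict]]:
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = cells
                missing = [c for c in columns if c not in header]
                if missing:
                    raise ParameterFileError(
                        f"{path}:{lineno}: missing required columns {missing}"
                    )
                continue
            if len(cells) != len(header):
                raise ParameterFileError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(cells)}"
                )
            yield lineno, dict(zip(header, cells))


_SPECIES_COLUMNS = ("name", "charge", "is_background", "d25", "d_form", "d_p1")
_REACTION_COLUMNS = (
    "id", "reactants", "products", "type_tag", "kinetics_class",
    "background", "k_form", "k25", "k_p1",
)


def load_species(path: str | Path | None = None) -> dict[str, Species]:
    """Load a species table; the packaged defaults when ``path`` is None."""
    path = _data_path("species.csv") if path is None else Path(path)
    out: dict[str, Species] = {}
    for lineno, row in _read_rows(path, _SPECIES_COLUMNS):
        try:
            sp = Species(
                name=row["name"],
                charge=int(row["charge"]),
                is_background=bool(int(row["is_background"])),
                d25=float(row["d25"]),
                d_form=row["d_form"],
                d_p1=float(row["d_p1"]),
            )
        except (KeyError, ValueError) as exc:
            raise ParameterFileError(f"{path}:{lineno}: {exc}") from exc
        if sp.charge not in (-1, 0, 1):
            raise ParameterFileError(
                f"{path}:{lineno}: charge must be -1, 0 or +1, got {sp.charge}"
            )
        if sp.d25 <= 0:
            raise ParameterFileError(f"{path}:{lineno}: diffusion coefficient must be positive")
        out[sp.name] = sp
    if "H2O" in out and not out["H2O"].is_background:
        raise ParameterFileError(f"{path}: H2O must be flagged as background")
    return out


def _validate_stoichiometry(rxn: Reaction, path: Path | str, lineno: int) -> None:
    """H/O atom counts must balance up to whole water molecules; charge exactly."""
    dh = do = dq = 0
    for name in rxn.reactants:
        h, o, q = _COMPOSITION[name]
        dh += h
        do += o
        dq += q
    for name in rxn.products:
        h, o, q = _COMPOSITION[name]
        dh -= h
        do -= o
        dq -= q
    if dq != 0:
        raise ParameterFileError(f"{path}:{lineno}: reaction {rxn.id} does not conserve charge")
    # surplus/deficit must be n * H2O
    if do * 2 != dh or dh % 2 != 0:
        raise ParameterFileError(
            f"{path}:{lineno}: reaction {rxn.id} does not conserve H/O atoms "
            f"(residual H={dh}, O={do} is not a whole number of water molecules)"
        )


def load_reactions(
    path: str | Path | None = None,
    species: dict[str, Species] | None = None,
) -> list[Reaction]:
    """Load a reaction table; the packaged defaults when ``path`` is None."""
    path = _data_path("reactions.csv") if path is None else Path(path)
    species = load_species() if species is None else species
    out: list[Reaction] = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path, _REACTION_COLUMNS):
        try:
            rxn = Reaction(
                id=row["id"],
                reactants=tuple(s for s in row["reactants"].split("|") if s),
                products=tuple(s for s in row["products"].split("|") if s),
                type_tag=int(row["type_tag"]),
                kinetics_class=row["kinetics_class"],
                background=row["background"] or None,
                k_form=row["k_form"],
                k25=float(row["k25"]),
                k_p1=float(row["k_p1"]),
            )
        except (KeyError, ValueError) as exc:
            raise ParameterFileError(f"{path}:{lineno}: {exc}") from exc
        if rxn.id in seen:
            raise ParameterFileError(f"{path}:{lineno}: duplicate reaction id {rxn.id}")
        seen.add(rxn.id)
        if rxn.kinetics_class not in KINETICS_CLASSES:
            raise ParameterFileError(
                f"{path}:{lineno}: unknown kinetics_class {rxn.kinetics_class!r} "
                f"(expected one of {KINETICS_CLASSES}); out-of-table reactions must "
                "declare it explicitly"
            )
        if not (1 <= len(rxn.reactants) <= 2):
            raise ParameterFileError(f"{path}:{lineno}: reactions need 1 or 2 reactants")
        unknown = [s for s in (*rxn.reactants, *rxn.products) if s not in species]
        if unknown:
            raise ParameterFileError(f"{path}:{lineno}: unknown species {unknown}")
        if rxn.kinetics_class == "background_scavenging":
            if rxn.background not in rxn.reactants:
                raise ParameterFileError(
                    f"{path}:{lineno}: background species {rxn.background!r} must be a reactant"
                )
            if rxn.background not in BACKGROUND_CAPABLE:
                raise ParameterFileError(
                    f"{path}:{lineno}: {rxn.background!r} cannot act as a background scavenger"
                )
            non_bg = [s for s in rxn.reactants if s != rxn.background]
            if len(non_bg) != 1:
                raise ParameterFileError(
                    f"{path}:{lineno}: background-scavenging reactions need exactly one "
                    "non-background reactant"
                )
        elif rxn.background:
            raise ParameterFileError(
                f"{path}:{lineno}: only background_scavenging reactions name a background reactant"
            )
        if rxn.k25 < 0:
            raise ParameterFileError(f"{path}:{lineno}: rate constant must be non-negative")
        _validate_stoichiometry(rxn, path, lineno)
        out.append(rxn)
    return out


# ---------------------------------------------------------------------------
# the assembled table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemicalTable:
    """All chemistry-stage parameters resolved for one (temperature, pH) condition."""

    temperature_c: float
    ph: float
    species: dict[str, Species]
    reactions: tuple[ResolvedReaction, ...]
    water: WaterProperties
    h3o_conc: float   # mol/L
    oh_conc: float    # mol/L
    diffusion: dict[str, float] = field(default_factory=dict)  # nm^2/ns

    @property
    def pair_reactions(self) -> tuple[ResolvedReaction, ...]:
        return tuple(r for r in self.reactions if not r.is_background)

    @property
    def background_reactions(self) -> tuple[ResolvedReaction, ...]:
        return tuple(r for r in self.reactions if r.is_background)

    def reaction(self, reaction_id: str) -> ResolvedReaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(f"no reaction {reaction_id!r} in the table")


def build_chemical_table(
    temperature: float,
    ph: float,
    overrides: str | Path | None = None,
    species_path: str | Path | None = None,
    reactions_path: str | Path | None = None,
) -> ChemicalTable:
    """Assemble the fully resolved :class:`ChemicalTable` for one condition.

    Deterministic for fixed inputs; every derived quantity (reaction radii,
    scavenging capacities, Onsager radius, density, background concentrations)
    is evaluated once here.  ``overrides`` is a reaction file in the packaged
    dialect whose rows replace (by id) or extend the default scheme.
    """
    _check_temperature(temperature)
    species = load_species(species_path)
    reactions = load_reactions(reactions_path, species)
    if overrides is not None:
        replacement = {r.id: r for r in load_reactions(overrides, species)}
        reactions = [replacement.pop(r.id, r) for r in reactions]
        reactions.extend(replacement.values())
    if not reactions:
        raise ParameterFileError("reaction table is empty")

    t_k = temperature + 273.15
    eps = relative_permittivity(temperature)
    water = WaterProperties(
        temperature_c=temperature,
        temperature_k=t_k,
        density_g_per_ml=water_density(temperature),
        relative_permittivity=eps,
        onsager_radius_nm=onsager_radius(t_k, eps),
    )
    h3o, oh = concentrations_from_ph(ph, temperature)
    conc = {
        "H3O+": h3o,
        "OH-": oh,
        "H2O": water_concentration(temperature),
    }
    diffusion = {
        name: sp.diffusion_coefficient(temperature) for name, sp in species.items()
    }

    resolved: list[ResolvedReaction] = []
    for rxn in reactions:
        k = rxn.rate_constant(temperature)
        if rxn.kinetics_class == "background_scavenging":
            target = next(s for s in rxn.reactants if s != rxn.background)
            resolved.append(
                ResolvedReaction(
                    reaction=rxn,
                    rate_constant=k,
                    mutual_diffusion=None,
                    radius_nm=None,
                    charge_product=0,
                    capacity_per_s=scavenging_capacity(k, conc[rxn.background]),
                    scavenged_species=target,
                )
            )
        else:
            if len(rxn.reactants) != 2:
                raise ParameterFileError(
                    f"pair reaction {rxn.id} must have two reactants"
                )
            a, b = rxn.reactants
            d_mut = diffusion[a] + diffusion[b]
            resolved.append(
                ResolvedReaction(
                    reaction=rxn,
                    rate_constant=k,
                    mutual_diffusion=d_mut,
                    radius_nm=reaction_radius(k, d_mut) if k > 0 else 0.0,
                    charge_product=species[a].charge * species[b].charge,
                    capacity_per_s=None,
                    scavenged_species=None,
                )
            )

    return ChemicalTable(
        temperature_c=temperature,
        ph=ph,
        species=species,
        reactions=tuple(resolved),
        water=water,
        h3o_conc=h3o,
        oh_conc=oh,
        diffusion=diffusion,
    )
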