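"""Synthetic spur generator: the chemistry-stage initial condition.

A *spur* is the localized cluster of reactive species left around one energy
deposition site once the physical and physico-chemical stages are over
(~1 ps).  This module emulates that hand-off: given per-channel initial
yields (species per 100 eV), per-species Gaussian spatial spreads and an
energy per spur, it draws the species identities and 3D positions the
reaction-time engine starts from.

Spur composition is sampled per water-decomposition channel rather than per
species, so every generated spur is exactly charge neutral and exactly
balanced between reducing and oxidizing equivalents; the material-balance
diagnostic downstream therefore probes the chemistry engine, not generator
shot noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SpurChannel",
    "SpurModel",
    "SpurState",
    "generate_spur",
    "generate_ensemble",
    "dump_particle_table",
    "load_particle_table",
]


@dataclass(frozen=True)
class SpurChannel:
    """One water-decomposition channel with its 1 ps yield (per 100 eV)."""

    name: str
    yield_per_100ev: float
    products: tuple[str, ...]


@dataclass(frozen=True)
class SpurModel:
    """Parameterization of the pre-chemical hand-off.

    ``sigma_nm`` maps species name -> per-axis rms Gaussian displacement about
    the spur centre ("default" applies to unlisted species).  ``sigma_scale``
    is an optional hook for temperature-dependent thermalization-distance
    scaling; 1.0 leaves the packaged spreads untouched.
    """

    channels: tuple[SpurChannel, ...]
    sigma_nm: dict[str, float]
    energy_per_spur_ev: float = 62.5
    creation_time_ns: float = 1.0e-3
    sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        if any(ch.yield_per_100ev < 0 for ch in self.channels):
            raise ValueError("channel yields must be non-negative")
        if self.energy_per_spur_ev < 0:
            raise ValueError("energy per spur must be non-negative")
        if self.sigma_scale <= 0:
            raise ValueError("sigma_scale must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpurModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        channels = tuple(
            SpurChannel(name, float(body["yield_per_100eV"]), tuple(body["products"]))
            for name, body in raw["channels"].items()
        )
        return cls(
            channels=channels,
            sigma_nm={k: float(v) for k, v in raw["sigma_nm"].items()},
            energy_per_spur_ev=float(raw.get("energy_per_spur_eV", 62.5)),
            creation_time_ns=float(raw.get("creation_time_ns", 1.0e-3)),
        )

    @classmethod
    def default(cls) -> "SpurModel":
        path = resources.files("radiolysis_irt").joinpath("data", "spur_model.yaml")
        return cls.from_yaml(str(path))

    def initial_yields(self) -> dict[str, float]:
        """Implied per-species yields (per 100 eV) at the start of the chemical stage."""
        out: dict[str, float] = {}
        for ch in self.channels:
            for sp in ch.products:
                out[sp] = out.get(sp, 0.0) + ch.yield_per_100ev
        return out

    def sigma_of(self, species: str) -> float:
        base = self.sigma_nm.get(species, self.sigma_nm.get("default"))
        if base is None:
            raise KeyError(f"no sigma for species {species!r} and no default")
        return base * self.sigma_scale


@dataclass
class SpurState:
    """Species identities and positions (nm) at the start of the chemical stage."""

    species: list[str]
    positions: np.ndarray          # (n, 3) nm
    deposited_energy_ev: float
    creation_time_ns: float = 1.0e-3

    def __len__(self) -> int:
        return len(self.species)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sp in self.species:
            out[sp] = out.get(sp, 0) + 1
        return out


def generate_spur(model: SpurModel, rng: np.random.Generator | int) -> SpurState:
    """Draw one spur: Poisson channel counts, isotropic Gaussian positions.

    Reproducible for a fixed integer seed or a caller-provided Generator.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    species: list[str] = []
    scale = model.energy_per_spur_ev / 100.0
    for ch in model.channels:
        n = int(rng.poisson(ch.yield_per_100ev * scale)) if scale > 0 else 0
        for _ in range(n):
            species.extend(ch.products)
    sigmas = np.array([model.sigma_of(sp) for sp in species], dtype=float)
    positions = rng.standard_normal((len(species), 3)) * sigmas[:, None]
    return SpurState(
        species=species,
        positions=positions,
        deposited_energy_ev=model.energy_per_spur_ev if species or scale > 0 else 0.0,
        creation_time_ns=model.creation_time_ns,
    )


def generate_ensemble(
    model: SpurModel, n_histories: int, rng_seed: int
) -> list[SpurState]:
    """Independent spurs with per-history sub-seeds spawned from one master seed."""
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    streams = np.random.SeedSequence(rng_seed).spawn(n_histories)
    return [generate_spur(model, np.random.default_rng(s)) for s in streams]


_TABLE_HEADER = "history,species,x_nm,y_nm,z_nm,energy_ev"


def dump_particle_table(ensemble: list[SpurState], path: str | Path) -> None:
    """Write an ensemble as a plain-text particle table (one row per particle)."""
    with open(path, "w") as fh:
        fh.write(_TABLE_HEADER + "\n")
        for hist, spur in enumerate(ensemble):
            if len(spur) == 0:
                fh.write(f"{hist},,,,,{spur.deposited_energy_ev:.6g}\n")
            for sp, pos in zip(spur.species, spur.positions):
                fh.write(
                    f"{hist},{sp},{pos[0]:.6f},{pos[1]:.6f},{pos[2]:.6f},"
                    f"{spur.deposited_energy_ev:.6g}\n"
                )


def load_particle_table(path: str | Path) -> list[SpurState]:
    """Read a particle table back into an ensemble of spur states."""
    histories: dict[int, tuple[list[str], list[list[float]], float]] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _TABLE_HEADER:
            raise ValueError(f"unexpected particle-table header {header!r}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            hist_s, sp, x, y, z, e = line.split(",")
            hist = int(hist_s)
            entry = histories.setdefault(hist, ([], [], float(e)))
            if sp:
                entry[0].append(sp)
                entry[1].append([float(x), float(y), float(z)])
    out = []
    for hist in sorted(histories):
        names, coords, energy = histories[hist]
        out.append(
            SpurState(
                species=names,
                positions=np.array(coords, dtype=float).reshape(len(names), 3),
                deposited_energy_ev=energy,
            )
        )
    return out
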