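"""Run configuration: validation, serialization and seed bookkeeping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .parameters import ParameterDomainError, TEMPERATURE_RANGE_C

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything one simulation needs; validated before anything runs.

    Times are microseconds at this level (the engine works in ns internally).
    The time grid is logarithmic with ``grid_points`` points between
    ``grid_tmin_us`` and ``grid_tmax_us``; the simulation itself truncates at
    ``end_time_us``, after which counts are frozen.
    """

    temperature_c: float = 25.0
    ph: float = 7.0
    n_runs: int = 2
    n_histories_per_run: int = 500
    rng_seed: int = 1
    end_time_us: float = 1.0
    grid_tmin_us: float = 1.0e-3
    grid_tmax_us: float = 1.0e3
    grid_points: int = 50
    spur_model_path: str | None = None
    overrides_path: str | None = None
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        lo, hi = TEMPERATURE_RANGE_C
        if not (lo <= self.temperature_c <= hi):
            raise ParameterDomainError(
                f"temperature {self.temperature_c} degC outside [{lo}, {hi}] degC"
            )
        if not (0.0 < self.ph < 14.0):
            raise ParameterDomainError(f"pH {self.ph} outside the open range (0, 14)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.n_histories_per_run < 1:
            raise ValueError("n_histories_per_run must be >= 1")
        if self.end_time_us <= 0:
            raise ValueError("end_time_us must be positive")
        if not (0 < self.grid_tmin_us < self.grid_tmax_us):
            raise ValueError("grid must satisfy 0 < tmin < tmax")
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash of the scientific configuration.

        The output directory is excluded: it does not affect the results, and
        the same simulation written to two places must hash identically.
        """
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    # -- seeds -------------------------------------------------------------

    def run_seed(self, run_index: int) -> int:
        """Documented counter scheme: one master seed spawns per-run streams."""
        if not (0 <= run_index < self.n_runs):
            raise ValueError("run index out of range")
        return (int(self.rng_seed) * 100003 + 7919 * run_index) % (2**31 - 1)
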