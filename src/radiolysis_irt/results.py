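"""Result containers shared by the simulation engines and the analysis layer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReactionEvent", "EventTimeline", "GValueSeries", "MaterialBalanceReport"]


@dataclass(frozen=True)
class ReactionEvent:
    """One realized reaction: when it fired, which channel, who was consumed."""

    time_ns: float
    reaction_id: str
    consumed: tuple[str, ...]      # species names removed
    produced: tuple[str, ...]      # species names added (background products omitted)


@dataclass
class EventTimeline:
    """Ordered realized reactions of one history plus its initial composition."""

    events: list[ReactionEvent]
    initial_counts: dict[str, int]
    deposited_energy_ev: float
    creation_time_ns: float = 1.0e-3

    def counts_at(self, times_ns: np.ndarray, species: list[str]) -> np.ndarray:
        """Species counts on a time grid, shape (len(species), len(times))."""
        times_ns = np.asarray(times_ns, dtype=float)
        idx = {name: i for i, name in enumerate(species)}
        out = np.zeros((len(species), times_ns.size), dtype=np.int64)
        for name, n in self.initial_counts.items():
            if name in idx:
                out[idx[name], :] += n
        for ev in self.events:
            after = times_ns >= ev.time_ns
            for name in ev.consumed:
                if name in idx:
                    out[idx[name], after] -= 1
            for name in ev.produced:
                if name in idx:
                    out[idx[name], after] += 1
        return out


@dataclass
class GValueSeries:
    """Per-species G(t) on a log time grid with between-run standard errors.

    ``g`` and ``stderr`` have shape (n_species, n_times); G is expressed in
    molecules per 100 eV of deposited energy.
    """

    times_us: np.ndarray
    species: list[str]
    g: np.ndarray
    stderr: np.ndarray
    temperature_c: float
    ph: float
    n_runs: int
    n_histories_per_run: int
    seed: int
    per_run_g: np.ndarray | None = None   # (n_runs, n_species, n_times)
    total_energy_ev: float = 0.0

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def g_of(self, name: str) -> np.ndarray:
        return self.g[self.species_index(name)]

    def at_time(self, t_us: float) -> dict[str, float]:
        """G per species at the first grid point >= t_us (counts are frozen
        after the simulation end time, so this equals G(t_us) whenever t_us is
        at or past the last event)."""
        i = int(np.searchsorted(self.times_us, t_us * (1 - 1e-12)))
        i = min(i, self.times_us.size - 1)
        return {name: float(self.g[j, i]) for j, name in enumerate(self.species)}

    def stderr_at_time(self, t_us: float) -> dict[str, float]:
        i = int(np.searchsorted(self.times_us, t_us * (1 - 1e-12)))
        i = min(i, self.times_us.size - 1)
        return {name: float(self.stderr[j, i]) for j, name in enumerate(self.species)}


@dataclass(frozen=True)
class MaterialBalanceReport:
    """Redox bookkeeping: G_red = G(e_aq) + 2 G(H2) + G(H) versus
    G_ox = G(OH) + 2 G(H2O2) + 3 G(HO2), and their discrepancy as a
    percentage of the mean."""

    g_red: float
    g_ox: float
    difference_pct: float
    red_terms: dict[str, float] = field(default_factory=dict)
    ox_terms: dict[str, float] = field(default_factory=dict)
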