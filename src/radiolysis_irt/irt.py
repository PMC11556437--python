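"""The independent-reaction-times (IRT) engine.

IRT replaces explicit Brownian trajectories with a single draw per reactive
pair: from the initial separation r0 and the channel's encounter radius, a
tentative reaction time is sampled from the first-passage distribution of the
pair's relative diffusion,

    W(t) = (a / r0) * erfc((r0 - a) / sqrt(4 D t)),

whose t -> inf limit W_inf = a / r0 is the classic Smoluchowski reaction
probability.  Background-scavenging channels contribute exponential deviates
at their scavenging capacity.  Events are then realized in global time order:
the earliest tentative reaction fires, its reactants disappear (cancelling
their other channels), products are placed and sampled against the survivors,
and the process repeats until the end time.

Charged pairs: for fully-diffusion-controlled reactions between ions the
separation is mapped through the Debye transform
r -> rc_s / (exp(rc_s / r) - 1), where rc_s is the Onsager radius signed by
the product of the charges, while the encounter radius is the Smoluchowski
radius itself: derived from the *observed* rate constant, it is already the
Coulomb-inclusive effective radius (k_obs = 4 pi N_A D r_eff).  Together
these reproduce the exact Debye-Smoluchowski ultimate reaction probability.
The :func:`effective_radius` helper maps an intrinsic *contact* radius to
its Debye-effective value — the construction needed when a channel is
specified geometrically (as the Brownian-dynamics cross-checks are) rather
than through an observed rate constant.  Partially-diffusion-controlled
channels use the Smoluchowski radius with no separation transform: their
observed rate constant folds in every interaction and re-dissociation
effect.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfcinv

from .config import RunConfig
from .parameters import ChemicalTable
from .results import EventTimeline, GValueSeries, ReactionEvent
from .spur import SpurModel, SpurState, generate_spur

__all__ = [
    "effective_radius",
    "PairChannel",
    "sample_pair_time",
    "sample_scavenging_time",
    "resolve_history",
    "run_ensemble",
]

_CONTACT_OFFSET_NM = 0.29  # one water diameter; separates co-located products


def _debye_transform(r: float, rc_signed: float) -> float:
    """Map a radius through the Debye factor rc_s / (exp(rc_s/r) - 1).

    Attractive pairs (rc_signed < 0) are inflated, repulsive ones shrunk;
    the neutral limit rc_signed -> 0 returns r unchanged.
    """
    if r <= 0:
        return r
    x = rc_signed / r
    if abs(x) < 1.0e-12:
        return r
    return rc_signed / math.expm1(x)


def effective_radius(radius_nm: float, rc_nm: float, charge_product: int) -> float:
    """Debye-corrected encounter radius for a charged pair (nm).

    Neutral pairs (charge_product == 0) keep the Smoluchowski radius; opposite
    charges are boosted, like charges suppressed.
    """
    if radius_nm <= 0:
        raise ValueError("reaction radius must be positive")
    if charge_product == 0 or rc_nm == 0:
        return radius_nm
    return _debye_transform(radius_nm, rc_nm * (1 if charge_product > 0 else -1))


@dataclass
class PairChannel:
    """A tentative pairwise reaction: geometry, kinetics, sampled time."""

    i: int
    j: int
    reaction_id: str
    r0_nm: float
    effective_radius_nm: float      # encounter radius after any Debye correction
    r0_effective_nm: float          # separation after the same correction
    mutual_diffusion: float         # nm^2/ns
    sampled_time_ns: float = math.inf


def sample_pair_time(channel: PairChannel, u: float) -> float:
    """Invert the first-passage law for one uniform deviate; ns or +inf.

    With probability W_inf = a/r0 (effective radii) returns the finite
    first-passage time; otherwise the pair never reacts.  A separation at or
    inside the encounter radius reacts immediately (contact).
    """
    a = channel.effective_radius_nm
    s = channel.r0_effective_nm
    d = channel.mutual_diffusion
    if a <= 0 or d <= 0:
        return math.inf
    if s <= a:
        return 0.0
    w_inf = a / s
    if u >= w_inf:
        return math.inf
    x = float(erfcinv(u / w_inf))
    if not math.isfinite(x) or x <= 0:
        return math.inf if x <= 0 else 0.0
    return (s - a) ** 2 / (4.0 * d * x * x)


def sample_scavenging_time(capacity_per_s: float, u: float) -> float:
    """Exponential deviate -ln(u)/capacity in ns; +inf at zero capacity."""
    if capacity_per_s < 0:
        raise ValueError("scavenging capacity must be non-negative")
    if capacity_per_s == 0.0:
        return math.inf
    return -math.log(u) / (capacity_per_s * 1.0e-9)


# ---------------------------------------------------------------------------
# compiled scheme (per-table cache of everything sampling needs)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _PairEntry:
    reaction_id: str
    reactants: tuple[str, str]
    products: tuple[str, ...]
    radius_nm: float              # encounter radius (Debye-corrected if charged FDC)
    rc_signed: float | None       # None -> neutral treatment of the separation
    mutual_diffusion: float


@dataclass(frozen=True)
class _BackgroundEntry:
    reaction_id: str
    target: str
    products: tuple[str, ...]
    capacity_per_s: float


class _CompiledScheme:
    """ChemicalTable lowered to lookup structures for the event loop."""

    def __init__(self, table: ChemicalTable):
        self.table = table
        self.tracked = [n for n, sp in table.species.items() if not sp.is_background]
        rc = table.water.onsager_radius_nm
        self.pairs: dict[tuple[str, str], list[_PairEntry]] = {}
        self.background: dict[str, list[_BackgroundEntry]] = {}
        for rr in table.reactions:
            rxn = rr.reaction
            if rr.is_background:
                assert rr.scavenged_species is not None
                products = tuple(
                    p for p in rxn.products if not table.species[p].is_background
                )
                self.background.setdefault(rr.scavenged_species, []).append(
                    _BackgroundEntry(
                        reaction_id=rxn.id,
                        target=rr.scavenged_species,
                        products=products,
                        capacity_per_s=rr.capacity_per_s or 0.0,
                    )
                )
                continue
            if rr.radius_nm is None or rr.radius_nm <= 0:
                continue  # zero-rate channel never fires
            if (
                rxn.kinetics_class == "fully_diffusion_controlled"
                and rr.charge_product != 0
            ):
                # The Smoluchowski radius from the *observed* rate constant is
                # already the Coulomb-inclusive effective encounter radius
                # (k_obs = 4 pi N_A D r_eff); only the separation still needs
                # the Debye transform.
                radius = rr.radius_nm
                rc_signed = rc * (1 if rr.charge_product > 0 else -1)
            else:
                radius = rr.radius_nm
                rc_signed = None
            a, b = rxn.reactants
            key = (a, b) if a <= b else (b, a)
            products = tuple(
                p for p in rxn.products if not table.species[p].is_background
            )
            self.pairs.setdefault(key, []).append(
                _PairEntry(
                    reaction_id=rxn.id,
                    reactants=(a, b),
                    products=products,
                    radius_nm=radius,
                    rc_signed=rc_signed,
                    mutual_diffusion=rr.mutual_diffusion or 0.0,
                )
            )


def _make_pair_channel(
    entry: _PairEntry, i: int, j: int, r0: float
) -> PairChannel:
    if entry.rc_signed is None:
        s = r0
    else:
        s = _debye_transform(r0, entry.rc_signed)
    return PairChannel(
        i=i,
        j=j,
        reaction_id=entry.reaction_id,
        r0_nm=r0,
        effective_radius_nm=entry.radius_nm,
        r0_effective_nm=s,
        mutual_diffusion=entry.mutual_diffusion,
    )


# ---------------------------------------------------------------------------
# one history
# ---------------------------------------------------------------------------

def resolve_history(
    spur: SpurState,
    table: ChemicalTable,
    end_time_ns: float,
    rng_seed: int | np.random.Generator,
    scheme: _CompiledScheme | None = None,
) -> EventTimeline:
    """Run the IRT event loop on one spur and return its realized timeline.

    Deterministic for a fixed seed: channels are sampled in construction
    order and ties in sampled times are broken by channel creation index.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    scheme = _CompiledScheme(table) if scheme is None else scheme
    t0 = spur.creation_time_ns
    if end_time_ns <= t0:
        raise ValueError("end time must exceed the spur creation time")

    species: list[str] = list(spur.species)
    positions: list[np.ndarray] = [np.asarray(p, dtype=float) for p in spur.positions]
    alive: list[bool] = [True] * len(species)
    heap: list[tuple[float, int, int, int, object]] = []
    seq = 0

    def push_pair(i: int, j: int, t_now: float) -> None:
        nonlocal seq
        a, b = species[i], species[j]
        key = (a, b) if a <= b else (b, a)
        for entry in scheme.pairs.get(key, ()):
            # orient indices to the entry's reactant order for bookkeeping
            r0 = float(np.linalg.norm(positions[i] - positions[j]))
            if r0 <= 0:
                r0 = 1.0e-6
            channel = _make_pair_channel(entry, i, j, r0)
            dt = sample_pair_time(channel, rng.random())
            t_evt = t_now + dt
            if t_evt <= end_time_ns:
                heapq.heappush(heap, (t_evt, seq, i, j, entry))
                seq += 1

    def push_background(i: int, t_now: float) -> None:
        nonlocal seq
        for entry in scheme.background.get(species[i], ()):
            dt = sample_scavenging_time(entry.capacity_per_s, rng.random())
            t_evt = t_now + dt
            if t_evt <= end_time_ns:
                heapq.heappush(heap, (t_evt, seq, i, -1, entry))
                seq += 1

    n0 = len(species)
    for i in range(n0):
        push_background(i, t0)
    for i in range(n0):
        for j in range(i + 1, n0):
            push_pair(i, j, t0)

    events: list[ReactionEvent] = []
    while heap:
        t_evt, _, i, j, entry = heapq.heappop(heap)
        if t_evt > end_time_ns:
            break
        if not alive[i] or (j >= 0 and not alive[j]):
            continue  # stale channel of a consumed particle
        if isinstance(entry, _BackgroundEntry):
            parent_pos = positions[i]
            consumed = (species[i],)
            alive[i] = False
            parent_radius = _CONTACT_OFFSET_NM
        else:
            w_i, w_j = (
                math.sqrt(table.diffusion[species[i]]),
                math.sqrt(table.diffusion[species[j]]),
            )
            parent_pos = (w_i * positions[i] + w_j * positions[j]) / (w_i + w_j)
            consumed = (species[i], species[j])
            alive[i] = alive[j] = False
            parent_radius = max(entry.radius_nm, _CONTACT_OFFSET_NM)

        new_indices: list[int] = []
        for m, prod in enumerate(entry.products):
            offset = (
                np.zeros(3)
                if m == 0 and len(entry.products) == 1
                else _random_unit(rng) * 0.5 * parent_radius
            )
            species.append(prod)
            positions.append(parent_pos + offset)
            alive.append(True)
            new_indices.append(len(species) - 1)

        events.append(
            ReactionEvent(
                time_ns=t_evt,
                reaction_id=entry.reaction_id,
                consumed=consumed,
                produced=tuple(entry.products),
            )
        )

        # new channels: products vs survivors, products vs products, background
        for p in new_indices:
            push_background(p, t_evt)
        for p in new_indices:
            for s_idx in range(len(species)):
                if s_idx == p or not alive[s_idx]:
                    continue
                if s_idx in new_indices and s_idx < p:
                    continue  # product-product pair already pushed
                push_pair(min(p, s_idx), max(p, s_idx), t_evt)

    events.sort(key=lambda e: e.time_ns)
    return EventTimeline(
        events=events,
        initial_counts=spur.counts(),
        deposited_energy_ev=spur.deposited_energy_ev,
        creation_time_ns=t0,
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = float(np.linalg.norm(v))
    while n < 1.0e-12:
        v = rng.standard_normal(3)
        n = float(np.linalg.norm(v))
    return v / n


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def run_ensemble(
    model: SpurModel,
    table: ChemicalTable,
    config: RunConfig,
) -> GValueSeries:
    """Simulate n_runs x n_histories spurs and assemble per-species G(t).

    G(t) = 100 * N_species(t) / E_total per run; the reported curve is the
    between-run mean with the between-run standard error of the mean.
    """
    scheme = _CompiledScheme(table)
    times_us = np.geomspace(
        config.grid_tmin_us, config.grid_tmax_us, config.grid_points
    )
    times_ns = times_us * 1.0e3
    end_ns = config.end_time_us * 1.0e3
    tracked = scheme.tracked

    per_run_g = np.zeros((config.n_runs, len(tracked), times_ns.size))
    total_energy = 0.0
    for run in range(config.n_runs):
        run_stream = np.random.SeedSequence(config.run_seed(run))
        counts = np.zeros((len(tracked), times_ns.size), dtype=np.int64)
        energy = 0.0
        for hist_stream in run_stream.spawn(config.n_histories_per_run):
            spur_ss, engine_ss = hist_stream.spawn(2)
            spur = generate_spur(model, np.random.default_rng(spur_ss))
            if spur.deposited_energy_ev <= 0:
                continue
            timeline = resolve_history(
                spur, table, end_ns, np.random.default_rng(engine_ss), scheme
            )
            counts += timeline.counts_at(times_ns, tracked)
            energy += timeline.deposited_energy_ev
        if energy <= 0:
            raise ValueError("ensemble deposited no energy; check the spur model")
        per_run_g[run] = 100.0 * counts / energy
        total_energy += energy

    g = per_run_g.mean(axis=0)
    if config.n_runs >= 2:
        stderr = per_run_g.std(axis=0, ddof=1) / math.sqrt(config.n_runs)
    else:
        stderr = np.zeros_like(g)
    return GValueSeries(
        times_us=times_us,
        species=list(tracked),
        g=g,
        stderr=stderr,
        temperature_c=table.temperature_c,
        ph=table.ph,
        n_runs=config.n_runs,
        n_histories_per_run=config.n_histories_per_run,
        seed=config.rng_seed,
        per_run_g=per_run_g,
        total_energy_ev=total_energy,
    )
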