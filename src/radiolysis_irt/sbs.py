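"""Step-by-step Brownian-dynamics oracle for validating the IRT engine.

Explicit reaction-diffusion simulation: every particle performs a Gaussian
random walk (variance 2 D dt per axis per step) and a reactive pair reacts
when its separation falls below the channel's Smoluchowski radius — the same
Eq.-style radii the IRT table uses.  Optionally a Debye drift term
v = D_i * rc_s * r_hat / r^2 (Euler–Maruyama) acts between charged pairs so
the Coulomb-corrected IRT sampling can be validated too.

Between successive steps a Brownian-bridge correction is applied to the
radial separation of each candidate pair: even when both endpoints lie
outside the contact radius, the continuous path may have crossed it, with
probability exp(-(r0 - R)(r1 - R) / (D dt)) for relative diffusivity D.
Without this correction the finite time step systematically underestimates
reaction probabilities.

This is a brute-force reference, deliberately restricted to toy problems
(<= 10 particles); it is never used for production yield runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import ChemicalTable
from .results import EventTimeline, ReactionEvent
from .spur import SpurState

__all__ = ["SBSConfig", "brownian_step", "run_sbs", "pair_reaction_times", "reaction_fractions"]

_MAX_PARTICLES = 10


@dataclass(frozen=True)
class SBSConfig:
    """Step-by-step run parameters (ns, nm)."""

    dt_ns: float
    end_time_ns: float
    rng_seed: int = 0
    with_drift: bool = False
    max_particles: int = _MAX_PARTICLES

    def __post_init__(self) -> None:
        if self.dt_ns <= 0 or self.end_time_ns <= 0:
            raise ValueError("dt and end time must be positive")


def brownian_step(
    positions: np.ndarray,
    d_coeffs: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One free-diffusion step: each coordinate gains N(0, 2 D dt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    positions = np.asarray(positions, dtype=float)
    d_coeffs = np.asarray(d_coeffs, dtype=float)
    sigma = np.sqrt(2.0 * d_coeffs * dt)
    return positions + rng.standard_normal(positions.shape) * sigma[..., None]


def _bridge_crossing_prob(
    r_before: np.ndarray | float,
    r_after: np.ndarray | float,
    radius: float,
    d_mutual: float,
    dt: float,
) -> np.ndarray | float:
    """P(the radial bridge dipped below ``radius``) given both endpoints outside."""
    a = np.maximum(np.asarray(r_before) - radius, 0.0)
    b = np.maximum(np.asarray(r_after) - radius, 0.0)
    return np.exp(-a * b / (d_mutual * dt))


def _check_dt(table: ChemicalTable, dt: float) -> None:
    """Guard: per-step rms displacement must stay below 0.2 x smallest radius."""
    radii = [
        r.radius_nm
        for r in table.pair_reactions
        if r.radius_nm is not None and r.radius_nm > 0
    ]
    if not radii:
        return
    r_min = min(radii)
    d_max = max(table.diffusion[n] for n, sp in table.species.items() if not sp.is_background)
    rms = math.sqrt(6.0 * d_max * dt)
    if rms >= 0.2 * r_min:
        raise ValueError(
            f"time step too coarse: rms step {rms:.3g} nm >= 0.2 x smallest "
            f"reaction radius ({0.2 * r_min:.3g} nm); reduce dt"
        )


def run_sbs(
    spur: SpurState,
    table: ChemicalTable,
    config: SBSConfig,
) -> EventTimeline:
    """Explicit Brownian simulation of one (toy) spur; IRT-compatible timeline."""
    if len(spur) > config.max_particles:
        raise ValueError(
            f"step-by-step oracle accepts at most {config.max_particles} particles "
            f"(got {len(spur)}); it exists only for small validation fixtures"
        )
    _check_dt(table, config.dt_ns)
    rng = np.random.default_rng(config.rng_seed)

    # per-pair channel lookup from the resolved table
    pair_radius: dict[tuple[str, str], list] = {}
    for rr in table.pair_reactions:
        if rr.radius_nm is None or rr.radius_nm <= 0:
            continue
        a, b = rr.reaction.reactants
        key = (a, b) if a <= b else (b, a)
        pair_radius.setdefault(key, []).append(rr)

    species = list(spur.species)
    positions = [np.asarray(p, dtype=float) for p in spur.positions]
    alive = [True] * len(species)
    charges = {n: sp.charge for n, sp in table.species.items()}
    rc = table.water.onsager_radius_nm

    # presampled background-scavenging clocks
    bg_clock: list[tuple[float, int, object]] = []

    def arm_background(idx: int, t_now: float) -> None:
        for rr in table.background_reactions:
            if rr.scavenged_species != species[idx]:
                continue
            cap = (rr.capacity_per_s or 0.0) * 1.0e-9  # per ns
            if cap <= 0:
                continue
            dt_s = -math.log(rng.random()) / cap
            bg_clock.append((t_now + dt_s, idx, rr))

    for idx in range(len(species)):
        arm_background(idx, spur.creation_time_ns)

    events: list[ReactionEvent] = []

    def place_products(rr, pos_parent: np.ndarray, radius: float, t_now: float) -> None:
        products = tuple(
            p for p in rr.reaction.products if not table.species[p].is_background
        )
        for m, prod in enumerate(products):
            if m == 0 and len(products) == 1:
                offset = np.zeros(3)
            else:
                v = rng.standard_normal(3)
                v /= max(float(np.linalg.norm(v)), 1e-12)
                offset = v * 0.5 * max(radius, 0.29)
            species.append(prod)
            positions.append(pos_parent + offset)
            alive.append(True)
            arm_background(len(species) - 1, t_now)
        return products

    t = spur.creation_time_ns
    while t < config.end_time_ns:
        t_next = min(t + config.dt_ns, config.end_time_ns)
        # displacement (+ optional pairwise Debye drift)
        live = [k for k in range(len(species)) if alive[k]]
        if not live:
            break
        drift = {k: np.zeros(3) for k in live} if config.with_drift else None
        if config.with_drift:
            for ai in range(len(live)):
                for bj in range(ai + 1, len(live)):
                    ka, kb = live[ai], live[bj]
                    qq = charges[species[ka]] * charges[species[kb]]
                    if qq == 0:
                        continue
                    rvec = positions[ka] - positions[kb]
                    r = float(np.linalg.norm(rvec))
                    if r < 1e-9:
                        continue
                    unit = rvec / r
                    rc_s = rc * qq
                    drift[ka] += table.diffusion[species[ka]] * rc_s * unit / r**2
                    drift[kb] -= table.diffusion[species[kb]] * rc_s * unit / r**2
        dt = t_next - t
        prev_positions = [p.copy() for p in positions]
        for k in live:
            d = table.diffusion[species[k]]
            step = rng.standard_normal(3) * math.sqrt(2.0 * d * dt)
            if drift is not None:
                step = step + drift[k] * dt
            positions[k] = positions[k] + step

        # background clocks that expired within this step
        for t_evt, idx, rr in sorted(bg_clock):
            if t_evt <= t_next and alive[idx]:
                alive[idx] = False
                produced = place_products(rr, positions[idx], 0.29, t_evt)
                events.append(
                    ReactionEvent(
                        time_ns=t_evt,
                        reaction_id=rr.reaction.id,
                        consumed=(species[idx],),
                        produced=produced,
                    )
                )
        bg_clock = [(te, idx, rr) for te, idx, rr in bg_clock if te > t_next and alive[idx]]

        # contact reactions (with a Brownian-bridge crossing check)
        live = [k for k in range(len(species)) if alive[k]]
        for ai in range(len(live)):
            for bj in range(ai + 1, len(live)):
                ka, kb = live[ai], live[bj]
                if not (alive[ka] and alive[kb]):
                    continue
                a_name, b_name = species[ka], species[kb]
                key = (a_name, b_name) if a_name <= b_name else (b_name, a_name)
                for rr in pair_radius.get(key, ()):
                    r = float(np.linalg.norm(positions[ka] - positions[kb]))
                    r_prev = float(np.linalg.norm(prev_positions[ka] - prev_positions[kb])) \
                        if ka < len(prev_positions) and kb < len(prev_positions) else r
                    hit = r < rr.radius_nm
                    if not hit and r_prev > rr.radius_nm:
                        p = _bridge_crossing_prob(
                            r_prev, r, rr.radius_nm, rr.mutual_diffusion or 1.0, dt
                        )
                        hit = rng.random() < p
                    if hit:
                        alive[ka] = alive[kb] = False
                        w_a = math.sqrt(table.diffusion[a_name])
                        w_b = math.sqrt(table.diffusion[b_name])
                        mid = (w_a * positions[ka] + w_b * positions[kb]) / (w_a + w_b)
                        produced = place_products(rr, mid, rr.radius_nm, t_next)
                        events.append(
                            ReactionEvent(
                                time_ns=t_next,
                                reaction_id=rr.reaction.id,
                                consumed=(a_name, b_name),
                                produced=produced,
                            )
                        )
                        break
        t = t_next

    events.sort(key=lambda e: e.time_ns)
    return EventTimeline(
        events=events,
        initial_counts=spur.counts(),
        deposited_energy_ev=spur.deposited_energy_ev,
        creation_time_ns=spur.creation_time_ns,
    )


# ---------------------------------------------------------------------------
# vectorized helpers for statistical comparisons
# ---------------------------------------------------------------------------

def pair_reaction_times(
    r0_nm: float,
    radius_nm: float,
    d_mutual: float,
    n_replicas: int,
    dt_ns: float,
    end_time_ns: float,
    rng_seed: int,
    rc_signed_nm: float = 0.0,
) -> np.ndarray:
    """First-contact times of an isolated pair over many replicas (inf = never).

    Simulated in the relative coordinate (diffusivity = the mutual D); with a
    nonzero signed Onsager radius an Euler–Maruyama Debye drift
    v = D rc_s r_hat / r^2 acts on the separation vector.
    """
    rng = np.random.default_rng(rng_seed)
    pos = np.zeros((n_replicas, 3))
    pos[:, 0] = r0_nm
    times = np.full(n_replicas, np.inf)
    active = np.ones(n_replicas, dtype=bool)
    sigma = math.sqrt(2.0 * d_mutual * dt_ns)
    n_steps = int(math.ceil(end_time_ns / dt_ns))
    step = 0
    block = 256
    while step < n_steps and active.any():
        nb = min(block, n_steps - step)
        noise = rng.standard_normal((nb, n_replicas, 3)) * sigma
        unif = rng.random((nb, n_replicas))
        for b in range(nb):
            step += 1
            r_old = np.linalg.norm(pos, axis=1)
            if rc_signed_nm != 0.0:
                r_safe = np.maximum(r_old, 0.25 * radius_nm)[:, None]
                pos += (d_mutual * rc_signed_nm * dt_ns) * pos / r_safe**3
            pos += noise[b]
            r_new = np.linalg.norm(pos, axis=1)
            crossed = unif[b] < _bridge_crossing_prob(
                r_old, r_new, radius_nm, d_mutual, dt_ns
            )
            hit = active & ((r_new < radius_nm) | crossed)
            if hit.any():
                times[hit] = step * dt_ns
                active &= ~hit
    return times


def reaction_fractions(
    spur: SpurState,
    table: ChemicalTable,
    dt_ns: float,
    grid_ns: np.ndarray,
    n_replicas: int,
    rng_seed: int,
) -> dict[str, np.ndarray]:
    """Per-channel cumulative reaction fractions on a time grid, replica-vectorized.

    Each replica restarts the same toy spur; on contact the reactants of the
    firing channel are removed.  Products are *not* propagated — fixtures for
    this helper use product-inert schemes so that IRT and Brownian dynamics
    are compared on identical footing.
    """
    if len(spur) > _MAX_PARTICLES:
        raise ValueError("reaction_fractions is restricted to toy spurs (<= 10 particles)")
    _check_dt(table, dt_ns)
    rng = np.random.default_rng(rng_seed)
    grid_ns = np.asarray(grid_ns, dtype=float)
    names = list(spur.species)
    n_part = len(names)
    d = np.array([table.diffusion[n] for n in names])
    charges = np.array([table.species[n].charge for n in names])
    rc = table.water.onsager_radius_nm

    channels = []  # (ia, jb, radius, reaction_id, uses_drift)
    for rr in table.pair_reactions:
        if rr.radius_nm is None or rr.radius_nm <= 0:
            continue
        a, b = rr.reaction.reactants
        for ia in range(n_part):
            for jb in range(ia + 1, n_part):
                if {names[ia], names[jb]} == {a, b} or (
                    a == b and names[ia] == a and names[jb] == a
                ):
                    channels.append((ia, jb, rr.radius_nm, rr.reaction.id))
    if not channels:
        return {}

    pos = np.tile(spur.positions[None, :, :], (n_replicas, 1, 1)).astype(float)
    alive = np.ones((n_replicas, n_part), dtype=bool)
    any_charged = bool(np.any(charges != 0))
    fired_at = {
        (ia, jb, rid): np.full(n_replicas, np.inf) for ia, jb, _, rid in channels
    }

    sigma = np.sqrt(2.0 * d * dt_ns)
    n_steps = int(math.ceil((grid_ns.max() - spur.creation_time_ns) / dt_ns))
    t = spur.creation_time_ns
    for _ in range(n_steps):
        t += dt_ns
        pos_old = pos.copy()
        if any_charged:
            for ia in range(n_part):
                for jb in range(ia + 1, n_part):
                    qq = charges[ia] * charges[jb]
                    if qq == 0:
                        continue
                    both = alive[:, ia] & alive[:, jb]
                    rvec = pos[:, ia, :] - pos[:, jb, :]
                    r = np.linalg.norm(rvec, axis=1, keepdims=True)
                    r = np.maximum(r, 1e-9)
                    v = rc * qq * rvec / r**3
                    pos[:, ia, :] += np.where(both[:, None], d[ia] * v * dt_ns, 0.0)
                    pos[:, jb, :] -= np.where(both[:, None], d[jb] * v * dt_ns, 0.0)
        pos += rng.standard_normal(pos.shape) * sigma[None, :, None]
        for ia, jb, radius, rid in channels:
            both = alive[:, ia] & alive[:, jb]
            if not both.any():
                continue
            r = np.linalg.norm(pos[:, ia, :] - pos[:, jb, :], axis=1)
            r_old = np.linalg.norm(pos_old[:, ia, :] - pos_old[:, jb, :], axis=1)
            hit = both & (r < radius)
            bridged = both & ~hit & (r_old > radius)
            if bridged.any():
                p_cross = _bridge_crossing_prob(
                    r_old[bridged], r[bridged], radius, float(d[ia] + d[jb]), dt_ns
                )
                crossed = rng.random(int(bridged.sum())) < p_cross
                hit = hit.copy()
                hit[np.flatnonzero(bridged)[crossed]] = True
            if hit.any():
                rec = fired_at[(ia, jb, rid)]
                rec[hit & ~np.isfinite(rec)] = t
                alive[hit, ia] = False
                alive[hit, jb] = False

    out: dict[str, np.ndarray] = {}
    for (ia, jb, rid), t_fire in fired_at.items():
        curve = (t_fire[:, None] <= grid_ns[None, :]).mean(axis=0)
        key = f"{rid}[{ia},{jb}]"
        out[key] = curve
    return out
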