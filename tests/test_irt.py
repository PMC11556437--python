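"""Unit and statistical tests for the independent-reaction-times engine."""

import math

import numpy as np
import pytest
from scipy.special import erfc

from radiolysis_irt import (
    RunConfig,
    SpurState,
    build_chemical_table,
    effective_radius,
    resolve_history,
    run_ensemble,
    sample_pair_time,
    sample_scavenging_time,
)
from radiolysis_irt.irt import PairChannel, _debye_transform
from radiolysis_irt.parameters import _COMPOSITION


def make_channel(r0, radius, d, rc_signed=None):
    s = r0 if rc_signed is None else _debye_transform(r0, rc_signed)
    a = radius if rc_signed is None else radius
    return PairChannel(0, 1, "toy", r0, a, s, d)


class TestEffectiveRadius:
    def test_neutral_pair_unchanged(self):
        assert effective_radius(0.5, 0.715, 0) == 0.5

    def test_zero_onsager_radius_unchanged(self):
        assert effective_radius(0.5, 0.0, -1) == 0.5

    def test_continuity_in_small_rc(self):
        assert effective_radius(0.5, 1e-9, 1) == pytest.approx(0.5, rel=1e-6)

    def test_sign_behaviour(self):
        attract = effective_radius(0.5, 0.715, -1)
        repel = effective_radius(0.5, 0.715, +1)
        assert attract > 0.5          # opposite charges react more readily
        assert repel < 0.5
        # cross-check numerically against the closed form
        assert attract == pytest.approx(-0.715 / math.expm1(-0.715 / 0.5))
        assert repel == pytest.approx(0.715 / math.expm1(0.715 / 0.5))


class TestSamplePairTime:
    def test_contact_reacts_immediately(self):
        ch = make_channel(r0=0.4, radius=0.5, d=1.0)
        assert sample_pair_time(ch, 0.5) == 0.0

    def test_distant_pair_never_reacts(self):
        ch = make_channel(r0=1e12, radius=0.5, d=1.0)
        assert sample_pair_time(ch, 0.999) == math.inf

    def test_reaction_probability_is_winf(self, rng):
        r0, radius, d = 2.0, 0.5, 1.5
        ch = make_channel(r0, radius, d)
        n = 100_000
        finite = sum(
            math.isfinite(sample_pair_time(ch, u)) for u in rng.random(n)
        )
        w = radius / r0
        se = math.sqrt(w * (1 - w) / n)
        assert abs(finite / n - w) < 3 * se

    def test_empirical_cdf_matches_first_passage_law(self, rng):
        """Conditional CDF of sampled times vs W(t)/W_inf = erfc(b/sqrt(4Dt))."""
        r0, radius, d = 2.0, 0.5, 1.5
        ch = make_channel(r0, radius, d)
        n = 100_000
        times = np.array([sample_pair_time(ch, u) for u in rng.random(n)])
        finite = times[np.isfinite(times)]
        b = r0 - radius
        for t in (0.2, 1.0, 5.0, 25.0, 125.0):
            empirical = (finite <= t).mean()
            expected = erfc(b / math.sqrt(4 * d * t))
            se = math.sqrt(expected * (1 - expected) / finite.size) + 1e-9
            assert abs(empirical - expected) < 3.5 * se, t


class TestSampleScavengingTime:
    def test_zero_capacity_never_fires(self):
        assert sample_scavenging_time(0.0, 0.5) == math.inf

    def test_mean_is_inverse_capacity(self, rng):
        n = 100_000
        t = np.array([sample_scavenging_time(1e3, u) for u in rng.random(n)])
        # capacity 1e3 /s -> mean 1e6 ns; exponential SE = mean / sqrt(n)
        assert abs(t.mean() - 1e6) < 3 * 1e6 / math.sqrt(n)

    def test_doubling_capacity_halves_mean(self, rng):
        u = rng.random(50_000)
        t1 = np.array([sample_scavenging_time(2e3, x) for x in u])
        t2 = np.array([sample_scavenging_time(4e3, x) for x in u])
        assert t1.mean() == pytest.approx(2 * t2.mean(), rel=1e-12)

    def test_negative_capacity_rejected(self):
        with pytest.raises(ValueError):
            sample_scavenging_time(-1.0, 0.5)


class TestResolveHistory:
    def test_single_particle_produces_no_events(self, table_25_7):
        spur = SpurState(["OH"], np.zeros((1, 3)), 62.5)
        timeline = resolve_history(spur, table_25_7, 1e3, 1)
        assert timeline.events == []

    def test_zero_rate_table_is_inert(self, zero_rate_overrides, spur_model, rng):
        table = build_chemical_table(25.0, 7.0, overrides=zero_rate_overrides)
        from radiolysis_irt import generate_spur

        spur = generate_spur(spur_model, 5)
        timeline = resolve_history(spur, table, 1e3, 2)
        assert timeline.events == []

    def test_deterministic_for_fixed_seed(self, table_25_7, spur_model):
        from radiolysis_irt import generate_spur

        spur = generate_spur(spur_model, 77)
        t1 = resolve_history(spur, table_25_7, 1e3, 99)
        t2 = resolve_history(spur, table_25_7, 1e3, 99)
        assert t1.events == t2.events

    def test_two_electron_outcome_frequency(self, table_25_7):
        """e_aq + e_aq reaction frequency equals the analytic W_inf = R/r0."""
        rr = table_25_7.reaction("R1")
        r0 = 0.6
        spur = SpurState(
            ["e_aq", "e_aq"],
            np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
            62.5,
        )
        n = 20_000
        reacted = 0
        for seed in range(n):
            tl = resolve_history(spur, table_25_7, 1e6, seed)
            reacted += any(e.reaction_id == "R1" for e in tl.events)
        w = rr.radius_nm / r0  # partially-controlled channel: no Debye factor
        se = math.sqrt(w * (1 - w) / n)
        assert abs(reacted / n - w) < 3 * se

    def test_events_conserve_atoms_and_charge(self, table_25_7, spur_model):
        """Every realized event conserves charge and H/O up to water molecules."""
        from radiolysis_irt import generate_spur

        reactions = {r.id: r.reaction for r in table_25_7.reactions}
        n_events = 0
        for seed in range(120):
            spur = generate_spur(spur_model, seed)
            tl = resolve_history(spur, table_25_7, 1e3, seed + 1)
            for ev in tl.events:
                consumed = list(ev.consumed)
                rxn = reactions[ev.reaction_id]
                if rxn.kinetics_class == "background_scavenging":
                    consumed.append(rxn.background)  # implicit bulk reactant
                dh = do = dq = 0
                for name in consumed:
                    h, o, q = _COMPOSITION[name]
                    dh, do, dq = dh + h, do + o, dq + q
                for name in ev.produced:
                    h, o, q = _COMPOSITION[name]
                    dh, do, dq = dh - h, do - o, dq - q
                assert dq == 0
                assert dh == 2 * do  # residual is whole water molecules
                n_events += 1
        assert n_events > 100  # the scheme actually fires

    def test_event_times_increase_and_no_double_consumption(
        self, table_25_7, spur_model
    ):
        from radiolysis_irt import generate_spur

        spur = generate_spur(spur_model, 3)
        tl = resolve_history(spur, table_25_7, 1e3, 4)
        times = [e.time_ns for e in tl.events]
        assert times == sorted(times)
        # species bookkeeping never goes negative on a fine grid
        grid = np.geomspace(1e-3, 1e3, 200)
        counts = tl.counts_at(grid, ["e_aq", "OH", "H", "H2", "H2O2", "H3O+", "OH-"])
        assert (counts >= 0).all()


class TestRunEnsemble:
    def test_zero_rate_ensemble_flat_at_initial_yields(
        self, zero_rate_overrides, spur_model
    ):
        table = build_chemical_table(25.0, 7.0, overrides=zero_rate_overrides)
        cfg = RunConfig(n_runs=2, n_histories_per_run=400, rng_seed=5)
        series = run_ensemble(spur_model, table, cfg)
        yields = spur_model.initial_yields()
        n_spurs = cfg.n_runs * cfg.n_histories_per_run
        for sp, y in yields.items():
            g = series.g_of(sp)
            assert np.allclose(g, g[0])  # flat in time
            # analytic Poisson standard error of the pooled G estimate
            lam = y * spur_model.energy_per_spur_ev / 100.0
            se = (100.0 / spur_model.energy_per_spur_ev) * math.sqrt(lam / n_spurs)
            assert abs(g[0] - y) < 4 * se, sp

    def test_energy_bookkeeping(self, spur_model, table_25_7):
        cfg = RunConfig(n_runs=2, n_histories_per_run=50, rng_seed=8)
        series = run_ensemble(spur_model, table_25_7, cfg)
        expected = cfg.n_runs * cfg.n_histories_per_run * spur_model.energy_per_spur_ev
        assert series.total_energy_ev == pytest.approx(expected)

    def test_seed_changes_output(self, spur_model, table_25_7):
        cfg1 = RunConfig(n_runs=2, n_histories_per_run=50, rng_seed=8)
        cfg2 = RunConfig(n_runs=2, n_histories_per_run=50, rng_seed=9)
        s1 = run_ensemble(spur_model, table_25_7, cfg1)
        s2 = run_ensemble(spur_model, table_25_7, cfg2)
        assert not np.array_equal(s1.g, s2.g)

    def test_reproducible_for_fixed_config(self, spur_model, table_25_7):
        cfg = RunConfig(n_runs=2, n_histories_per_run=50, rng_seed=8)
        s1 = run_ensemble(spur_model, table_25_7, cfg)
        s2 = run_ensemble(spur_model, table_25_7, cfg)
        np.testing.assert_array_equal(s1.g, s2.g)
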