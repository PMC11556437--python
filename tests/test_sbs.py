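"""Tests for the step-by-step Brownian oracle and IRT/Brownian equivalence."""

import math

import numpy as np
import pytest
from scipy.special import erfc

from radiolysis_irt import (
    SBSConfig,
    SpurState,
    brownian_step,
    build_chemical_table,
    effective_radius,
    run_sbs,
)
from radiolysis_irt.irt import PairChannel, _debye_transform, sample_pair_time
from radiolysis_irt.sbs import pair_reaction_times, reaction_fractions

_TOY_HEADER = (
    "id,reactants,products,type_tag,kinetics_class,background,k_form,k25,k_p1\n"
)


@pytest.fixture(scope="module")
def toy_table(tmp_path_factory):
    """Default table with only two (enlarged) radical channels left active.

    Boosting k(OH+OH) and k(OH+H) gives ~2 nm reaction radii, which lets the
    Brownian oracle run at an affordable time step while keeping reaction
    probabilities O(1); every other channel is switched off.
    """
    rows = [
        "R1,e_aq|e_aq,H2|OH-|OH-,2,partially_diffusion_controlled,,none,0,0",
        "R2,e_aq|OH,OH-,2,partially_diffusion_controlled,,none,0,0",
        "R3,e_aq|H,H2|OH-,1,partially_diffusion_controlled,,none,0,0",
        "R4,e_aq|H3O+,H,3,fully_diffusion_controlled,,none,0,0",
        "R5,e_aq|H2O2,OH|OH-,1,partially_diffusion_controlled,,none,0,0",
        "R6,OH|OH,H2O2,2,partially_diffusion_controlled,,none,8.8e10,0",
        "R7,OH|H,,2,partially_diffusion_controlled,,none,1.44e11,0",
        "R8,H|H,H2,2,partially_diffusion_controlled,,none,0,0",
        "R9,H3O+|OH-,,3,fully_diffusion_controlled,,none,0,0",
    ]
    path = tmp_path_factory.mktemp("toy") / "toy_reactions.csv"
    path.write_text(_TOY_HEADER + "\n".join(rows) + "\n")
    return build_chemical_table(25.0, 7.0, overrides=path)


class TestBrownianStep:
    def test_zero_diffusion_freezes_positions(self, rng):
        pos = rng.standard_normal((5, 3))
        out = brownian_step(pos, np.zeros(5), 0.1, rng)
        np.testing.assert_array_equal(out, pos)

    def test_msd_matches_einstein_relation(self):
        """Mean squared displacement of a free walker equals 6 D t within 3 sigma."""
        rng = np.random.default_rng(42)
        d, dt, n_steps, n_walkers = 1.7, 0.05, 200, 4000
        pos = np.zeros((n_walkers, 3))
        for _ in range(n_steps):
            pos = brownian_step(pos, np.full(n_walkers, d), dt, rng)
        t = n_steps * dt
        msd = (pos**2).sum(axis=1)
        expected = 6 * d * t
        se = msd.std(ddof=1) / math.sqrt(n_walkers)
        assert abs(msd.mean() - expected) < 3 * se

    def test_independent_seeds_are_uncorrelated(self):
        r1 = np.random.default_rng(1)
        r2 = np.random.default_rng(2)
        a = brownian_step(np.zeros((2000, 3)), np.ones(2000), 1.0, r1)
        b = brownian_step(np.zeros((2000, 3)), np.ones(2000), 1.0, r2)
        corr = np.corrcoef(a[:, 0], b[:, 0])[0, 1]
        assert abs(corr) < 0.07

    def test_rejects_bad_dt(self, rng):
        with pytest.raises(ValueError):
            brownian_step(np.zeros((1, 3)), np.ones(1), 0.0, rng)


class TestRunSbs:
    def test_rejects_large_spurs(self, table_25_7):
        spur = SpurState(["OH"] * 11, np.zeros((11, 3)), 62.5)
        with pytest.raises(ValueError, match="at most"):
            run_sbs(spur, table_25_7, SBSConfig(dt_ns=1e-4, end_time_ns=1.0))

    def test_rejects_coarse_time_step(self, table_25_7):
        spur = SpurState(["OH", "OH"], np.array([[0.0] * 3, [1.0, 0, 0]]), 62.5)
        with pytest.raises(ValueError, match="rms step"):
            run_sbs(spur, table_25_7, SBSConfig(dt_ns=1.0, end_time_ns=10.0))

    def test_inert_table_produces_no_events(self, zero_rate_overrides):
        table = build_chemical_table(25.0, 7.0, overrides=zero_rate_overrides)
        spur = SpurState(["OH", "OH"], np.array([[0.0] * 3, [1.0, 0, 0]]), 62.5)
        tl = run_sbs(spur, table, SBSConfig(dt_ns=1e-3, end_time_ns=5.0))
        assert tl.events == []

    def test_timeline_format_matches_irt(self, toy_table):
        spur = SpurState(
            ["OH", "OH"], np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]]), 62.5
        )
        tl = run_sbs(spur, toy_table, SBSConfig(dt_ns=2e-3, end_time_ns=20.0, rng_seed=3))
        assert tl.initial_counts == {"OH": 2}
        for ev in tl.events:
            assert ev.reaction_id == "R6"
            assert ev.consumed == ("OH", "OH")
            assert ev.produced == ("H2O2",)


class TestPairLaw:
    def test_long_time_reaction_probability_is_r_over_r0(self):
        """Smoluchowski escape law: P(react) -> R/r0 for an isolated pair."""
        r0, radius, d = 1.5, 0.5, 2.0
        n = 4000
        times = pair_reaction_times(
            r0, radius, d, n_replicas=n, dt_ns=5e-3, end_time_ns=300.0, rng_seed=9
        )
        p = np.isfinite(times).mean()
        w = radius / r0
        se = math.sqrt(w * (1 - w) / n)
        # small residual truncation bias: W(400)/W_inf ~ 0.983
        assert abs(p - w) < 3 * se + 0.017 * w

    def test_halving_dt_converges(self):
        r0, radius, d = 1.5, 0.5, 2.0
        w = radius / r0
        errs = []
        for dt in (2e-2, 5e-3):
            times = pair_reaction_times(r0, radius, d, 2000, dt, 150.0, 10)
            errs.append(abs(np.isfinite(times).mean() - w))
        # finer step is closer to (or statistically indistinguishable from) truth
        se = math.sqrt(w * (1 - w) / 2000)
        assert errs[1] < errs[0] + 3 * se


class TestOracleEquivalence:
    """IRT sampling vs explicit Brownian dynamics on toy configurations."""

    def test_neutral_pair_time_distribution(self):
        r0, radius, d = 1.5, 0.5, 2.0
        n = 4000
        sbs_times = pair_reaction_times(r0, radius, d, n, 5e-3, 300.0, 21)
        rng = np.random.default_rng(22)
        ch = PairChannel(0, 1, "toy", r0, radius, r0, d)
        irt_times = np.array([sample_pair_time(ch, u) for u in rng.random(n)])
        for t in (2.0, 10.0, 50.0, 250.0):
            p_sbs = (sbs_times <= t).mean()
            p_irt = (irt_times <= t).mean()
            p_exact = (radius / r0) * erfc((r0 - radius) / math.sqrt(4 * d * t))
            se = math.sqrt(p_exact * (1 - p_exact) / n)
            assert abs(p_sbs - p_exact) < 3 * se + 0.1 * p_exact, t
            assert abs(p_irt - p_exact) < 3 * se, t

    def test_charged_pair_ultimate_probability(self):
        """Debye drift simulation vs the Coulomb-corrected IRT probability.

        The Brownian walker absorbs at the *contact* radius; the IRT channel
        therefore uses the Debye-effective radius of that contact radius, and
        the Debye-transformed separation.
        """
        rc = 0.715
        contact, r0, d = 0.5, 1.5, 2.0
        n = 4000
        for qq in (-1, +1):
            rc_s = rc * qq
            sbs_times = pair_reaction_times(
                r0, contact, d, n, 5e-3, 250.0, 30 + qq, rc_signed_nm=rc_s
            )
            p_sbs = np.isfinite(sbs_times).mean()
            a_eff = effective_radius(contact, rc, qq)
            r0_eff = _debye_transform(r0, rc_s)
            w = a_eff / r0_eff
            se = math.sqrt(w * (1 - w) / n)
            # allow truncation bias comparable to the neutral case
            assert abs(p_sbs - w) < 3 * se + 0.05 * w, qq

    def test_three_particle_channel_fractions(self, toy_table):
        """Competing channels on a 3-particle toy: IRT vs Brownian dynamics.

        Two OH radicals and one H atom: the OH+OH and two OH+H channels
        compete; products are inert here, so the engines are compared on
        identical footing.
        """
        from radiolysis_irt import resolve_history

        spur = SpurState(
            ["OH", "OH", "H"],
            np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 3.5, 0.0]]),
            62.5,
        )
        grid = np.array([5.0, 40.0])
        n_sbs = 3000
        fractions = reaction_fractions(
            spur, toy_table, dt_ns=2e-3, grid_ns=grid, n_replicas=n_sbs, rng_seed=5
        )
        n_irt = 6000
        irt_r6 = np.zeros(grid.size)
        irt_r7 = np.zeros(grid.size)
        for seed in range(n_irt):
            tl = resolve_history(spur, toy_table, float(grid.max()), seed)
            for ev in tl.events:
                if ev.reaction_id == "R6":
                    irt_r6 += ev.time_ns <= grid
                elif ev.reaction_id == "R7":
                    irt_r7 += ev.time_ns <= grid
        p_irt_r6 = irt_r6 / n_irt
        p_sbs_r6 = fractions["R6[0,1]"]
        p_irt_r7 = irt_r7 / n_irt
        p_sbs_r7 = fractions["R7[0,2]"] + fractions["R7[1,2]"]
        for i in range(grid.size):
            se6 = math.sqrt(max(p_sbs_r6[i] * (1 - p_sbs_r6[i]), 1e-4) / n_sbs)
            assert abs(p_irt_r6[i] - p_sbs_r6[i]) < 3.5 * se6 + 0.02, ("R6", grid[i])
            se7 = math.sqrt(max(p_sbs_r7[i] * (1 - p_sbs_r7[i]), 1e-4) / n_sbs)
            assert abs(p_irt_r7[i] - p_sbs_r7[i]) < 3.5 * se7 + 0.02, ("R7", grid[i])
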