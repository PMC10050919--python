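"""Condition-specific acquisition, movement, reproduction and death rules."""

import numpy as np
import pytest

from tooltrans import (
    AgentState,
    Attractor,
    SimConfig,
    asocial_acquire,
    attractor_move,
    death_probability,
    follow_probability,
    mother_follow_move,
    offspring_phenotype,
    offspring_tool_status,
    reproduce,
    social_acquisition_probability,
)
from tooltrans.simcore import COMMON_LIKE, HYBRID_LIKE, Simulation
from tooltrans.transmission import place_attractors


def make_agent(aid=0, age=30, phenotype=HYBRID_LIKE, tool=False, row=10, col=10, **kw):
    return AgentState(aid, age, phenotype, tool, row, col, **kw)


class TestSocialRule:
    @pytest.mark.parametrize(
        "encounters,expected", [(0, 0.0), (1, 0.01), (50, 0.5), (150, 1.0)]
    )
    def test_probability_linear_and_capped(self, encounters, expected):
        assert social_acquisition_probability(encounters) == pytest.approx(expected)

    def test_negative_encounters_rejected(self):
        with pytest.raises(ValueError):
            social_acquisition_probability(-1)

    def test_acquirers_have_encounter_history(self):
        sim = Simulation(SimConfig(condition="social", rng_seed=21))
        while sim.steps < sim.config.max_steps and sim.tool_fraction() < 0.5:
            sim.step()
        for a in sim.agents.values():
            if a.tool_user and a.id != 0:
                assert a.encounters_with_tool_users >= 1


class TestAsocialRule:
    def test_acquisition_rate_matches_per_step_chance(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig(condition="asocial")
        n = 10_000
        hits = 0
        for _ in range(n):
            a = make_agent(age=40)
            hits += asocial_acquire(a, cfg, rng)
        se = (0.05 * 0.95 / n) ** 0.5
        assert abs(hits / n - 0.05) < 3 * se

    def test_age_gate_blocks_juveniles(self):
        rng = np.random.default_rng(1)
        cfg = SimConfig(condition="asocial")
        for _ in range(2000):
            a = make_agent(age=25)
            assert not asocial_acquire(a, cfg, rng)

    def test_existing_tool_user_unchanged(self, rng):
        a = make_agent(age=40, tool=True)
        assert asocial_acquire(a, SimConfig(condition="asocial"), rng)
        assert a.tool_user


class TestAttractorMovement:
    def test_directed_move_frequency(self):
        # from (10,10) toward an attractor at (0,0) the minimizing neighbour
        # is (9,9); a random move also lands there 1/8 of the time:
        # P = pull + (1 - pull)/8 = 0.25 + 0.75/8
        rng = np.random.default_rng(2)
        cfg = SimConfig(condition="asocial")
        att = [Attractor(0, 0)]
        n = 10_000
        hits = sum(
            attractor_move(make_agent(tool=True), att, cfg, rng) == (9, 9)
            for _ in range(n)
        )
        p = 0.25 + 0.75 / 8
        se = (p * (1 - p) / n) ** 0.5
        assert abs(hits / n - p) < 3 * se

    def test_non_tool_user_moves_randomly(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig(condition="asocial")
        att = [Attractor(0, 0)]
        cells = {attractor_move(make_agent(tool=False), att, cfg, rng) for _ in range(500)}
        assert len(cells) == 8  # full Moore neighbourhood reached

    def test_agent_on_attractor_stays_when_pulled(self):
        rng = np.random.default_rng(4)
        cfg = SimConfig(condition="asocial", attractor_pull=1.0)
        att = [Attractor(10, 10)]
        for _ in range(50):
            assert attractor_move(make_agent(tool=True), att, cfg, rng) == (10, 10)

    def test_attractors_placed_within_grid(self, rng):
        cfg = SimConfig(condition="asocial", n_attractors=200)
        for att in place_attractors(cfg, rng):
            assert 0 <= att.row < 20 and 0 <= att.col < 20

    def test_tool_users_cluster_around_single_attractor(self):
        # spatial signature of resource attraction: at termination, tool
        # users sit closer together than random same-size agent subsets
        rng = np.random.default_rng(5)
        tool_d, null_d = [], []
        for seed in range(20):
            sim = Simulation(
                SimConfig(condition="asocial", n_attractors=1, rng_seed=seed)
            )
            while sim.steps < sim.config.max_steps and sim.tool_fraction() < 0.5:
                sim.step()
            pos = np.array(
                [(a.row, a.col) for a in sim.agents.values() if a.alive]
            )
            tool = np.array(
                [a.tool_user for a in sim.agents.values() if a.alive]
            )

            def mean_pairwise(p):
                d = p[:, None, :] - p[None, :, :]
                dist = np.sqrt((d**2).sum(-1))
                n = len(p)
                return dist[np.triu_indices(n, 1)].mean()

            tool_d.append(mean_pairwise(pos[tool]))
            k = tool.sum()
            null_d.append(
                np.mean(
                    [
                        mean_pairwise(pos[rng.choice(len(pos), k, replace=False)])
                        for _ in range(20)
                    ]
                )
            )
        assert np.mean(tool_d) < np.mean(null_d)


class TestDeath:
    @pytest.mark.parametrize(
        "age,expected", [(0, 0.0001), (100, 0.0011), (10**9, 1.0)]
    )
    def test_death_probability_formula(self, age, expected):
        assert death_probability(age, SimConfig(condition="inheritance")) == pytest.approx(expected)


class TestReproduction:
    def test_offspring_phenotype_rules(self):
        rng = np.random.default_rng(6)
        assert offspring_phenotype(HYBRID_LIKE, HYBRID_LIKE, rng) == HYBRID_LIKE
        assert offspring_phenotype(COMMON_LIKE, COMMON_LIKE, rng) == COMMON_LIKE
        n = 10_000
        hybrids = sum(
            offspring_phenotype(HYBRID_LIKE, COMMON_LIKE, rng) == HYBRID_LIKE
            for _ in range(n)
        )
        se = (0.25 / n) ** 0.5
        assert abs(hybrids / n - 0.5) < 3 * se

    def test_trait_needs_hybrid_phenotype(self):
        carrier = make_agent(tool=True, tool_heir=True)
        naive = make_agent(aid=1, phenotype=COMMON_LIKE)
        assert offspring_tool_status(carrier, naive, HYBRID_LIKE)
        assert not offspring_tool_status(carrier, naive, COMMON_LIKE)

    def test_strict_descent_switch(self):
        a = make_agent()
        b = make_agent(aid=1)
        # default rule: trait rides the hybrid phenotype itself
        assert offspring_tool_status(a, b, HYBRID_LIKE, require_tool_parent=False)
        # strict rule: a carrier parent is additionally required
        assert not offspring_tool_status(a, b, HYBRID_LIKE, require_tool_parent=True)
        c = make_agent(aid=2, tool_heir=True)
        assert offspring_tool_status(a, c, HYBRID_LIKE, require_tool_parent=True)

    def test_offspring_state(self):
        rng = np.random.default_rng(7)
        cfg = SimConfig(condition="inheritance", reproduction_p=1.0)
        pa = make_agent(aid=1, age=40, row=4, col=5)
        pb = make_agent(aid=2, age=50, row=4, col=5)
        child = reproduce(pa, pb, cfg, rng, offspring_id=99, living_population=10)
        assert child is not None
        assert child.age == 0
        assert (child.row, child.col) == (4, 5)
        assert child.mother_id in (1, 2)
        assert not child.tool_user  # trait, if carried, is latent until maturity

    def test_population_cap_blocks_birth(self, rng):
        cfg = SimConfig(condition="inheritance", reproduction_p=1.0)
        pa, pb = make_agent(aid=1, age=40), make_agent(aid=2, age=40)
        assert (
            reproduce(pa, pb, cfg, rng, offspring_id=9,
                      living_population=cfg.population_cap)
            is None
        )

    def test_juvenile_parents_cannot_breed(self, rng):
        cfg = SimConfig(condition="inheritance", reproduction_p=1.0)
        adult, young = make_agent(aid=1, age=40), make_agent(aid=2, age=20)
        for _ in range(50):
            assert reproduce(adult, young, cfg, rng, offspring_id=9,
                             living_population=10) is None


class TestMotherFollowing:
    @pytest.mark.parametrize("age,expected", [(0, 1.0), (25, 0.5), (50, 0.0), (80, 0.0)])
    def test_follow_probability_decays(self, age, expected):
        assert follow_probability(age) == pytest.approx(expected)

    def test_follow_probability_monotone(self):
        probs = [follow_probability(a) for a in range(0, 120)]
        assert all(p2 <= p1 for p1, p2 in zip(probs, probs[1:]))

    def test_newborn_steps_onto_mother(self, rng):
        cfg = SimConfig(condition="inheritance")
        mother = make_agent(aid=1, row=6, col=6)
        child = make_agent(aid=2, age=0, row=5, col=5, mother_id=1)
        for _ in range(50):
            assert mother_follow_move(child, mother, cfg, rng) == (6, 6)

    def test_dead_or_missing_mother_falls_back_to_random(self, rng):
        cfg = SimConfig(condition="inheritance")
        child = make_agent(aid=2, age=0, row=5, col=5, mother_id=1)
        dead = make_agent(aid=1, row=6, col=6, alive=False)
        cells = {mother_follow_move(child, dead, cfg, rng) for _ in range(300)}
        assert len(cells) == 8
        cells = {mother_follow_move(child, None, cfg, rng) for _ in range(300)}
        assert len(cells) == 8


class TestInheritanceRunInvariants:
    def test_all_tool_users_are_hybrid_and_adult(self, inheritance_run):
        log, meta = inheritance_run
        assert meta.terminated_by == "stop_fraction"
        tools = log.agents[log.agents.tool_user]
        assert (tools.phenotype == HYBRID_LIKE).all()
        assert (tools[tools.id != 0].age > 25).all()

    def test_carriers_never_express_before_maturity(self, inheritance_run):
        log, _ = inheritance_run
        young = log.agents[(log.agents.age <= 25) & (log.agents.id != 0)]
        assert not young.tool_user.any()
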