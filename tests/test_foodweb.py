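"""Niche-model generation, trophic levels, and guild classification."""

import numpy as np
import pytest

import multiplexatn as ma
from multiplexatn.foodweb import WebConstraints


class TestGeneration:
    def test_paper_scale_constraints(self, webs):
        """Accepted 50-species webs satisfy every structural constraint."""
        for web in webs:
            assert web.n_species == 50
            assert 0.0976 < web.connectance < 0.1024
            assert web.connectance == web.n_links / 50**2
            assert web.plants.size == 20
            assert web.strict_herbivores().size == 5
            # no isolated species: every plant has a consumer
            assert web.adjacency[:, web.is_plant].any(axis=0).all()
            # niche-trait invariants
            assert ((web.c >= web.rng / 2 - 1e-12)
                    & (web.c <= np.minimum(web.n, 1 - web.rng / 2) + 1e-12)).all()
            assert (web.rng <= web.n + 1e-12).all()

    def test_constraint_counts_hold_over_many_webs(self):
        """Exact plant/herbivore counts hold across 100 accepted webs.

        Uses a cheaper constraint set (smaller web, wider connectance
        window) so that 100 webs are affordable; the acceptance machinery
        is identical to the paper-scale configuration.
        """
        cons = WebConstraints(
            n_plants=5, n_strict_herbivores=2, c_window=(0.10, 0.20)
        )
        rng = np.random.default_rng(0)
        for _ in range(100):
            web = ma.generate_niche_web(
                s_f=20, c_f_target=0.15, constraints=cons,
                rng_seed=rng,
            )
            assert web.plants.size == 5
            assert web.strict_herbivores().size == 2
            assert 0.10 < web.connectance < 0.20

    def test_deterministic_given_seed(self):
        cons = WebConstraints(n_plants=5, n_strict_herbivores=2,
                              c_window=(0.10, 0.20))
        w1 = ma.generate_niche_web(20, 0.15, cons, rng_seed=42)
        w2 = ma.generate_niche_web(20, 0.15, cons, rng_seed=42)
        assert np.array_equal(w1.adjacency, w2.adjacency)
        assert np.array_equal(w1.n, w2.n)

    def test_feeding_interval_membership(self):
        """A resource inside the feeding interval is always linked."""
        for seed in range(5):
            cons = WebConstraints(n_plants=5, n_strict_herbivores=2,
                                  c_window=(0.10, 0.20))
            web = ma.generate_niche_web(20, 0.15, cons, rng_seed=seed)
            inside = (
                np.abs(web.n[None, :] - web.c[:, None]) <= web.rng[:, None] / 2
            )
            assert np.array_equal(inside, web.adjacency)

    def test_beta_draw_matches_target_connectance(self):
        """x ~ Beta(1, b) with b = 1/(2C) - 1 has mean 2C (b = 4 at C = 0.1)."""
        b = 1 / (2 * 0.1) - 1
        assert b == 4.0
        x = np.random.default_rng(0).beta(1.0, b, 200_000)
        assert x.mean() == pytest.approx(0.2, rel=0.01)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ma.generate_niche_web(s_f=1)
        with pytest.raises(ValueError):
            ma.generate_niche_web(c_f_target=0.6)
        with pytest.raises(ma.GenerationError):
            # unattainable: more plants than species
            ma.generate_niche_web(
                10, 0.15,
                WebConstraints(n_plants=11, n_strict_herbivores=0,
                               c_window=(0.0, 1.0)),
                rng_seed=0, max_attempts=2000,
            )


class TestTrophicLevels:
    def test_hand_computed_cases(self):
        # species 0,1 plants; 2 eats plants only; 3 eats a plant and the
        # strict herbivore -> shortest 2, prey-averaged 2.5, swTL 2.25
        adj = np.zeros((4, 4), dtype=bool)
        adj[2, 0] = adj[2, 1] = True
        adj[3, 0] = adj[3, 2] = True
        swtl = ma.trophic_levels(adj)
        assert swtl[0] == swtl[1] == 1.0
        assert swtl[2] == 2.0
        assert swtl[3] == pytest.approx(2.25)

    def test_defining_equations_satisfied(self, web):
        """swTL components satisfy their linear systems to 1e-10."""
        adj = web.adjacency
        swtl = ma.trophic_levels(adj)
        diet = adj.sum(axis=1)
        d = np.where(diet[:, None] > 0, adj / np.maximum(diet, 1)[:, None], 0)
        prey_avg = np.linalg.solve(np.eye(50) - d, np.ones(50))
        shortest = 2 * swtl - prey_avg
        residual = prey_avg - (1 + d @ prey_avg)
        assert np.abs(residual).max() < 1e-10
        # shortest levels: plants at 1, consumers 1 + min over diet
        for i in range(50):
            if diet[i]:
                assert shortest[i] == pytest.approx(
                    1 + shortest[adj[i]].min()
                )
            else:
                assert shortest[i] == pytest.approx(1.0)

    def test_unreachable_consumer_raises(self):
        # two consumers eating only each other, one isolated plant
        adj = np.zeros((3, 3), dtype=bool)
        adj[1, 2] = adj[2, 1] = True
        with pytest.raises(ValueError, match="no diet path"):
            ma.trophic_levels(adj)


class TestGuilds:
    def test_labels_follow_diet_composition(self, web):
        guild = ma.classify_guilds(web)
        is_plant = web.is_plant
        for i in range(web.n_species):
            eats_plant = web.adjacency[i, is_plant].any()
            eats_animal = web.adjacency[i, ~is_plant].any()
            if is_plant[i]:
                assert guild[i] == "plant"
            elif eats_plant and eats_animal:
                assert guild[i] == "omnivore"
            elif eats_plant:
                assert guild[i] == "herbivore"
            else:
                assert guild[i] == "carnivore"

    def test_strict_herbivores_sit_at_level_two(self, web):
        swtl = ma.trophic_levels(web.adjacency)
        assert np.allclose(swtl[web.strict_herbivores()], 2.0)
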