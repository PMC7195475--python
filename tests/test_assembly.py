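"""Integration of pollination networks into food webs; treatment derivation."""

import numpy as np
import pytest

import multiplexatn as ma


class TestIntegrate:
    def test_plant_assignment_and_link_bijection(self, ro_pair):
        base, pnet = ro_pair["base"], ro_pair["pnet"]
        assert base.has_rewards_pool.sum() == pnet.n_plants
        assert (~base.has_rewards_pool[:50][base.is_plant[:50]]).sum() == 20 - pnet.n_plants
        # every bipartite link became exactly one rewards link
        assert base.rew.sum() == pnet.n_links
        assert base.n_species == 50 + pnet.n_pollinators

    def test_diversity_arithmetic_endpoints(self, web):
        for p, s in ((3, 56), (19, 88)):
            pnet = ma.generate_pollination_network(p, rng_seed=p)
            base = ma.integrate(web, pnet, rng_seed=0)
            assert base.n_species == s

    def test_too_many_plants_rejected(self, web):
        pnet = ma.generate_pollination_network(19, rng_seed=0)
        # inflate the request beyond the web's 20 plants
        big = ma.PollinationNetwork(
            incidence=np.ones((21, 42), dtype=bool)
        )
        with pytest.raises(ValueError):
            ma.integrate(web, big, rng_seed=0)
        ma.integrate(web, pnet, rng_seed=0)  # 19 <= 20 is fine


class TestRewardsOnly:
    def test_pollinators_have_no_foodweb_resources(self, ro_pair):
        ro = ro_pair["RO"]
        polls = ro.pollinators
        assert (ro.rng[polls] == 0).all()
        assert (ro.c[polls] == 0).all()
        assert not ro.veg[polls].any()
        assert not ro.ani[polls].any()
        assert ro.rew[polls].any(axis=1).all()

    def test_niche_values_near_some_strict_herbivore(self, ro_pair):
        ro = ro_pair["RO"]
        herbs = ro.n[
            np.intersect1d(
                np.flatnonzero(ro.guild == "herbivore"), np.arange(50)
            )
        ]
        for n_p in ro.n[ro.pollinators]:
            assert (np.abs(n_p - herbs) <= 0.05 * herbs + 1e-12).any()

    def test_predators_cover_pollinator_niche(self, ro_pair):
        ro = ro_pair["RO"]
        polls = ro.pollinators
        inside = (
            np.abs(ro.n[None, polls] - ro.c[:50, None]) <= ro.rng[:50, None] / 2
        )
        inside[ro.is_plant[:50]] = False
        assert np.array_equal(inside, ro.ani[:50][:, polls])

    def test_requires_strict_herbivore(self):
        # a web view with no strict herbivores cannot template RO pollinators
        adj = np.zeros((3, 3), dtype=bool)
        adj[1, 0] = adj[2, 1] = adj[2, 0] = True  # herbivore is index 1
        web = ma.FoodWeb(n=np.array([0.1, 0.5, 0.9]), rng=np.zeros(3),
                         c=np.zeros(3), adjacency=adj)
        pnet = ma.PollinationNetwork(incidence=np.ones((1, 2), dtype=bool))
        base = ma.integrate(web, pnet, rng_seed=0)
        ro = ma.attach_ro_pollinators(base, rng_seed=0)  # herbivore exists
        assert ro.treatment == "RO"
        adj2 = adj.copy()
        adj2[1, 2] = True  # now an omnivore; no strict herbivore remains
        web2 = ma.FoodWeb(n=web.n, rng=web.rng, c=web.c, adjacency=adj2)
        with pytest.raises(ValueError, match="strict herbivore"):
            ma.attach_ro_pollinators(ma.integrate(web2, pnet, rng_seed=0),
                                     rng_seed=0)


class TestRewardsPlus:
    def test_templates_confined_to_low_trophic_plant_eaters(self, ro_pair):
        rp = ro_pair["RP"]
        swtl = ma.trophic_levels((rp.veg | rp.ani)[:50, :50])
        eligible_n = rp.n[:50][
            (swtl >= 2) & (swtl <= 2.3)
            & (rp.veg[:50, :50].any(axis=1))
        ]
        for n_p in rp.n[rp.pollinators]:
            assert (np.abs(n_p - eligible_n) <= 0.05 * eligible_n + 1e-12).any()

    def test_niche_invariants_after_perturbation(self, ro_pair):
        rp = ro_pair["RP"]
        polls = rp.pollinators
        assert (rp.rng[polls] <= rp.n[polls] + 1e-12).all()
        assert (rp.c[polls] >= rp.rng[polls] / 2 - 1e-12).all()
        assert (
            rp.c[polls]
            <= np.minimum(rp.n[polls], 1 - rp.rng[polls] / 2) + 1e-12
        ).all()

    def test_double_links_allowed(self, webs):
        """Some RP pollinator eats both vegetation and rewards of one plant."""
        found = False
        for k in range(8):
            pnet = ma.generate_pollination_network(10, rng_seed=k)
            base = ma.integrate(webs[0], pnet, rng_seed=k)
            rp = ma.attach_rp_pollinators(base, rng_seed=k)
            if (rp.veg & rp.rew).any():
                found = True
                break
        assert found

    def test_pollinators_resolve_diets_from_intervals(self, ro_pair):
        rp = ro_pair["RP"]
        polls = rp.pollinators
        inside = (
            np.abs(rp.n[None, :] - rp.c[polls, None]) <= rp.rng[polls, None] / 2
        )
        assert np.array_equal(inside & rp.is_plant[None, :], rp.veg[polls])
        assert np.array_equal(inside & ~rp.is_plant[None, :], rp.ani[polls])


class TestFoodWebDerivation:
    def test_no_rewards_structure_remains(self, ro_pair):
        for key in ("RO", "RP"):
            fw = ma.to_food_web(ro_pair[key])
            assert fw.treatment == key + "_FW"
            assert not fw.rew.any()
            assert not fw.has_rewards_pool.any()
            assert not (fw.guild == "plant_with_pollinators").any()

    def test_ro_added_animals_are_strict_herbivores(self, ro_pair):
        fw = ma.to_food_web(ro_pair["RO"])
        polls = fw.pollinators
        assert (fw.guild[polls] == "added_herbivore").all()
        assert fw.veg[polls].any(axis=1).all()
        assert not fw.ani[polls].any()

    def test_deduplication_can_only_reduce_connectance(self, ro_pair):
        rp = ro_pair["RP"]
        fw = ma.to_food_web(rp)
        assert fw.connectance <= rp.connectance

    def test_idempotent(self, ro_pair):
        fw = ma.to_food_web(ro_pair["RO"])
        fw2 = ma.to_food_web(fw)
        assert np.array_equal(fw.veg, fw2.veg)
        assert np.array_equal(fw.ani, fw2.ani)
        assert (fw.guild == fw2.guild).all()


class TestDesignQuantities:
    def test_mutualism_prevalence_by_construction(self, web):
        """(P+A)/S rises from 16% at S=56 to 65% at S=88."""
        for p, pct in ((3, 16), (19, 65)):
            pnet = ma.generate_pollination_network(p, rng_seed=p)
            base = ma.integrate(web, pnet, rng_seed=1)
            frac = (p + pnet.n_pollinators) / base.n_species
            assert round(100 * frac) == pct
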