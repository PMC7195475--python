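"""Functional response, consumption, benefit, RHS, and integration."""

import numpy as np
import pytest

import multiplexatn as ma
from multiplexatn.assembly import MultiplexNetwork
from multiplexatn.fixtures import fixture

from .oracle import naive_rhs, random_small_system


def _single_consumer_system(b0_key="b0_biomass"):
    """One plant, one consumer with a single vegetation resource."""
    fx = fixture("three-level-chain")
    return ma.compile_system(fx.network, fx.params)


class TestFunctionalResponse:
    def test_half_saturation_and_zero_resource(self):
        sys = _single_consumer_system()
        b0 = sys.params.constants["b0_biomass"]
        y = np.array([b0, 1.0, 0.0])  # plant at B0, herbivore present
        assert sys.functional_response(y, 1, 0) == pytest.approx(0.5)
        y0 = np.array([0.0, 1.0, 0.0])
        assert sys.functional_response(y0, 1, 0) == 0.0

    def test_two_equal_resources_at_half_saturation(self):
        """omega = 1/2 each, X = B0 = 60, h = 1.5 -> F = 1/4 per resource."""
        veg = np.zeros((3, 3), dtype=bool)
        veg[2, 0] = veg[2, 1] = True
        mx = MultiplexNetwork(
            treatment="base", n=np.array([0.1, 0.2, 0.5]), rng=np.zeros(3),
            c=np.zeros(3),
            guild=np.array(["plant", "plant", "herbivore"], dtype=object),
            veg=veg, ani=np.zeros_like(veg), rew=np.zeros_like(veg),
            has_rewards_pool=np.zeros(3, dtype=bool),
        )
        params = ma.parameterize(mx, z=np.full(3, 10.0))
        sys = ma.compile_system(mx, params)
        y = np.array([60.0, 60.0, 1.0])
        # denominator: 60^1.5 + 0.5*60^1.5 + 0.5*60^1.5 = 2*60^1.5
        assert sys.functional_response(y, 2, 0) == pytest.approx(0.25)
        assert sys.functional_response(y, 2, 1) == pytest.approx(0.25)


class TestConsumption:
    def test_rate_and_extraction_reference_values(self):
        """C = x y B F = 0.314*10*1*0.5 = 1.57; extraction = C/0.66 = 2.379."""
        veg = np.zeros((2, 2), dtype=bool)
        veg[1, 0] = True
        mx = MultiplexNetwork(
            treatment="base", n=np.array([0.1, 0.5]), rng=np.zeros(2),
            c=np.zeros(2), guild=np.array(["plant", "herbivore"], dtype=object),
            veg=veg, ani=np.zeros_like(veg), rew=np.zeros_like(veg),
            has_rewards_pool=np.zeros(2, dtype=bool),
        )
        # z = 1 puts the herbivore at the reference mass, so x = 0.314
        params = ma.parameterize(mx, z=np.ones(2))
        sys = ma.compile_system(mx, params)
        b0 = sys.params.constants["b0_biomass"]
        y = np.array([b0, 1.0])
        c = sys.consumption(y, 1, 0)
        assert c == pytest.approx(0.314 * 10 * 1.0 * 0.5)
        assert c / 0.66 == pytest.approx(1.57 / 0.66)
        y_zero = y.copy()
        y_zero[1] = 0.0
        assert sys.consumption(y_zero, 1, 0) == 0.0


class TestBenefit:
    def test_no_visits_no_benefit(self):
        fx = fixture("plant-pollinator-pair")
        sys = ma.compile_system(fx.network, fx.params)
        y = np.array([10.0, 0.0, 5.0])  # pollinator extinct
        assert sys.benefit(y, 0) == 0.0

    def test_half_saturation_at_printed_constant(self):
        """services = 0.05 -> P = 0.5 under the 0.05 half-saturation."""
        fx = fixture("plant-pollinator-pair")
        sys = ma.compile_system(fx.network, fx.params)
        # specialist pollinator: quality = 1, services = C. Solve for the
        # rewards level R* at which C(R*) = 0.05, then check P = 0.5.
        x_p = fx.params.x[1]
        b_poll = 1.0
        target = 0.05

        def services(r):
            y = np.array([10.0, b_poll, r])
            return sys.consumption(y, 1, 0, rewards=True)

        lo, hi = 1e-9, 50.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if services(mid) < target:
                lo = mid
            else:
                hi = mid
        y = np.array([10.0, b_poll, 0.5 * (lo + hi)])
        assert sys.benefit(y, 0) == pytest.approx(0.5, abs=1e-6)

    def test_specialist_quality_is_unity(self):
        fx = fixture("plant-pollinator-pair")
        sys = ma.compile_system(fx.network, fx.params)
        y = np.array([10.0, 2.0, 15.0])
        c = sys.consumption(y, 1, 0, rewards=True)
        h0 = fx.params.constants["benefit_half_saturation"]
        assert sys.benefit(y, 0) == pytest.approx(c / (h0 + c))


class TestRhs:
    def test_logistic_equilibrium_and_low_density_growth(self):
        fx = fixture("one-plant-logistic")
        sys = ma.compile_system(fx.network, fx.params)
        k = fx.params.k
        assert sys.rhs(0.0, np.array([k]))[0] == pytest.approx(0.0, abs=1e-12)
        b = 1e-4
        assert sys.rhs(0.0, np.array([b]))[0] == pytest.approx(
            0.8 * b, rel=1e-3
        )

    def test_rewards_pool_net_production(self):
        """dR/dt = beta*B - s*R = 1 at B=1, R=0, beta=1."""
        fx = fixture("plant-pollinator-pair")
        sys = ma.compile_system(fx.network, fx.params)
        y = np.array([1.0, 0.0, 0.0])
        assert sys.rhs(0.0, y)[2] == pytest.approx(1.0)
        y2 = np.array([1.0, 0.0, 2.0])
        assert sys.rhs(0.0, y2)[2] == pytest.approx(1.0 - 0.4 * 2.0)

    @pytest.mark.parametrize("control", [False, True])
    def test_matches_independent_evaluator(self, control):
        """Vectorised RHS equals the naive loop evaluator to 1e-10."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            mx, params = random_small_system(rng)
            n_pools = int(mx.has_rewards_pool.sum())
            prod = rng.uniform(0, 2, n_pools) if control else None
            sys = ma.compile_system(mx, params, control_production=prod)
            y = np.concatenate([
                rng.uniform(0, 100, mx.n_species),
                rng.uniform(0, 50, n_pools),
            ])
            got = sys.rhs(0.0, y)
            want = naive_rhs(mx, params, y, control_production=prod)
            scale = np.maximum(np.abs(want), 1.0)
            assert np.abs(got - want).max() / scale.max() < 1e-10
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-10)


class TestSimulate:
    def test_plants_only_community_reaches_carrying_capacity(self):
        """With no consumers, summed vegetation converges to K = 480."""
        s = 5
        mx = MultiplexNetwork(
            treatment="base", n=np.linspace(0.1, 0.5, s), rng=np.zeros(s),
            c=np.zeros(s), guild=np.array(["plant"] * s, dtype=object),
            veg=np.zeros((s, s), dtype=bool), ani=np.zeros((s, s), dtype=bool),
            rew=np.zeros((s, s), dtype=bool),
            has_rewards_pool=np.zeros(s, dtype=bool),
        )
        params = ma.parameterize(mx, z=np.ones(s))
        res = ma.simulate(ma.compile_system(mx, params), t_end=5000)
        total = res.biomass()[-1].sum()
        assert abs(total - 480.0) / 480.0 < 1e-3
        assert ma.persistence(res) == 1.0

    def test_extinct_species_zeroed_for_good(self, batch):
        """Once below threshold, sampled biomass is exactly 0 ever after."""
        checked = 0
        for pairing in batch[:3]:
            for res in pairing.values():
                for sp, t_ev in res.extinctions:
                    after = res.times > t_ev
                    assert (res.biomass()[after, sp] == 0.0).all()
                    checked += 1
        assert checked > 0

    def test_no_negative_biomass_beyond_solver_tolerance(self, batch):
        for pairing in batch[:3]:
            for res in pairing.values():
                assert res.trajectory.min() > -1e-9

    def test_foodweb_equivalence_of_code_paths(self, ro_pair):
        """An FW treatment integrates identically through the multiplex
        machinery and through a bare food-web reconstruction."""
        fw = ma.to_food_web(ro_pair["RO"])
        z = ma.draw_size_ratios(fw.n_species, rng_seed=4)
        p1 = ma.parameterize(fw, rewards_productivity=0.0, z=z)
        res1 = ma.simulate(ma.compile_system(fw, p1), t_end=300)
        # rebuild as a plain food web: same adjacency, fresh guild labels
        adj = fw.veg | fw.ani
        plain_web = ma.FoodWeb(n=fw.n, rng=fw.rng, c=fw.c, adjacency=adj)
        plain = MultiplexNetwork(
            treatment="base", n=fw.n, rng=fw.rng, c=fw.c,
            guild=ma.classify_guilds(plain_web),
            veg=adj & plain_web.is_plant[None, :],
            ani=adj & ~plain_web.is_plant[None, :],
            rew=np.zeros_like(adj),
            has_rewards_pool=np.zeros(fw.n_species, dtype=bool),
        )
        p2 = ma.parameterize(plain, rewards_productivity=0.0, z=z)
        res2 = ma.simulate(ma.compile_system(plain, p2), t_end=300)
        np.testing.assert_allclose(
            res1.trajectory, res2.trajectory, rtol=1e-5, atol=1e-7
        )

    def test_deterministic_trajectories(self):
        fx = fixture("rp-double-link")
        sys = ma.compile_system(fx.network, fx.params)
        r1 = ma.simulate(sys, t_end=200)
        r2 = ma.simulate(sys, t_end=200)
        assert np.array_equal(r1.trajectory, r2.trajectory)

    def test_higher_rewards_productivity_helps_pollinators(self, batch):
        """Mean added-pollinator persistence does not fall from beta=0.2
        to beta=1.0 (rewards-only treatments, across the batch)."""
        def poll_persist(key):
            vals = []
            for pairing in batch:
                res = pairing[key]
                polls = res.network.pollinators
                vals.append(res.survived[polls].mean())
            return np.mean(vals)

        assert poll_persist("RO_High") >= poll_persist("RO_Low")
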