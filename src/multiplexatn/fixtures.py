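"""Hand-built miniature networks with closed-form expectations.

These bypass the stochastic generators entirely, so dynamics can be
exercised (and debugged) independently of generator behaviour.  Each
fixture bundles a network, a parameter set, and a dictionary of
documented expectations used by the test-suite (closed-form equilibria
and reference states for term-by-term right-hand-side checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import MultiplexNetwork
from .bioenergetics import ParameterSet, parameterize

__all__ = ["Fixture", "available_fixtures", "fixture"]


@dataclass(frozen=True)
class Fixture:
    name: str
    network: MultiplexNetwork
    params: ParameterSet
    expected: dict = field(default_factory=dict)


def _network(
    treatment: str,
    guild: list[str],
    veg: list[tuple[int, int]] = (),
    ani: list[tuple[int, int]] = (),
    rew: list[tuple[int, int]] = (),
    pools: list[int] = (),
    n_foodweb: int | None = None,
) -> MultiplexNetwork:
    s = len(guild)
    mats = {}
    for name, links in (("veg", veg), ("ani", ani), ("rew", rew)):
        m = np.zeros((s, s), dtype=bool)
        for i, j in links:
            m[i, j] = True
        mats[name] = m
    has_pool = np.zeros(s, dtype=bool)
    has_pool[list(pools)] = True
    return MultiplexNetwork(
        treatment=treatment,
        n=np.linspace(0.1, 0.9, s),
        rng=np.zeros(s),
        c=np.zeros(s),
        guild=np.array(guild, dtype=object),
        has_rewards_pool=has_pool,
        n_foodweb_species=s if n_foodweb is None else n_foodweb,
        **mats,
    )


def _one_plant_logistic() -> Fixture:
    net = _network("base", ["plant"])
    params = parameterize(net, rewards_productivity=0.0, z=np.ones(1))
    return Fixture(
        "one-plant-logistic", net, params,
        expected={
            # logistic growth alone: dB/dt = (1 - B/K) r B, equilibrium at K
            "equilibrium_biomass": params.k,
            "growth_rate": 0.8,
        },
    )


def _plant_pollinator_pair() -> Fixture:
    # minimal rewards-only mutualism: one plant with a pool, one pollinator
    net = _network(
        "RO", ["plant_with_pollinators", "added_herbivore"],
        rew=[(1, 0)], pools=[0], n_foodweb=1,
    )
    params = parameterize(net, rewards_productivity=1.0, z=np.array([1.0, 10.0]))
    return Fixture(
        "plant-pollinator-pair", net, params,
        expected={
            "pollinator_swtl": 2.0,
            "pollinator_mass": 10.0,
            # with no pollinator biomass there are no visits, hence no
            # reproductive services and zero vegetative growth
            "benefit_without_pollinator": 0.0,
            # dR/dt = beta*B - s*R with no feeding
            "rewards_net_at_B1_R0": 1.0,
        },
    )


def _three_level_chain() -> Fixture:
    net = _network(
        "base", ["plant", "herbivore", "carnivore"],
        veg=[(1, 0)], ani=[(2, 1)],
    )
    params = parameterize(
        net, rewards_productivity=0.0, z=np.array([1.0, 10.0, 10.0])
    )
    return Fixture(
        "three-level-chain", net, params,
        expected={
            "swtl": [1.0, 2.0, 3.0],
            "mass": [1.0, 10.0, 100.0],
            # reference state for term-by-term right-hand-side evaluation
            "state": [10.0, 10.0, 10.0],
        },
    )


def _rp_double_link() -> Fixture:
    # rewards-plus pollinator holding vegetation AND rewards links to the
    # same plant: two resource pools, omega = 1/2 each
    net = _network(
        "RP", ["plant_with_pollinators", "added_herbivore"],
        veg=[(1, 0)], rew=[(1, 0)], pools=[0], n_foodweb=1,
    )
    params = parameterize(net, rewards_productivity=1.0, z=np.array([1.0, 10.0]))
    return Fixture(
        "rp-double-link", net, params,
        expected={"omega": 0.5, "n_links": 2},
    )


_REGISTRY = {
    "one-plant-logistic": _one_plant_logistic,
    "plant-pollinator-pair": _plant_pollinator_pair,
    "three-level-chain": _three_level_chain,
    "rp-double-link": _rp_double_link,
}


def available_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def fixture(name: str) -> Fixture:
    """Return a registered fixture by name."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {available_fixtures()}"
        ) from None
    return builder()
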