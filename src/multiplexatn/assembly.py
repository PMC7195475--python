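"""Assemble food webs and pollination networks into multiplex treatments.

A multiplex network holds the 50 food-web species plus ``A`` added
pollinators, with three typed link classes:

- ``veg[i, j]``: consumer ``i`` eats the vegetative biomass of plant ``j``;
- ``ani[i, j]``: consumer ``i`` eats animal ``j``;
- ``rew[i, j]``: pollinator ``i`` eats the floral-rewards pool of plant
  ``j`` (each such link also carries the reproductive-service direction
  back to the plant).

Treatments: ``RO`` pollinators eat rewards only; ``RP`` pollinators get
perturbed copies of low-trophic-level consumers' niche traits and so also
eat vegetation and/or animals; ``RO_FW`` / ``RP_FW`` are the food-web
controls in which every rewards link is converted to a herbivory link on
the same plant and rewards pools are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .foodweb import FoodWeb, classify_guilds, trophic_levels
from .pollination import PollinationNetwork

__all__ = [
    "MultiplexNetwork",
    "attach_ro_pollinators",
    "attach_rp_pollinators",
    "integrate",
    "to_food_web",
]

#: multiplicative half-width of the "+/-5%" niche-trait perturbations
PERTURB = 0.05


@dataclass(frozen=True)
class MultiplexNetwork:
    """Typed multiplex interaction network for one treatment.

    Node order is fixed: food-web species 0..49 first, added pollinators
    after.  ``has_rewards_pool`` marks plants with pollinators; their
    rewards pools are resources but not nodes, so ``S`` counts species
    only and connectance is ``L / S**2`` with one link per (consumer,
    resource-pool) pair (an RP pollinator eating both vegetation and
    rewards of one plant contributes two links).
    """

    treatment: str  # "base", "RO", "RP", "RO_FW", "RP_FW"
    n: np.ndarray
    rng: np.ndarray
    c: np.ndarray
    guild: np.ndarray  # per-species labels, dtype=object
    veg: np.ndarray  # (S, S) bool
    ani: np.ndarray
    rew: np.ndarray
    has_rewards_pool: np.ndarray  # (S,) bool
    n_foodweb_species: int = 50

    @property
    def n_species(self) -> int:
        return self.guild.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.veg.sum() + self.ani.sum() + self.rew.sum())

    @property
    def connectance(self) -> float:
        return self.n_links / self.n_species**2

    @property
    def is_plant(self) -> np.ndarray:
        return (self.guild == "plant") | (self.guild == "plant_with_pollinators")

    @property
    def pollinators(self) -> np.ndarray:
        """Indices of the added species (pollinators or added animals)."""
        return np.arange(self.n_foodweb_species, self.n_species)

    def diet_matrix(self) -> np.ndarray:
        """Union of typed links with rewards mapped to the host plant.

        This is the trophic-structure view used for trophic levels: a
        rewards link counts as a resource link at the plant's trophic
        height.
        """
        return self.veg | self.ani | self.rew

    def trophic_levels(self) -> np.ndarray:
        return trophic_levels(self.diet_matrix())


def integrate(
    web: FoodWeb,
    pnet: PollinationNetwork,
    rng_seed: int | np.random.Generator | None = None,
) -> MultiplexNetwork:
    """Merge a pollination network into a food web (base multiplex).

    ``P`` of the web's plants, chosen uniformly at random, become plants
    with pollinators and gain rewards pools; the ``A`` pollinators enter
    as new nodes whose rewards links copy the bipartite incidence.  Niche
    traits of pollinators stay unset (NaN) until an attach step runs.
    """
    p = pnet.n_plants
    a = pnet.n_pollinators
    plants = web.plants
    if p > plants.size:
        raise ValueError(f"pollination network needs {p} plants, web has {plants.size}")
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(plants, size=p, replace=False)

    s_fw = web.n_species
    s = s_fw + a
    n = np.full(s, np.nan)
    r = np.full(s, np.nan)
    c = np.full(s, np.nan)
    n[:s_fw], r[:s_fw], c[:s_fw] = web.n, web.rng, web.c

    guild = np.empty(s, dtype=object)
    guild[:s_fw] = classify_guilds(web)
    guild[s_fw:] = "added_herbivore"  # provisional; attach steps refine

    is_plant_row = np.zeros(s, dtype=bool)
    is_plant_row[:s_fw] = web.is_plant
    veg = np.zeros((s, s), dtype=bool)
    ani = np.zeros((s, s), dtype=bool)
    rew = np.zeros((s, s), dtype=bool)
    veg[:s_fw, :s_fw] = web.adjacency & is_plant_row[None, :s_fw]
    ani[:s_fw, :s_fw] = web.adjacency & ~is_plant_row[None, :s_fw]

    has_pool = np.zeros(s, dtype=bool)
    has_pool[chosen] = True
    guild[chosen] = "plant_with_pollinators"
    for k in range(p):
        rew[s_fw + np.flatnonzero(pnet.incidence[k]), chosen[k]] = True

    return MultiplexNetwork(
        treatment="base", n=n, rng=r, c=c, guild=guild,
        veg=veg, ani=ani, rew=rew, has_rewards_pool=has_pool,
        n_foodweb_species=s_fw,
    )


def _perturb(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return values * rng.uniform(1.0 - PERTURB, 1.0 + PERTURB, size=values.shape)


def _foodweb_view(mx: MultiplexNetwork) -> FoodWeb:
    s_fw = mx.n_foodweb_species
    adj = (mx.veg | mx.ani)[:s_fw, :s_fw]
    return FoodWeb(
        n=mx.n[:s_fw], rng=mx.rng[:s_fw], c=mx.c[:s_fw], adjacency=adj
    )


def attach_ro_pollinators(
    base: MultiplexNetwork,
    rng_seed: int | np.random.Generator | None = None,
) -> MultiplexNetwork:
    """Rewards-Only treatment: pollinators eat floral rewards only.

    Each pollinator's niche value is set within +/-5% of a uniformly
    chosen strict herbivore's, placing it where herbivore predators
    forage; its feeding range and centre are zero so it gains no food-web
    resources.  Food-web consumers whose feeding interval covers the new
    niche value acquire a predation link on the pollinator.
    """
    rng = np.random.default_rng(rng_seed)
    web = _foodweb_view(base)
    herbs = web.strict_herbivores()
    if herbs.size == 0:
        raise ValueError("food web has no strict herbivore to template from")

    n = base.n.copy()
    r = base.rng.copy()
    c = base.c.copy()
    ani = base.ani.copy()
    polls = base.pollinators
    templates = rng.choice(herbs, size=polls.size, replace=True)
    n[polls] = np.clip(_perturb(n[templates], rng), 0.0, 1.0)
    r[polls] = 0.0
    c[polls] = 0.0
    s_fw = base.n_foodweb_species
    covered = (
        np.abs(n[None, polls] - c[:s_fw, None]) <= r[:s_fw, None] / 2.0
    )
    covered[web.is_plant, :] = False  # plants never gain feeding links
    ani[:s_fw, polls] = covered

    guild = base.guild.copy()
    guild[polls] = "added_herbivore"
    return replace(
        base, treatment="RO", n=n, rng=r, c=c, ani=ani, guild=guild
    )


def attach_rp_pollinators(
    base: MultiplexNetwork,
    rng_seed: int | np.random.Generator | None = None,
    tl_range: tuple[float, float] = (2.0, 2.3),
) -> MultiplexNetwork:
    """Rewards-Plus treatment: pollinators also eat vegetation and prey.

    Each pollinator copies the niche triple (n, rng, c) of a uniformly
    chosen plant-eating consumer with short-weighted trophic level inside
    ``tl_range``, each value independently perturbed by +/-5% and re-clipped
    to the niche-model invariants.  Diets and predators are then resolved
    from feeding intervals across the whole network (pollinators may eat
    or be eaten by other pollinators) on top of the retained rewards links.
    """
    rng = np.random.default_rng(rng_seed)
    web = _foodweb_view(base)
    swtl = trophic_levels(web.adjacency)
    eats_plant = (web.adjacency & web.is_plant[None, :]).any(axis=1)
    lo, hi = tl_range
    eligible = np.flatnonzero(eats_plant & (swtl >= lo) & (swtl <= hi))
    if eligible.size == 0:
        raise ValueError(
            f"no plant-eating consumer with swTL in [{lo}, {hi}] to template from"
        )

    n = base.n.copy()
    r = base.rng.copy()
    c = base.c.copy()
    polls = base.pollinators
    templates = rng.choice(eligible, size=polls.size, replace=True)
    n[polls] = np.clip(_perturb(n[templates], rng), 0.0, 1.0)
    r[polls] = np.minimum(_perturb(r[templates], rng), n[polls])
    c[polls] = np.clip(
        _perturb(c[templates], rng),
        r[polls] / 2.0,
        np.minimum(n[polls], 1.0 - r[polls] / 2.0),
    )

    s = base.n_species
    s_fw = base.n_foodweb_species
    is_plant = base.is_plant
    veg = base.veg.copy()
    ani = base.ani.copy()
    # pollinator diets from their new feeding intervals, over all species
    eats = np.abs(n[None, :] - c[polls, None]) <= r[polls, None] / 2.0
    veg[polls, :] = eats & is_plant[None, :]
    ani[polls, :] = eats & ~is_plant[None, :]
    # food-web consumers (not plants) prey on pollinators inside their interval
    covered = (
        np.abs(n[None, polls] - c[:s_fw, None]) <= r[:s_fw, None] / 2.0
    )
    covered[web.is_plant, :] = False
    ani[:s_fw, polls] = covered

    guild = base.guild.copy()
    eats_animal = ani[polls].any(axis=1)
    guild[polls] = np.where(eats_animal, "added_omnivore", "added_herbivore")
    return replace(
        base, treatment="RP", n=n, rng=r, c=c, veg=veg, ani=ani, guild=guild
    )


def to_food_web(mx: MultiplexNetwork) -> MultiplexNetwork:
    """Derive the food-web control of a multiplex treatment.

    Every rewards link becomes a herbivory link on the same plant
    (deduplicated against existing vegetation links, so RP_FW connectance
    can be slightly below RP), rewards pools disappear, plants with
    pollinators revert to ordinary plants, and added species are
    relabelled by their resulting diets.  Idempotent.
    """
    veg = mx.veg | mx.rew
    rew = np.zeros_like(mx.rew)
    guild = mx.guild.copy()
    guild[guild == "plant_with_pollinators"] = "plant"
    polls = mx.pollinators
    eats_animal = mx.ani[polls].any(axis=1)
    guild[polls] = np.where(eats_animal, "added_omnivore", "added_herbivore")
    treatment = {"RO": "RO_FW", "RP": "RP_FW"}.get(mx.treatment, mx.treatment)
    return replace(
        mx, treatment=treatment, veg=veg, rew=rew, guild=guild,
        has_rewards_pool=np.zeros_like(mx.has_rewards_pool),
    )
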