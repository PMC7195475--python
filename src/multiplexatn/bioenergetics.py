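"""Allometric and fixed parameters for multiplex dynamics.

Consumers' vital rates scale with body mass, as in allometric trophic
network (ATN) theory for invertebrates.  Plants sit at the reference mass
``m = 1``; a consumer's mass is ``Z ** (swTL - 1)`` where ``swTL`` is its
short-weighted trophic level on the multiplex structure (rewards links
count as resources at the host plant's trophic height) and ``Z`` is its
consumer-resource body-size ratio, drawn per species from a lognormal
with mean 10 and standard deviation 100, truncated below at 1 so that no
consumer is lighter than a plant.  Metabolic rate is ``x = 0.314 m**-0.25``.

Fixed parameters (overridable): maximum metabolic-specific consumption
``y = 10``; assimilation efficiencies 0.85 (animal prey), 0.66
(vegetation), 1.0 (rewards); half-saturation densities 60 (biomass) and
30 (rewards, reflecting lower handling time); Hill exponent ``h = 1.5``
(weak Type III); community carrying capacity ``K = 480``; plant growth
rates 0.8 (no pollinators) and 1.0 (with pollinators); rewards production
``beta`` (1.0 High / 0.2 Low / 0 in food-web treatments), self-limitation
``s = 0.4`` and production cost ``kappa = 0.1``; reproductive services
saturate with half-saturation constant 0.05.  Consumers are weak
generalists: preference ``omega = 1 / (initial diet size)``, never
renormalised after extinctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import MultiplexNetwork

__all__ = ["DEFAULTS", "ParameterSet", "draw_size_ratios",
           "parameterize", "weak_generalist_preferences"]

#: Fixed (non-allometric) defaults; any key can be overridden.
DEFAULTS: dict[str, float] = {
    "metabolic_coeff": 0.314,
    "metabolic_exp": -0.25,
    "y": 10.0,
    "e_animal": 0.85,
    "e_vegetation": 0.66,
    "e_rewards": 1.0,
    "b0_biomass": 60.0,
    "b0_rewards": 30.0,
    "hill": 1.5,
    "carrying_capacity": 480.0,
    "r_plant": 0.8,
    "r_plant_with_pollinators": 1.0,
    "self_limitation": 0.4,
    "rewards_cost": 0.1,
    "benefit_half_saturation": 0.05,
    "z_mean": 10.0,
    "z_sd": 100.0,
}


@dataclass(frozen=True)
class ParameterSet:
    """Complete dynamic parameterization of one multiplex treatment."""

    z: np.ndarray          # body-size ratios (NaN for plants)
    swtl: np.ndarray       # short-weighted trophic levels
    mass: np.ndarray       # body masses (plants = 1)
    x: np.ndarray          # mass-specific metabolic rates (plants = 0)
    r: np.ndarray          # plant growth rates (0 for animals)
    beta: np.ndarray       # rewards production (0 without a pool)
    s: np.ndarray          # rewards self-limitation
    kappa: np.ndarray      # vegetative cost of rewards production
    omega: np.ndarray      # weak-generalist preference per consumer
    constants: dict = field(default_factory=dict)

    @property
    def k(self) -> float:
        return self.constants["carrying_capacity"]

    @property
    def hill(self) -> float:
        return self.constants["hill"]


def draw_size_ratios(
    n: int,
    rng_seed: int | np.random.Generator | None = None,
    mean: float = 10.0,
    sd: float = 100.0,
    truncate_at: float | None = 1.0,
) -> np.ndarray:
    """Lognormal consumer-resource size ratios, one per species.

    ``mean`` and ``sd`` parameterize the lognormal variate itself; the
    underlying normal has ``sigma**2 = ln(1 + (sd/mean)**2)`` and
    ``mu = ln(mean) - sigma**2 / 2``.  Draws below ``truncate_at`` are
    resampled (pass ``None`` to disable truncation).
    """
    rng = np.random.default_rng(rng_seed)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    z = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    if truncate_at is not None:
        while True:
            low = z < truncate_at
            if not low.any():
                break
            z[low] = rng.lognormal(mu, np.sqrt(sigma2), size=int(low.sum()))
    return z


def weak_generalist_preferences(mx: MultiplexNetwork) -> np.ndarray:
    """Preference ``omega_i = 1 / |initial diet of i|`` per consumer.

    The diet counts resource pools: an RP pollinator holding both a
    vegetation and a rewards link to one plant has two resources there.
    Preferences are fixed at assembly and never renormalised when
    resources go extinct.  Plants (empty diets) get 0.
    """
    diet_size = (
        mx.veg.sum(axis=1) + mx.ani.sum(axis=1) + mx.rew.sum(axis=1)
    )
    if ((diet_size == 0) & ~mx.is_plant).any():
        raise ValueError("non-plant consumer with empty diet")
    with np.errstate(divide="ignore"):
        return np.where(diet_size > 0, 1.0 / np.maximum(diet_size, 1), 0.0)


def parameterize(
    mx: MultiplexNetwork,
    rewards_productivity: float = 1.0,
    rng_seed: int | np.random.Generator | None = None,
    z: np.ndarray | None = None,
    overrides: dict[str, float] | None = None,
) -> ParameterSet:
    """Build the full :class:`ParameterSet` for one treatment.

    ``rewards_productivity`` is the per-biomass rewards production rate
    ``beta`` applied to plants with pollinators (ignored in food-web
    treatments, which have no rewards pools).  Pass ``z`` to reuse size
    ratios across the treatments of one network pairing; otherwise they
    are drawn from ``rng_seed``.  ``overrides`` substitutes any scalar in
    :data:`DEFAULTS`.
    """
    consts = dict(DEFAULTS)
    if overrides:
        unknown = set(overrides) - set(consts)
        if unknown:
            raise KeyError(f"unknown parameter overrides: {sorted(unknown)}")
        consts.update(overrides)

    s_n = mx.n_species
    is_plant = mx.is_plant
    swtl = mx.trophic_levels()
    if z is None:
        z = draw_size_ratios(
            s_n, rng_seed, mean=consts["z_mean"], sd=consts["z_sd"]
        )
    z = np.asarray(z, dtype=float)
    z_eff = np.where(is_plant, np.nan, z)

    mass = np.where(is_plant, 1.0, z ** (swtl - 1.0))
    if not (mass[~is_plant] > 0).all():
        raise ValueError("non-positive consumer body mass")
    x = np.where(
        is_plant, 0.0,
        consts["metabolic_coeff"] * mass ** consts["metabolic_exp"],
    )
    r = np.where(
        is_plant,
        np.where(
            mx.has_rewards_pool,
            consts["r_plant_with_pollinators"],
            consts["r_plant"],
        ),
        0.0,
    )
    beta = np.where(mx.has_rewards_pool, rewards_productivity, 0.0)
    s_lim = np.where(mx.has_rewards_pool, consts["self_limitation"], 0.0)
    kappa = np.where(mx.has_rewards_pool, consts["rewards_cost"], 0.0)
    omega = weak_generalist_preferences(mx)

    return ParameterSet(
        z=z_eff, swtl=swtl, mass=mass, x=x, r=r, beta=beta,
        s=s_lim, kappa=kappa, omega=omega, constants=consts,
    )
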