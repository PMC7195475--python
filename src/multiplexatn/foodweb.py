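"""Niche-model food webs with structural constraints.

The niche model places every species on a one-dimensional niche axis:
species i gets a niche value ``n_i ~ U(0,1)``, a feeding-range width
``rng_i = x * n_i`` with ``x ~ Beta(1, b)`` chosen so that ``E[x]`` equals
twice the target connectance, and a feeding centre ``c_i`` drawn uniformly
from ``[rng_i/2, min(n_i, 1 - rng_i/2)]``.  Species i eats every species j
whose niche value falls inside i's feeding interval of total width
``rng_i`` centred on ``c_i``.  The species with the smallest niche value
is forced basal (``rng = 0``) so at least one plant always exists.

Webs are rejection-sampled until they satisfy a set of structural
constraints (connectance window, exact plant count, exact count of strict
herbivores, no isolated or trophically duplicate species, every consumer
connected to a plant).  Sampling is vectorised over large batches because
the joint constraints are rare (~1e-5 per draw at the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FoodWeb",
    "GenerationError",
    "WebConstraints",
    "classify_guilds",
    "generate_niche_web",
    "trophic_levels",
]


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget."""


@dataclass(frozen=True)
class WebConstraints:
    """Structural acceptance constraints for generated niche webs.

    ``n_plants`` and ``n_strict_herbivores`` are exact counts; a strict
    herbivore is a species with a non-empty diet consisting only of
    plants (hence short-weighted trophic level exactly 2).  ``c_window``
    is an open interval for directed connectance ``L / S**2``.
    """

    n_plants: int = 20
    n_strict_herbivores: int = 5
    c_window: tuple[float, float] = (0.0976, 0.1024)


@dataclass(frozen=True)
class FoodWeb:
    """A directed feeding network from the niche model.

    ``adjacency[i, j]`` is True when consumer ``i`` eats resource ``j``
    (cannibalistic ``i == j`` entries are legal).  Plants are exactly the
    species with empty diets.
    """

    n: np.ndarray
    rng: np.ndarray
    c: np.ndarray
    adjacency: np.ndarray

    @property
    def n_species(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())

    @property
    def connectance(self) -> float:
        return self.n_links / self.n_species**2

    @property
    def is_plant(self) -> np.ndarray:
        return ~self.adjacency.any(axis=1)

    @property
    def plants(self) -> np.ndarray:
        return np.flatnonzero(self.is_plant)

    def strict_herbivores(self) -> np.ndarray:
        """Species whose non-empty diet contains only plants."""
        eats_animal = (self.adjacency & ~self.is_plant[None, :]).any(axis=1)
        return np.flatnonzero(~self.is_plant & ~eats_animal)

    def edge_list(self) -> np.ndarray:
        """(L, 2) array of (consumer_id, resource_id), 0-based."""
        cons, res = np.nonzero(self.adjacency)
        return np.column_stack([cons, res])


def _batch_draw(batch: int, s_f: int, beta_b: float, rng: np.random.Generator):
    """Draw a batch of niche webs as stacked trait and adjacency arrays."""
    n = rng.random((batch, s_f))
    x = rng.beta(1.0, beta_b, (batch, s_f))
    r = x * n
    # force the lowest-niche species basal so >=1 plant always exists
    r[np.arange(batch), np.argmin(n, axis=1)] = 0.0
    lo = r / 2.0
    hi = np.minimum(n, 1.0 - r / 2.0)
    c = lo + rng.random((batch, s_f)) * (hi - lo)
    adj = np.abs(n[:, None, :] - c[:, :, None]) <= r[:, :, None] / 2.0
    return n, r, c, adj


def _structurally_sound(adj: np.ndarray, is_plant: np.ndarray) -> bool:
    """Check connectivity, no isolated nodes and no trophic duplicates."""
    s = adj.shape[0]
    # plants must have at least one consumer (no isolated nodes)
    if not adj[:, is_plant].any(axis=0).all():
        return False
    # every consumer must reach a plant along diet links
    reach = is_plant.copy()
    for _ in range(s):
        new = reach | (adj & reach[None, :]).any(axis=1)
        if (new == reach).all():
            break
        reach = new
    if not reach.all():
        return False
    # no two consumers with identical consumer and resource sets; plants
    # are exempt -- consumer sets are niche intervals, so with many
    # plants, pairs of plants sharing an identical consumer set are near
    # certain and rejecting them makes the joint constraints unattainable
    cons = ~is_plant
    sig = np.concatenate([adj[cons], adj.T[cons]], axis=1)
    if np.unique(sig, axis=0).shape[0] != int(cons.sum()):
        return False
    return True


def generate_niche_web(
    s_f: int = 50,
    c_f_target: float = 0.1,
    constraints: WebConstraints | None = None,
    rng_seed: int | np.random.Generator | None = None,
    max_attempts: int = 10**7,
    batch_size: int = 4096,
) -> FoodWeb:
    """Rejection-sample a niche-model food web meeting all constraints.

    Parameters
    ----------
    s_f
        Species richness of the web (default 50).
    c_f_target
        Target directed connectance; sets the beta-distribution shape via
        ``E[x] = 2 * c_f_target``, i.e. ``x ~ Beta(1, 1/(2*C) - 1)``.
    constraints
        Structural acceptance rules; ``None`` uses :class:`WebConstraints`
        defaults (20 plants, 5 strict herbivores, C in (0.0976, 0.1024)).
    rng_seed
        Seed or Generator; the same seed always yields the same web.
    max_attempts
        Budget of candidate draws before :class:`GenerationError`.
    """
    if s_f < 2:
        raise ValueError("s_f must be >= 2")
    if not 0.0 < c_f_target < 0.5:
        raise ValueError("c_f_target must lie in (0, 0.5)")
    cons = constraints if constraints is not None else WebConstraints()
    beta_b = 1.0 / (2.0 * c_f_target) - 1.0
    gen = np.random.default_rng(rng_seed)
    lo, hi = cons.c_window

    attempts = 0
    while attempts < max_attempts:
        nb = min(batch_size, max_attempts - attempts)
        n, r, c, adj = _batch_draw(nb, s_f, beta_b, gen)
        attempts += nb
        diet = adj.sum(axis=2)
        is_plant = diet == 0
        links = adj.sum(axis=(1, 2))
        conn = links / s_f**2
        eats_animal = (adj & ~is_plant[:, None, :]).any(axis=2)
        n_herb = ((diet > 0) & ~eats_animal).sum(axis=1)
        ok = (
            (is_plant.sum(axis=1) == cons.n_plants)
            & (n_herb == cons.n_strict_herbivores)
            & (conn > lo)
            & (conn < hi)
        )
        for k in np.flatnonzero(ok):
            if _structurally_sound(adj[k], is_plant[k]):
                return FoodWeb(
                    n=n[k].copy(), rng=r[k].copy(), c=c[k].copy(),
                    adjacency=adj[k].copy(),
                )
    raise GenerationError(
        f"no web satisfying {cons} after {attempts} draws "
        f"(s_f={s_f}, c_f_target={c_f_target}); constraints are jointly "
        "rare -- raise max_attempts or relax the constraint set"
    )


def trophic_levels(adjacency: np.ndarray) -> np.ndarray:
    """Short-weighted trophic level (swTL) for every species.

    swTL is the mean of two classical measures: the shortest-chain
    trophic level (1 + length of the shortest diet path to any plant)
    and the prey-averaged trophic level (1 + mean trophic level of the
    diet, solved as a linear system).  Plants (empty diets) sit at
    level 1 for both, hence swTL = 1.
    """
    adj = np.asarray(adjacency, dtype=bool)
    s = adj.shape[0]
    is_plant = ~adj.any(axis=1)
    # shortest-chain levels via breadth-first relaxation from the plants
    shortest = np.where(is_plant, 1.0, np.inf)
    for _ in range(s):
        prey_min = np.where(adj, shortest[None, :], np.inf).min(
            axis=1, initial=np.inf
        )
        new = np.where(is_plant, 1.0, 1.0 + prey_min)
        if np.array_equal(new, shortest):
            break
        shortest = new
    if not np.isfinite(shortest).all():
        bad = np.flatnonzero(~np.isfinite(shortest))
        raise ValueError(
            f"species {bad.tolist()} have no diet path to any plant"
        )
    # prey-averaged levels: TL = 1 + D @ TL with row-normalised diets
    diet_size = adj.sum(axis=1)
    d = np.where(
        diet_size[:, None] > 0, adj / np.maximum(diet_size, 1)[:, None], 0.0
    )
    prey_avg = np.linalg.solve(np.eye(s) - d, np.ones(s))
    return (shortest + prey_avg) / 2.0


def classify_guilds(web: FoodWeb) -> np.ndarray:
    """Guild label per species of a bare niche-model web.

    Labels: ``plant`` (empty diet), ``herbivore`` (eats only plants),
    ``omnivore`` (eats plants and animals), ``carnivore`` (eats only
    animals).  Assembly-added species receive ``added_*`` labels from the
    assembly step, never here.
    """
    is_plant = web.is_plant
    eats_plant = (web.adjacency & is_plant[None, :]).any(axis=1)
    eats_animal = (web.adjacency & ~is_plant[None, :]).any(axis=1)
    labels = np.empty(web.n_species, dtype=object)
    labels[is_plant] = "plant"
    labels[~is_plant & eats_plant & ~eats_animal] = "herbivore"
    labels[~is_plant & eats_plant & eats_animal] = "omnivore"
    labels[~is_plant & ~eats_plant & eats_animal] = "carnivore"
    if (labels == None).any():  # noqa: E711 -- unfilled object entries
        raise ValueError("species with empty diet not flagged as plant")
    return labels
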