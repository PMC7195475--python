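"""Stochastic bipartite plant-pollinator networks and NODF nestedness.

Networks have ``P`` plants and exactly ``A = 2P`` animal pollinators, the
pollinator-to-plant ratio typical of empirical pollination webs.  Link
counts follow a connectance-diversity curve ``C_p(S_p) = a * S_p**-b``
(connectance decreasing with diversity, as observed empirically); the
default ``(a, b)`` are calibrated so that, after assembly into a 50-species
food web, mean rewards-only multiplex connectance is ~0.091 at S = 56 and
~0.06 at S = 88.

The generator samples heavy-tailed degree weights for both guilds, lays a
coverage skeleton so every species holds at least one link, places the
remaining links by weighted sampling without replacement, and finally
accepts or rejects on a NODF nestedness band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .foodweb import GenerationError

__all__ = [
    "PollinationNetwork",
    "batch_generate",
    "default_connectance_curve",
    "generate_pollination_network",
    "nodf",
]

#: Default power-law connectance curve C_p(S_p) = a * S_p**-b, calibrated
#: against the assembled multiplex connectance means (see docs/methods.md).
CONNECTANCE_A = 2.86
CONNECTANCE_B = 0.851


def default_connectance_curve(s_p: int | float) -> float:
    """Target bipartite connectance for a network of diversity ``S_p``."""
    return min(1.0, CONNECTANCE_A * float(s_p) ** -CONNECTANCE_B)


@dataclass(frozen=True)
class PollinationNetwork:
    """Binary plant x pollinator incidence with summary statistics."""

    incidence: np.ndarray  # (P, A) bool, rows are plants

    @property
    def n_plants(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_pollinators(self) -> int:
        return self.incidence.shape[1]

    @property
    def diversity(self) -> int:
        """S_p = P + A."""
        return self.n_plants + self.n_pollinators

    @property
    def n_links(self) -> int:
        return int(self.incidence.sum())

    @property
    def connectance(self) -> float:
        return self.n_links / (self.n_plants * self.n_pollinators)

    @property
    def nestedness(self) -> float:
        return nodf(self.incidence)


def nodf(incidence: np.ndarray) -> float:
    """NODF nestedness of a binary matrix, on the 0-100 scale.

    For every (row, row) and (column, column) pair whose marginal totals
    strictly decrease, the pair contributes the percentage of the smaller
    margin's links shared with the larger; all other pairs contribute 0.
    NODF is the mean contribution over all pairs.
    """
    m = np.asarray(incidence, dtype=bool)
    if m.size == 0:
        raise ValueError("incidence matrix must be non-empty")

    def _axis_sum(mat: np.ndarray) -> tuple[float, int]:
        k = mat.shape[0]
        if k < 2:
            return 0.0, 0
        deg = mat.sum(axis=1)
        overlap = (mat.astype(np.int64) @ mat.T.astype(np.int64)).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = overlap / np.minimum.outer(deg, deg)
        frac = np.nan_to_num(frac)
        decreasing = np.not_equal.outer(deg, deg)  # strict inequality somewhere
        iu = np.triu_indices(k, 1)
        paired = np.where(decreasing, frac * 100.0, 0.0)
        return float(paired[iu].sum()), len(iu[0])

    row_sum, row_pairs = _axis_sum(m)
    col_sum, col_pairs = _axis_sum(m.T)
    total_pairs = row_pairs + col_pairs
    if total_pairs == 0:
        return 0.0
    return (row_sum + col_sum) / total_pairs


def _degree_weights(k: int, rng: np.random.Generator) -> np.ndarray:
    # heavy-tailed (truncated power-law) weights drive degree heterogeneity,
    # which in turn produces nested incidence structure
    w = 1.0 + rng.pareto(1.5, size=k)
    return np.minimum(w, 50.0)

def _candidate(
    p: int, a: int, n_links: int, rng: np.random.Generator
) -> np.ndarray:
    wp = _degree_weights(p, rng)
    wa = _degree_weights(a, rng)
    inc = np.zeros((p, a), dtype=bool)
    # coverage skeleton: the first P pollinators (in random order) each take
    # a distinct plant, the rest choose a plant by weight -- exactly A links,
    # every plant and every pollinator covered
    order = rng.permutation(a)
    plants_perm = rng.permutation(p)
    for idx, pol in enumerate(order):
        if idx < p:
            inc[plants_perm[idx], pol] = True
        else:
            inc[rng.choice(p, p=wp / wp.sum()), pol] = True
    extra = n_links - int(inc.sum())
    if extra > 0:
        cellw = np.outer(wp, wa)[~inc]
        free = np.flatnonzero(~inc.ravel())
        pick = rng.choice(free, size=extra, replace=False,
                          p=cellw / cellw.sum())
        inc.ravel()[pick] = True
    return inc


def generate_pollination_network(
    p: int,
    connectance_curve: Callable[[int], float] | None = None,
    nestedness_band: tuple[float, float] = (10.0, 90.0),
    rng_seed: int | np.random.Generator | None = None,
    max_attempts: int = 10_000,
) -> PollinationNetwork:
    """Generate one plant-pollinator network with ``A = 2P`` pollinators.

    The link count is ``round(C_p(S_p) * P * A)`` under the connectance
    curve; candidates are rejection-sampled until NODF lands inside
    ``nestedness_band``.  Raises before sampling if the requested link
    count cannot cover every species or exceeds the matrix size.
    """
    if p < 2:
        raise ValueError("need at least 2 plants")
    a = 2 * p
    s_p = p + a
    curve = connectance_curve or default_connectance_curve
    n_links = int(round(curve(s_p) * p * a))
    if n_links < max(p, a) or n_links > p * a:
        raise ValueError(
            f"infeasible link count {n_links} for P={p}, A={a}: "
            f"must lie in [{max(p, a)}, {p * a}]"
        )
    rng = np.random.default_rng(rng_seed)
    lo, hi = nestedness_band
    for _ in range(max_attempts):
        inc = _candidate(p, a, n_links, rng)
        if lo <= nodf(inc) <= hi:
            return PollinationNetwork(incidence=inc)
    raise GenerationError(
        f"no network with NODF in {nestedness_band} after "
        f"{max_attempts} attempts (P={p}, L_p={n_links})"
    )


def batch_generate(
    classes: Sequence[int],
    per_class: int,
    rng_seed: int | None = None,
    **kwargs,
) -> list[PollinationNetwork]:
    """Generate ``per_class`` networks for each plant count in ``classes``.

    Seeds are derived per (class, replicate) from ``rng_seed`` so any
    single network can be regenerated independently.
    """
    nets = []
    for ci, p in enumerate(classes):
        for rep in range(per_class):
            seed = np.random.SeedSequence(rng_seed, spawn_key=(ci, rep))
            try:
                nets.append(
                    generate_pollination_network(
                        p, rng_seed=np.random.default_rng(seed), **kwargs
                    )
                )
            except (ValueError, GenerationError) as err:
                raise GenerationError(
                    f"class P={p}, replicate {rep}: {err}"
                ) from err
    return nets
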