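"""Stability and function metrics at species, guild, and ecosystem levels.

Outputs mirror the study design: persistence and final diversity;
biomass, productivity and consumption totals at the end of a run; and
coefficients of variation (CV = standard deviation / mean, population
standard deviation) of biomass over the last 1000 sampled timesteps,
computed per surviving species, per guild (CV of the guild's summed
biomass), and for the whole ecosystem (CV of summed species biomass).

Productivity follows the flux definitions: plant productivity is growth
minus the vegetative cost of rewards production; rewards productivity is
production minus self-limitation; animal productivity is assimilation
minus metabolic maintenance.  Consumption is biomass assimilated divided
by assimilation efficiency (i.e. raw extraction).  Rewards pools count
toward biomass and productivity tallies as an eighth guild but never
toward diversity or persistence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import MultiplexNetwork
from .dynamics import SimulationResult

__all__ = [
    "CVSuite", "EcosystemMetrics", "STANDARD_GUILDS", "cv_suite",
    "ecosystem_metrics", "flux_accounting", "guild_members",
    "guild_metrics", "persistence",
]

#: The five-guild grouping that is comparable across all six treatments.
STANDARD_GUILDS = ("plants", "herbivores", "added", "omnivores", "carnivores")

_STANDARD_MAP = {
    "plant": "plants",
    "plant_with_pollinators": "plants",
    "herbivore": "herbivores",
    "omnivore": "omnivores",
    "carnivore": "carnivores",
    "added_herbivore": "added",
    "added_omnivore": "added",
}


def guild_members(
    mx: MultiplexNetwork, standardized: bool = False
) -> dict[str, np.ndarray]:
    """Map guild label -> member species indices.

    With ``standardized=True`` the seven labels collapse to the five
    treatment-comparable guilds (all plants, herbivores, all added
    animals, omnivores, carnivores).
    """
    out: dict[str, list[int]] = {}
    for i, g in enumerate(mx.guild):
        key = _STANDARD_MAP[g] if standardized else g
        out.setdefault(key, []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}


def persistence(result: SimulationResult) -> float:
    """Fraction of initial species above the extinction threshold at the end."""
    return float(result.survived.sum() / result.survived.size)


def _cv(series: np.ndarray) -> float:
    mean = series.mean()
    if mean == 0.0:
        return 0.0
    return float(series.std(ddof=0) / mean)


def flux_accounting(result: SimulationResult, t: float | None = None) -> pd.DataFrame:
    """Per-guild productivity and consumption rates at sampled time ``t``.

    Rows cover the seven species guilds plus ``rewards``.  ``t`` defaults
    to the final timestep and must lie on the sampled grid.
    """
    if t is None:
        t = float(result.times[-1])
    hits = np.flatnonzero(result.times == t)
    if hits.size == 0:
        raise ValueError(f"t={t} is not on the sampled time grid")
    y = result.trajectory[hits[0]]
    sys = result.system
    fx = sys.term_fluxes(y)
    productivity = (
        fx["growth"] - fx["rewards_cost"]          # plants
        + fx["assimilation"] - fx["metabolism"]    # animals
    )
    consumption = fx["extraction"]
    rows = []
    for guild, idx in guild_members(result.network).items():
        rows.append({
            "guild": guild,
            "productivity": float(productivity[idx].sum()),
            "consumption": float(consumption[idx].sum()),
        })
    rows.append({
        "guild": "rewards",
        "productivity": float(fx["rewards_net"].sum()),
        "consumption": 0.0,
    })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CVSuite:
    """Coefficients of variation over the steady-state window."""

    species: np.ndarray            # per-species CV (NaN for extinct)
    ecosystem_species_level: float  # mean CV of surviving species
    guild_level: dict              # guild -> CV of summed biomass
    ecosystem_guild_level: float   # mean over the five standardized guilds
    ecosystem_level: float         # CV of summed species biomass


def cv_suite(result: SimulationResult, window: int = 1000) -> CVSuite:
    """Species-, guild-, and ecosystem-level biomass CVs.

    The window is the last ``window`` sampled timesteps.  Species extinct
    before the window closes have no defined CV and are excluded from the
    species-level averages; standardized guilds without survivors are
    excluded from the guild-level average.
    """
    if result.times.size <= window:
        raise ValueError("trajectory shorter than the CV window")
    tail = result.biomass()[-window:]
    surv = result.survived
    species = np.full(surv.size, np.nan)
    for i in np.flatnonzero(surv):
        species[i] = _cv(tail[:, i])
    std_members = guild_members(result.network, standardized=True)
    guild_cvs: dict[str, float] = {}
    guild_avg = []
    for guild in STANDARD_GUILDS:
        idx = std_members.get(guild, np.array([], dtype=int))
        if idx.size == 0 or not surv[idx].any():
            continue
        g_cv = _cv(tail[:, idx].sum(axis=1))
        guild_cvs[guild] = g_cv
        guild_avg.append(g_cv)
    if result.system.n_pools:
        guild_cvs["rewards"] = _cv(result.rewards()[-window:].sum(axis=1))
    return CVSuite(
        species=species,
        ecosystem_species_level=float(np.nanmean(species)),
        guild_level=guild_cvs,
        ecosystem_guild_level=float(np.mean(guild_avg)),
        ecosystem_level=_cv(tail.sum(axis=1)),
    )


@dataclass(frozen=True)
class EcosystemMetrics:
    """Whole-ecosystem summary of one run."""

    initial_diversity: int
    final_diversity: int
    persistence: float
    total_biomass: float          # species + rewards at the final timestep
    total_productivity: float
    total_consumption: float
    cv_species_level: float
    cv_guild_level: float
    cv_ecosystem_level: float


def ecosystem_metrics(result: SimulationResult, window: int = 1000) -> EcosystemMetrics:
    fx = flux_accounting(result)
    cvs = cv_suite(result, window=window)
    final = result.final_state
    return EcosystemMetrics(
        initial_diversity=int(result.survived.size),
        final_diversity=int(result.survived.sum()),
        persistence=persistence(result),
        total_biomass=float(final.sum()),
        total_productivity=float(fx["productivity"].sum()),
        total_consumption=float(fx["consumption"].sum()),
        cv_species_level=cvs.ecosystem_species_level,
        cv_guild_level=cvs.ecosystem_guild_level,
        cv_ecosystem_level=cvs.ecosystem_level,
    )


def guild_metrics(result: SimulationResult, window: int = 1000) -> pd.DataFrame:
    """Tidy per-guild table: survivors, persistence, biomass, fluxes, CVs."""
    fx = flux_accounting(result).set_index("guild")
    tail = result.biomass()[-window:]
    surv = result.survived
    final_b = result.biomass()[-1]
    cvs = cv_suite(result, window=window)
    rows = []
    for guild, idx in guild_members(result.network).items():
        g_surv = surv[idx]
        sp_cvs = cvs.species[idx][g_surv]
        rows.append({
            "guild": guild,
            "n_initial": idx.size,
            "n_surviving": int(g_surv.sum()),
            "persistence": float(g_surv.mean()),
            "biomass": float(final_b[idx].sum()),
            "productivity": float(fx.loc[guild, "productivity"]),
            "consumption": float(fx.loc[guild, "consumption"]),
            "cv_species_level": float(np.mean(sp_cvs)) if sp_cvs.size else np.nan,
            "cv_guild_level": _cv(tail[:, idx].sum(axis=1))
            if g_surv.any() else np.nan,
        })
    if result.system.n_pools:
        rew_tail = result.rewards()[-window:]
        rows.append({
            "guild": "rewards",
            "n_initial": 0, "n_surviving": 0, "persistence": np.nan,
            "biomass": float(result.rewards()[-1].sum()),
            "productivity": float(fx.loc["rewards", "productivity"]),
            "consumption": 0.0,
            "cv_species_level": np.nan,
            "cv_guild_level": _cv(rew_tail.sum(axis=1)),
        })
    return pd.DataFrame(rows)
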