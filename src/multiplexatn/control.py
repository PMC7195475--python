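"""Feedback-control experiments: multiplex dynamics with mutualism severed.

A feedback control takes a completed multiplex simulation and re-runs the
same network with every plant-pollinator feedback cut: former plants with
pollinators grow as ordinary plants (no reproductive-services benefit, no
rewards-production cost, growth rate back to the baseline 0.8), while
their rewards pools are forced to produce at a fixed rate equal to the
plant's average net rewards production (mean of ``beta*B - s*R``) over
the multiplex run's last 1000 sampled timesteps.  All feeding links are
unchanged.  Comparing the two runs isolates what mutualistic feedback
adds beyond the sheer provisioning of rewards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import CompiledSystem, SimulationResult, compile_system, simulate
from .metrics import guild_members, STANDARD_GUILDS

__all__ = ["ControlSpec", "FeedbackEffect", "build_control",
           "feedback_effect", "run_control"]


@dataclass(frozen=True)
class ControlSpec:
    """Forcing terms for a feedback control, one entry per rewards pool."""

    production: np.ndarray  # fixed net rewards production rate, >= 0
    rewards_init: np.ndarray  # mean rewards stock over the window

    def __post_init__(self):
        if not np.isfinite(self.production).all():
            raise ValueError("non-finite control production rate")
        if (self.rewards_init < 0).any():
            raise ValueError("negative initial rewards stock")


def build_control(
    multiplex_result: SimulationResult,
    window: int = 1000,
) -> tuple[CompiledSystem, ControlSpec]:
    """Build the severed-feedback system matching a multiplex run.

    The fixed production rate is the time average of ``beta*B - s*R``
    over the last ``window`` sampled timesteps; negative averages (self-
    limitation exceeding production) are clipped to zero, since a
    constant negative inflow would force unphysical negative rewards.
    """
    sys = multiplex_result.system
    if sys.control_production is not None:
        raise ValueError("result is already a feedback control")
    if multiplex_result.times.size <= window:
        raise ValueError("multiplex run shorter than the averaging window")
    p = sys.params
    b_tail = multiplex_result.biomass()[-window:][:, sys.pool_plants]
    r_tail = multiplex_result.rewards()[-window:]
    net = (p.beta[sys.pool_plants] * b_tail - p.s[sys.pool_plants] * r_tail)
    production = np.maximum(net.mean(axis=0), 0.0)
    spec = ControlSpec(production=production,
                       rewards_init=r_tail.mean(axis=0))
    control_sys = compile_system(sys.network, p, control_production=production)
    return control_sys, spec


def run_control(
    multiplex_result: SimulationResult,
    t_end: float | None = None,
    **simulate_kwargs,
) -> SimulationResult:
    """Convenience wrapper: build and integrate the feedback control.

    Species restart from biomass 10; rewards pools start at their
    multiplex window-averaged stock.
    """
    control_sys, spec = build_control(multiplex_result)
    if t_end is None:
        t_end = float(multiplex_result.times[-1])
    return simulate(
        control_sys, t_end=t_end, init_rewards=spec.rewards_init,
        **simulate_kwargs,
    )


@dataclass(frozen=True)
class FeedbackEffect:
    """Multiplex-minus-control differences (positive = feedbacks help)."""

    persistence: float          # ecosystem persistence difference
    total_biomass: float        # ecosystem final-biomass difference
    table: pd.DataFrame         # per-guild fraction differences

    def guild_effect(self, guild: str, metric: str) -> float:
        row = self.table[(self.table.guild == guild)
                         & (self.table.metric == metric)]
        return float(row["effect"].iloc[0])


def feedback_effect(
    multiplex_result: SimulationResult,
    control_result: SimulationResult,
) -> FeedbackEffect:
    """Per-guild and ecosystem effects of mutualistic feedback.

    Guild effects are differences of normalised fractions -- the guild's
    share of final diversity and of final total biomass in the multiplex
    run minus the control run -- so each metric's effects sum to zero
    across guilds.  Uses the five standardized guilds.
    """
    mx_net = multiplex_result.network
    rows = []
    per_ecosystem = {}
    for label, result in (("multiplex", multiplex_result),
                          ("control", control_result)):
        surv = result.survived
        final_b = result.biomass()[-1]
        n_final = int(surv.sum())
        tot_b = float(final_b.sum())
        if n_final == 0 or tot_b <= 0:
            raise ValueError(f"{label} run has no survivors or zero biomass")
        per_ecosystem[label] = (n_final, tot_b, surv, final_b)

    members = guild_members(mx_net, standardized=True)
    for guild in STANDARD_GUILDS:
        idx = members.get(guild, np.array([], dtype=int))
        rec = {"guild": guild}
        for label in ("multiplex", "control"):
            n_final, tot_b, surv, final_b = per_ecosystem[label]
            rec[f"{label}_diversity_frac"] = surv[idx].sum() / n_final
            rec[f"{label}_biomass_frac"] = final_b[idx].sum() / tot_b
        rows.append(rec)
    table = pd.DataFrame(rows)
    tidy = []
    for metric in ("diversity_frac", "biomass_frac"):
        for _, rec in table.iterrows():
            tidy.append({
                "guild": rec["guild"], "metric": metric,
                "multiplex": rec[f"multiplex_{metric}"],
                "control": rec[f"control_{metric}"],
                "effect": rec[f"multiplex_{metric}"] - rec[f"control_{metric}"],
            })
    tidy = pd.DataFrame(tidy)

    s_mx = multiplex_result.survived.sum() / multiplex_result.survived.size
    s_ct = control_result.survived.sum() / control_result.survived.size
    db = float(multiplex_result.biomass()[-1].sum()
               - control_result.biomass()[-1].sum())
    return FeedbackEffect(
        persistence=float(s_mx - s_ct), total_biomass=db, table=tidy,
    )
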