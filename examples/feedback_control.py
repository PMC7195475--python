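"""Sever plant-pollinator feedbacks and measure what they contribute.

Runs a high-productivity rewards-only multiplex, builds its feedback
control (vegetation grows as an ordinary plant; rewards production is
forced at the multiplex steady-state rate), and prints the per-guild
effect of the feedbacks on community composition.
"""

import multiplexatn as ma
from multiplexatn.control import feedback_effect, run_control
from multiplexatn.experiment import ExperimentPlan, run_pairing

web = ma.generate_niche_web(rng_seed=2)
pnet = ma.generate_pollination_network(4, rng_seed=5)
results = run_pairing(
    web, pnet, ExperimentPlan(master_seed=0, treatments=("RO_High",)), (0, 0)
)
multiplex = results["RO_High"]
control = run_control(multiplex)
eff = feedback_effect(multiplex, control)

print(f"persistence: multiplex - control = {eff.persistence:+.3f}")
print(f"total biomass difference:         {eff.total_biomass:+.1f}\n")
print(eff.table.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))
print("\nPositive effects mean the dynamic plant-pollinator feedback "
      "(not just the extra rewards food) raises that guild's share; the "
      "fraction effects sum to zero across guilds by construction.")
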