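# multiplexatn

Consumer–resource dynamics of *multiplex* ecological networks: food webs
and plant–pollinator mutualisms integrated into one system, for studying
how mutualism affects the diversity, stability, and function of complex
ecosystems.

Classical theory treats mutualism as destabilizing, yet pollination
sustains much of terrestrial biodiversity. This package takes the
mechanistic route: instead of asserting interaction signs, it models the
*mechanisms* — pollinators eat floral rewards, plants "consume" the
reproductive services pollinators provide — and lets positive and
negative effects emerge from bioenergetic consumer–resource dynamics.
It is intended for theoretical ecologists running in-silico experiments
on network architecture and mutualism intensity.

## The model

**Structure.** Food webs come from the niche model: each of the
`S_f = 50` species gets a niche value `n_i ~ U(0,1)`, a feeding range
`r_i = x·n_i` with `x ~ Beta(1, b)`, `E[x] = 2C_f`, and a feeding centre
`c_i`; species `i` eats every `j` whose `n_j` lies in the interval of
width `r_i` centred on `c_i`. Webs are rejection-sampled to exactly 20
plants, exactly 5 strict herbivores, and connectance
`0.0976 < C_f < 0.1024`. Plant–pollinator networks have `A = 2P`
pollinators, empirically decreasing connectance `C_p(S_p)`, and NODF
nestedness inside a configurable band. Assembly maps the `P` bipartite
plants onto randomly chosen food-web plants (which gain floral-rewards
pools) and attaches the `A` pollinators, in two topologies: **RO**
(rewards only — pollinators eat nothing else) and **RP** (rewards plus —
pollinators carry perturbed niche traits of low-trophic-level consumers
and also eat vegetation and prey). Converting every rewards link to
herbivory yields structurally matched food-web controls (**RO FW**,
**RP FW**).

**Dynamics.** Consumers follow allometric trophic network (ATN) theory:

    dB_i/dt = Σ_j C_ij − x_i B_i − Σ_j C_ji / e_ji,
    C_ij = x_i y_ij B_i F_ij,
    F_ij = ω_ij X_j^h / (B0_ij^h + Σ_k ω_ik X_k^h),

with metabolic rate `x_i = 0.314 m_i^−0.25`, mass `m_i = Z_i^(swTL_i−1)`,
`h = 1.5` (weak Type III), and weak-generalist preferences
`ω_ij = 1/|diet_i|` that are never renormalised after extinctions.
Plants grow logistically against a shared carrying capacity `K = 480`.
A plant with pollinators splits into vegetation `B_i` and rewards `R_i`:

    dR_i/dt = β_i B_i − s_i R_i − Σ_pollinators C_ji(R_i),

its vegetative growth is multiplied by the saturating benefit
`P(R_i) = services/(0.05 + services)` where services sum each
pollinator's visit *quantity* (rewards consumption rate) times visit
*quality* (that consumption as a share of the pollinator's total
intake), and it pays a cost `κ_i(β_i B_i − s_i R_i)` for producing
rewards. Six treatments cross the two topologies with rewards
productivity `β` = 1.0 (High), 0.2 (Low), and 0 (FW). Simulations start
all stocks at 10, run 5000 timesteps with a stiff solver, and zero any
species crossing the extinction threshold `10⁻⁶` via event detection.

**Outputs.** Persistence, final diversity, biomass, productivity,
consumption, and coefficients of variation of biomass (last 1000
timesteps) at species, guild, and ecosystem levels, plus severed-feedback
*control* experiments that force rewards production at the multiplex
steady-state rate to isolate what dynamic feedback adds.

## Worked example

```sh
python examples/simulate_treatments.py
```

```
S = 60 species (5 plants with pollinators)

treatment  persist   biomass  product.   CV(eco)
RO_High      0.600     519.5      5.99  3.92e-05
RO_Low       0.517     504.6      3.39  2.59e-03
RO_FW        0.350     480.0      0.00  1.15e-07
RP_High      0.533     596.7     16.40  9.68e-07
RP_Low       0.500     526.2      8.77  2.72e-05
RP_FW        0.383     480.1      0.01  3.00e-05
```

One 50-species web coupled to a 15-species pollination network: the
high-rewards multiplexes keep 60% / 53% of species against 35% / 38% in
the matched food webs, hold more biomass, and produce at rates an order
of magnitude higher — rewards productivity, not network structure, makes
the difference. Ecosystem-level variability is tiny (a lone slow
transient in Low RO is visible as the largest CV). The other scripts in
`examples/` demonstrate network generation, the feedback control, and an
optional long-horizon persistence-drift check.

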