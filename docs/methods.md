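# Methods

This note documents the model as implemented, the parameter defaults,
the numerical choices, and the places where the design was genuinely
open. Nothing here states an empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Network generation

**Niche-model food webs.** Species are placed on a one-dimensional
niche axis; consumer `i` eats every species whose niche value falls in
an interval of *total width* `r_i = x·n_i` centred on `c_i`, with
`x ~ Beta(1, b)` and `b = 1/(2C_f) − 1` so `E[x] = 2C_f` yields expected
connectance `C_f`. (The interval endpoints are `c ± r/2`; the centre's
admissible range `[r/2, min(n, 1 − r/2)]` keeps the interval on the
axis.) The smallest-niche species is forced basal (`r = 0`), the
standard device guaranteeing at least one plant. Accepted webs must
have exactly 20 plants (empty diets), exactly 5 strict herbivores
(non-empty diets containing only plants, hence short-weighted trophic
level exactly 2), connectance in the open window (0.0976, 0.1024), no
isolated species (every plant has a consumer), every consumer connected
to a plant, and no two *consumers* that are trophically identical.
Cannibalistic links are legal and count toward `L_f`.

Two judgement calls here:

- The trophic-duplicate rule is restricted to consumers. Consumer sets
  are contiguous niche intervals, so with 20 plants forced, some pair
  of plants shares an identical consumer set in essentially every
  otherwise-valid web (41 of 41 in a measured sample); extending the
  rule to plants makes the joint constraints practically unattainable.
  Duplicate consumers, by contrast, occur in only ~7% of candidates and
  are rejected.
- Joint acceptance is ~2×10⁻⁶ per draw, so the sampler vectorises the
  cheap constraints over batches of 4096 candidate webs (~15 s per
  accepted web on one core) and applies the graph-level checks only to
  survivors. `max_attempts` bounds the search with a diagnostic error.

**Plant–pollinator networks.** `A = 2P` pollinators per `P` plants.
The target link count follows `C_p(S_p) = a·S_p^−b` with defaults
`a = 2.86`, `b = 0.851`. These two constants are the one genuinely
calibrated choice in the package: the generating model behind the
published connectance–diversity relation is not fully specified, so
`(a, b)` were fit such that the *assembled* rewards-only multiplex
connectance means reproduce the published anchors (≈0.091 at S = 56,
≈0.06 at S = 88), given the measured ≈5.5 predator links that each
added pollinator attracts and the ≈248 links of an average accepted
food web. Two constraints bound the curve from below: every species
needs a link (`L_p ≥ A`), and very sparse matrices cannot reach the
NODF acceptance band (see next paragraph), which is why the fitted
curve sits slightly above the algebraic optimum at high diversity and
the assembled mean at S = 88 lands near 0.068 rather than 0.060 (still
inside the stated ±0.01).

The generator draws heavy-tailed (truncated-Pareto) degree weights for
both guilds, lays a coverage skeleton (each pollinator one plant, all
plants covered, exactly `A` links), adds the remaining links by
weighted sampling without replacement, and rejects candidates whose
NODF nestedness falls outside the band [10, 90] (configurable). NODF is
the field-standard metric: the mean over all row pairs and column pairs
of the percentage overlap, counting only pairs with strictly different
marginal totals.

**Assembly.** `P` of the 20 plants, chosen uniformly, become plants
with pollinators and gain a rewards pool; bipartite links become
rewards-feeding links. RO pollinators take a niche value within ±5%
(uniform multiplicative) of a random strict herbivore's, with zero
feeding range, so food-web consumers whose intervals cover that value
prey on them while they eat rewards only. RP pollinators copy the
full niche triple of a random plant-eating consumer with swTL in
[2, 2.3], each trait independently perturbed ±5% and re-clipped to the
niche invariants; their diets and predators are then resolved from the
intervals uniformly over *all* species — including other added
pollinators — on top of the retained rewards links (a plant can be
linked twice: vegetation + rewards). The food-web controls convert
every rewards link into a (deduplicated) herbivory link on the same
plant and drop the pools, so RP FW connectance can sit slightly below
RP. Because the interval rule is applied uniformly, pollinator–
pollinator feeding adds a link component that grows with `A²`; it
lifts the RP grand-mean connectance to ≈0.109 in our populations,
somewhat above the published 0.102 — the price of keeping one
consistent linking rule rather than special-casing added species.

## Parameters

| parameter | value | meaning / unit |
|---|---|---|
| `m_i` | 1 (plants); `Z_i^(swTL_i−1)` | body mass, reference units |
| `Z_i` | lognormal, mean 10, sd 100, truncated ≥ 1 | consumer–resource size ratio |
| `x_i` | `0.314·m^−0.25` | mass-specific metabolic rate, per timestep |
| `y` | 10 | max metabolic-specific consumption |
| `e_ij` | 0.85 animal / 0.66 vegetation / 1.0 rewards | assimilation efficiency |
| `B0_ij` | 60 biomass / 30 rewards | half-saturation density |
| `h` | 1.5 | Hill exponent (weak Type III) |
| `K` | 480 | community carrying capacity (vegetation) |
| `r_i` | 0.8 without / 1.0 with pollinators | max plant growth rate |
| `β_i` | 1.0 High / 0.2 Low / 0 FW | rewards production rate |
| `s_i` | 0.4 | rewards self-limitation |
| `κ_i` | 0.1 | vegetative cost of rewards production |
| — | 0.05 | benefit half-saturation (services) |
| `ω_ij` | `1/|initial diet|` | weak-generalist preference, frozen |

`swTL` is the mean of the shortest-chain and prey-averaged trophic
levels; a rewards link contributes at the host plant's height (level 1),
so an RO pollinator sits at swTL = 2 and mass `Z`, allometrically
comparable to the strict herbivore it replaces in the FW control. The
lognormal's mean/sd parameterize the variate itself (underlying normal:
`σ² = ln(1 + (sd/mean)²)`, `μ = ln(mean) − σ²/2`); truncation at `Z ≥ 1`
keeps consumers at or above the plant reference mass. `Z` is drawn once
per species and shared across the six treatments of a pairing, so
treatment contrasts are not confounded by allometric draws. The
per-link half-saturation (30 for rewards, 60 for biomass) enters the
multi-resource functional response denominator through the per-pair
`B0_ij^h` term, the standard multi-resource generalisation. Every
scalar above is overridable through `parameterize(..., overrides=...)`
for sensitivity work. The "±5%" perturbations are uniform on
[0.95, 1.05]; a two-point or truncated-normal reading is equally
consistent with the verbal description and can be substituted.

## Dynamics and numerics

The right-hand side is evaluated with vectorised segment sums over a
flattened link table. Integration uses scipy's BDF with relative
tolerance 1e-8, absolute 1e-10, and the network's Jacobian sparsity
pattern (consumer–resource couplings, shared-denominator co-resource
couplings, the all-plants competition block, and the benefit pathway
from pollinators and their co-resources into plant growth); the solver
and tolerances are configurable. Extinctions are handled by event
detection — a single terminal event on the minimum living biomass minus
the 10⁻⁶ threshold — followed by hard zeroing and restart, which
prevents revival from sub-threshold biomass. A zeroed species has an
exactly zero derivative thereafter. When a plant with pollinators goes
extinct its rewards pool is zeroed and frozen (the limiting case of the
pool's decline, since production is proportional to the vanished
vegetation). Trajectories are sampled on the integer grid 0..5000
regardless of internal adaptive steps; all CV windows use samples
4001..5000 inclusive.

In the rewards balance the pollinator drain is divided by the
assimilation efficiency uniformly; with `e = 1.0` for rewards this is
numerically identical to omitting the division, and it keeps one
extraction rule across biomass and rewards resources.

**Feedback controls** rebuild the system from a completed multiplex
run: former plants with pollinators grow as ordinary plants (`r = 0.8`,
no benefit factor, no production cost), and each rewards pool receives
a constant inflow equal to the run's mean net production
(`βB − sR` averaged over samples 4001..5000, clipped at zero — a
constant negative inflow would drive the pool negative) minus pollinator
consumption. Species restart at biomass 10; pools start at their
window-mean stock. Controls are fully deterministic given the multiplex
run. In a control the pool is decoupled from its plant, so it is *not*
zeroed if the plant goes extinct — production is externally forced.

## Metrics

CVs use the population (1/N) standard deviation; over a 1000-sample
window the distinction from 1/(N−1) is negligible but the choice is
fixed. Species extinct before the window have no defined CV and are
excluded from species-level averages; standardized guilds with no
survivors are excluded from the guild-level average. The five
standardized guilds (all plants, herbivores, all added animals,
omnivores, carnivores) make guild-level quantities comparable across
treatments; the finer seven-guild split plus rewards-as-an-eighth-guild
appears in the per-guild tables. Rewards pools count toward biomass and
productivity tallies but never toward diversity or persistence. The
ecosystem-level CV is computed on summed *species* biomass. Plant
productivity is growth minus the rewards-production cost; rewards
productivity is production minus self-limitation; animal productivity
is assimilation minus metabolism; consumption is assimilation divided
by efficiency (raw extraction). At exact steady state total production
equals total consumption; in finite runs a rare, slowly declining
species can leave a small imbalance that is large *relative* to an
otherwise near-zero total, so the production–consumption comparison is
made on treatment-aggregated totals.

## Problem sizes

Simulation-backed checks run at desk scale by design: the shared test
batch simulates ten pairings (initial diversities 56–78, three food
webs, mixed pollination sizes) under all six treatments for 5000
timesteps; the acceptance script uses five pairings across two webs.
The 100-web generator soak test runs at a cheaper constraint
configuration (20 species, 5 plants, 2 strict herbivores, wider
connectance window) because paper-scale constrained webs cost ~15 s
each; the paper-scale constraint set is asserted on the session webs.
The full published design (102 webs × 238 pollination networks × 6
treatments) is expressible through `ExperimentPlan` but is batch-scale
compute, as is the long-horizon persistence-drift check
(`examples/long_run_drift.py`).

## What the generators do and do not emulate

Generated webs match the published structural constraints (diversity,
connectance, plant and herbivore counts) but, like all niche-model
webs, idealise real food webs: interval diets, a single trait axis, no
spatial or temporal refuges. The pollination generator reproduces a
connectance–diversity decline and a nestedness spectrum, not any
specific empirical dataset, and its connectance curve is calibrated
against assembled-network targets rather than transcribed from an
empirical fit. Passing tests therefore demonstrate internal consistency
with the modelled study design, not agreement with field data.

## Known limitations

- Slow transients: a minority of runs still drift measurably at
  t = 5000 (e.g. omnivores growing into freed plant biomass), so the
  maximum ecosystem-level CV across a sample can approach or
  occasionally exceed 10⁻³ even though typical values are 10⁻⁵–10⁻⁷.
- The RP grand-mean connectance runs ≈0.007 above the published value
  for the structural reason given above.
- No demographic or environmental stochasticity, seasonality, or
  temperature dependence; statistical post-analysis across treatments
  is out of scope.
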