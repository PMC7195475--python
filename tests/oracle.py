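"""Independent, naive reference implementations used only by tests.

Everything here is written loop-by-loop, term-by-term, straight from the
model definitions, sharing no evaluation code with the package, so that
agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np


def naive_nodf(m) -> float:
    """Brute-force NODF: explicit loops over row and column pairs."""
    m = np.asarray(m, dtype=bool)
    contributions = []
    for mat in (m, m.T):
        k = mat.shape[0]
        for i in range(k):
            for j in range(i + 1, k):
                di, dj = mat[i].sum(), mat[j].sum()
                if di == dj or min(di, dj) == 0:
                    contributions.append(0.0)
                else:
                    if di < dj:
                        small, big = mat[i], mat[j]
                    else:
                        small, big = mat[j], mat[i]
                    shared = np.logical_and(small, big).sum()
                    contributions.append(100.0 * shared / small.sum())
    return float(np.mean(contributions)) if contributions else 0.0


def naive_rhs(mx, params, y, control_production=None):
    """Term-by-term evaluation of the dynamic equations.

    ``y`` is the packed state [species biomasses, rewards pools in
    ``pool_plants`` order].  Returns the packed derivative.
    """
    consts = params.constants
    s = mx.n_species
    pool_plants = [int(i) for i in np.flatnonzero(mx.has_rewards_pool)]
    b = [max(float(v), 0.0) for v in y[:s]]
    r_pool = {pl: max(float(v), 0.0)
              for pl, v in zip(pool_plants, y[s:])}
    h = consts["hill"]
    y_max = consts["y"]

    # diet as (resource, kind) pairs; kind in {"veg", "ani", "rew"}
    diets = {}
    for i in range(s):
        entries = []
        for j in range(s):
            if mx.veg[i, j]:
                entries.append((j, "veg"))
            if mx.ani[i, j]:
                entries.append((j, "ani"))
            if mx.rew[i, j]:
                entries.append((j, "rew"))
        diets[i] = entries

    def density(j, kind):
        return r_pool[j] if kind == "rew" else b[j]

    def b0(kind):
        return consts["b0_rewards"] if kind == "rew" else consts["b0_biomass"]

    def eff(kind):
        return {"veg": consts["e_vegetation"], "ani": consts["e_animal"],
                "rew": consts["e_rewards"]}[kind]

    def functional_response(i, j, kind):
        omega = 1.0 / len(diets[i])
        denom = b0(kind) ** h
        for k, kk in diets[i]:
            denom += omega * density(k, kk) ** h
        return omega * density(j, kind) ** h / denom

    def consumption(i, j, kind):
        return params.x[i] * y_max * b[i] * functional_response(i, j, kind)

    db = [0.0] * s
    dr = {pl: 0.0 for pl in pool_plants}
    total_plant_b = sum(b[j] for j in range(s) if mx.is_plant[j])
    compet = 1.0 - total_plant_b / consts["carrying_capacity"]

    for i in range(s):
        # gains from feeding
        for j, kind in diets[i]:
            db[i] += consumption(i, j, kind)
        # metabolic loss (x is 0 for plants)
        db[i] -= params.x[i] * b[i]
        # losses to consumers (biomass links only; rewards feeding drains
        # the pool, not the plant)
        for j in range(s):
            for jj, kind in diets[j]:
                if jj == i and kind in ("veg", "ani"):
                    db[i] -= consumption(j, i, kind) / eff(kind)

    for i in range(s):
        if not mx.is_plant[i]:
            continue
        if i in pool_plants and control_production is None:
            services = 0.0
            for j in range(s):
                if not mx.rew[j, i]:
                    continue
                quantity = consumption(j, i, "rew")
                total = sum(consumption(j, k, kind) for k, kind in diets[j])
                quality = quantity / total if total > 0 else 0.0
                services += quantity * quality
            h0 = consts["benefit_half_saturation"]
            benefit = services / (h0 + services)
            db[i] += compet * params.r[i] * b[i] * benefit
            net = params.beta[i] * b[i] - params.s[i] * r_pool[i]
            db[i] -= params.kappa[i] * net
            dr[i] += net
        else:
            rate = (consts["r_plant"] if control_production is not None
                    and i in pool_plants else params.r[i])
            db[i] += compet * rate * b[i]

    if control_production is not None:
        for idx, pl in enumerate(pool_plants):
            dr[pl] += float(control_production[idx])
    for j in range(s):
        for k, kind in diets[j]:
            if kind == "rew":
                dr[k] -= consumption(j, k, kind) / eff(kind)
    return np.array(db + [dr[pl] for pl in pool_plants])


def random_small_system(rng, max_species=8, allow_pools=True):
    """A random tiny multiplex network + parameters (<= 8 species).

    Consumers only eat lower-indexed species, which guarantees every
    consumer a directed path to a plant.
    """
    from multiplexatn.assembly import MultiplexNetwork
    from multiplexatn.bioenergetics import parameterize

    s = int(rng.integers(2, max_species + 1))
    n_plants = int(rng.integers(1, s))
    veg = np.zeros((s, s), dtype=bool)
    ani = np.zeros((s, s), dtype=bool)
    rew = np.zeros((s, s), dtype=bool)
    for i in range(n_plants, s):
        k = int(rng.integers(1, i + 1))
        for j in rng.choice(i, size=k, replace=False):
            if j < n_plants:
                veg[i, j] = True
            else:
                ani[i, j] = True
    has_pool = np.zeros(s, dtype=bool)
    if allow_pools and n_plants and s > n_plants:
        for pl in range(n_plants):
            if rng.random() < 0.5:
                has_pool[pl] = True
                # at least one rewards consumer per pool half the time
                if rng.random() < 0.8:
                    j = int(rng.integers(n_plants, s))
                    rew[j, pl] = True
    guild = np.empty(s, dtype=object)
    for i in range(s):
        if i < n_plants:
            guild[i] = "plant_with_pollinators" if has_pool[i] else "plant"
        else:
            e_v, e_a = veg[i].any(), ani[i].any()
            guild[i] = ("omnivore" if e_v and e_a
                        else "herbivore" if e_v
                        else "carnivore" if e_a else "added_herbivore")
    mx = MultiplexNetwork(
        treatment="RP", n=np.sort(rng.random(s)), rng=np.zeros(s),
        c=np.zeros(s), guild=guild, veg=veg, ani=ani, rew=rew,
        has_rewards_pool=has_pool, n_foodweb_species=s,
    )
    params = parameterize(
        mx,
        rewards_productivity=float(rng.choice([0.2, 1.0])),
        z=rng.uniform(1.0, 40.0, size=s),
    )
    return mx, params
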