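"""Serialization: the JSON network schema and tabular exports.

The network schema is shared by food webs and multiplex networks::

    {"treatment": "...",
     "nodes": [{"id", "guild", "niche": {"n", "rng", "c"},
                "has_rewards_pool"}, ...],
     "links": [{"consumer", "resource", "type"}, ...]}

Link types are ``eats_vegetation``, ``eats_animal`` and ``eats_rewards``
(the latter implies the paired reproductive-service direction).  Node
order is the deterministic internal order (food-web species first).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import MultiplexNetwork
from .dynamics import SimulationResult
from .foodweb import FoodWeb, classify_guilds
from .pollination import PollinationNetwork

__all__ = [
    "foodweb_edge_list_tsv", "incidence_csv", "network_from_json",
    "network_to_json", "result_to_csv",
]

_LINK_TYPES = ("eats_vegetation", "eats_animal", "eats_rewards")


def _as_multiplex(net: FoodWeb | MultiplexNetwork) -> MultiplexNetwork:
    if isinstance(net, MultiplexNetwork):
        return net
    is_plant = net.is_plant
    return MultiplexNetwork(
        treatment="food_web",
        n=net.n, rng=net.rng, c=net.c,
        guild=classify_guilds(net),
        veg=net.adjacency & is_plant[None, :],
        ani=net.adjacency & ~is_plant[None, :],
        rew=np.zeros_like(net.adjacency),
        has_rewards_pool=np.zeros(net.n_species, dtype=bool),
        n_foodweb_species=net.n_species,
    )


def network_to_json(net: FoodWeb | MultiplexNetwork,
                    path: str | Path | None = None) -> dict:
    """Serialize a network to the JSON schema (optionally write a file)."""
    mx = _as_multiplex(net)

    def _num(v: float):
        return None if math.isnan(v) else float(v)

    doc = {
        "treatment": mx.treatment,
        "nodes": [
            {
                "id": int(i),
                "guild": str(mx.guild[i]),
                "niche": {"n": _num(mx.n[i]), "rng": _num(mx.rng[i]),
                          "c": _num(mx.c[i])},
                "has_rewards_pool": bool(mx.has_rewards_pool[i]),
            }
            for i in range(mx.n_species)
        ],
        "links": [],
        "n_foodweb_species": int(mx.n_foodweb_species),
    }
    for mat, typ in zip((mx.veg, mx.ani, mx.rew), _LINK_TYPES):
        for i, j in np.argwhere(mat):
            doc["links"].append(
                {"consumer": int(i), "resource": int(j), "type": typ}
            )
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def network_from_json(doc: dict | str | Path) -> MultiplexNetwork:
    """Inverse of :func:`network_to_json`."""
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    nodes = sorted(doc["nodes"], key=lambda d: d["id"])
    s = len(nodes)

    def _arr(key):
        return np.array(
            [np.nan if n["niche"][key] is None else n["niche"][key]
             for n in nodes]
        )

    mats = {t: np.zeros((s, s), dtype=bool) for t in _LINK_TYPES}
    for link in doc["links"]:
        mats[link["type"]][link["consumer"], link["resource"]] = True
    return MultiplexNetwork(
        treatment=doc["treatment"],
        n=_arr("n"), rng=_arr("rng"), c=_arr("c"),
        guild=np.array([n["guild"] for n in nodes], dtype=object),
        veg=mats["eats_vegetation"], ani=mats["eats_animal"],
        rew=mats["eats_rewards"],
        has_rewards_pool=np.array(
            [n["has_rewards_pool"] for n in nodes], dtype=bool
        ),
        n_foodweb_species=int(doc.get("n_foodweb_species", s)),
    )


def foodweb_edge_list_tsv(web: FoodWeb, path: str | Path) -> None:
    """Two-column TSV of (consumer_id, resource_id), 0-based."""
    pd.DataFrame(web.edge_list(), columns=["consumer_id", "resource_id"]).to_csv(
        path, sep="\t", index=False
    )


def incidence_csv(pnet: PollinationNetwork, path: str | Path) -> None:
    """Plant x pollinator incidence as CSV (plants as rows)."""
    pd.DataFrame(
        pnet.incidence.astype(int),
        index=[f"plant_{i}" for i in range(pnet.n_plants)],
        columns=[f"pollinator_{j}" for j in range(pnet.n_pollinators)],
    ).to_csv(path)


def result_to_csv(result: SimulationResult, directory: str | Path) -> None:
    """Persist a run: trajectory and extinction-event CSVs + metadata."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    sys = result.system
    cols = [f"sp_{i}" for i in range(sys.n_species)] + [
        f"rewards_{int(p)}" for p in sys.pool_plants
    ]
    df = pd.DataFrame(result.trajectory, columns=cols)
    df.insert(0, "t", result.times)
    df.to_csv(out / "trajectory.csv", index=False)
    pd.DataFrame(result.extinctions, columns=["species", "time"]).to_csv(
        out / "extinctions.csv", index=False
    )
    meta = {
        "treatment": result.network.treatment,
        "n_species": int(sys.n_species),
        "n_rewards_pools": int(sys.n_pools),
        "t_end": float(result.times[-1]),
        "constants": result.params.constants,
    }
    (out / "run.json").write_text(json.dumps(meta, indent=1))
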