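"""Shared fixtures: constrained webs and a batch of simulated treatments.

The expensive objects (paper-scale constrained food webs, a multi-pairing
six-treatment simulation batch) are session-scoped and shared across test
modules; tests only read them.
"""

from __future__ import annotations

import numpy as np
import pytest

import multiplexatn as ma
from multiplexatn.experiment import ExperimentPlan, run_pairing

#: plant counts of the simulated pairings (mixed initial diversities)
BATCH_P_VALUES = (3, 4, 5, 6, 7, 8, 9, 10, 12, 14)


@pytest.fixture(scope="session")
def webs():
    """Three constrained 50-species niche webs (paper-scale constraints)."""
    return [ma.generate_niche_web(rng_seed=s) for s in (2, 3, 10)]


@pytest.fixture(scope="session")
def web(webs):
    return webs[0]


@pytest.fixture(scope="session")
def plan():
    return ExperimentPlan(master_seed=0)


@pytest.fixture(scope="session")
def batch(webs, plan):
    """Six-treatment simulation results for ten mixed-size pairings.

    Returns a list of dicts ``{treatment: SimulationResult}``, one per
    pairing; pairings cycle over the session webs.
    """
    out = []
    for k, p in enumerate(BATCH_P_VALUES):
        pnet = ma.generate_pollination_network(p, rng_seed=1000 + k)
        out.append(run_pairing(webs[k % len(webs)], pnet, plan, (k, p)))
    return out


@pytest.fixture(scope="session")
def ro_pair(webs):
    """One assembled base + RO + RP trio reused by structural tests."""
    pnet = ma.generate_pollination_network(5, rng_seed=7)
    base = ma.integrate(webs[0], pnet, rng_seed=7)
    return {
        "pnet": pnet,
        "base": base,
        "RO": ma.attach_ro_pollinators(base, rng_seed=8),
        "RP": ma.attach_rp_pollinators(base, rng_seed=9),
    }
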