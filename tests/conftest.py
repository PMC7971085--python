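"""Shared fixtures: registry, EOS/activity models, pathway, TFA runs.

Heavy pipeline results (full condition-set TFA runs) are session-scoped so
the unit and acceptance suites share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from actipath import (
    ActivityModel,
    bundled_medium,
    default_registry,
    load_conditions,
    load_pathway,
    load_pka_table,
    run_tfa,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def model(registry):
    return ActivityModel(registry)


@pytest.fixture(scope="session")
def pathway():
    return load_pathway()


@pytest.fixture(scope="session")
def reactions(pathway):
    return {r.reaction_id: r for r in pathway}


@pytest.fixture(scope="session")
def ladders():
    return load_pka_table()


@pytest.fixture(scope="session")
def hansen_medium(registry):
    return bundled_medium("hansen_pfk", registry)


@pytest.fixture(scope="session")
def veech_medium(registry):
    return bundled_medium("veech_aldolase", registry)


@pytest.fixture(scope="session")
def conditions_a():
    return load_conditions("A")


@pytest.fixture(scope="session")
def conditions_b():
    return load_conditions("B")


@pytest.fixture(scope="session")
def tfa_a(pathway, registry, model, conditions_a):
    return run_tfa(pathway, registry.standard, conditions_a, registry, model)


@pytest.fixture(scope="session")
def tfa_b(pathway, registry, model, conditions_b):
    return run_tfa(pathway, registry.standard, conditions_b, registry, model)


@pytest.fixture(scope="session")
def tfa_b_310(pathway, registry, model, conditions_b):
    return run_tfa(
        pathway, registry.standard, conditions_b.replace(T=310.15), registry, model
    )


def random_liquid_state(eos, rng):
    """A random liquid-like (T, rho, x) state for derivative cross-checks."""
    n = len(eos.species)
    x = rng.dirichlet(np.full(n, 5.0))
    # keep water dominant and charges balanced pairwise by construction
    T = rng.uniform(280.0, 340.0)
    eta = rng.uniform(0.25, 0.50)
    tc = eos._tcache(T)
    rho = 6.0 * eta / (np.pi * float(np.sum(x * eos.m * tc["d"] ** 3)))
    return T, rho, x
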