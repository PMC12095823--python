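"""Shared fixtures: the toy community and cached reference trajectories."""

from __future__ import annotations

import logging

import pytest
from hypothesis import settings

from commscreen import SimulationConfig, generate_toy_community, simulate
from commscreen.toys import P1_EXCHANGE, P2_EXCHANGE

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

logging.getLogger("cobra").setLevel(logging.WARNING)

PRODUCTS = (P1_EXCHANGE, P2_EXCHANGE)


@pytest.fixture(scope="session")
def toy_community():
    return generate_toy_community(seed=0)


@pytest.fixture(scope="session")
def toy_models(toy_community):
    return toy_community.models


@pytest.fixture(scope="session")
def minimal_medium(toy_community):
    return toy_community.media["minimal"]


@pytest.fixture(scope="session")
def rich_medium(toy_community):
    return toy_community.media["rich"]


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def trajectories(toy_models, minimal_medium, default_config):
    """Monoculture and pair trajectories on the glucose minimal medium."""
    a, b, c = (toy_models[k] for k in ("toy_a", "toy_b", "toy_c"))
    return {
        "mono_a": simulate([a], minimal_medium, default_config,
                           products=PRODUCTS),
        "mono_b": simulate([b], minimal_medium, default_config,
                           products=PRODUCTS),
        "mono_c": simulate([c], minimal_medium, default_config,
                           products=PRODUCTS),
        "ab": simulate([a, b], minimal_medium, default_config,
                       products=PRODUCTS),
        "ac": simulate([a, c], minimal_medium, default_config,
                       products=PRODUCTS),
    }
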