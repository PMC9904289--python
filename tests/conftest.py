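"""Shared fixtures: one default synthetic world per test session."""

import pytest

from assocnet.fixtures import WorldSpec, generate_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic world, seed 1."""
    return generate_world(WorldSpec(seed=1))


@pytest.fixture(scope="session")
def ortholog_maps(world):
    return world.compute_ortholog_maps()


@pytest.fixture(scope="session")
def host_taxid(world):
    return world.roles["host"][0]


@pytest.fixture(scope="session")
def parasite_taxid(world):
    return world.roles["parasite"][0]


@pytest.fixture(scope="session")
def vector_taxid(world):
    return world.roles["vector"][0]
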