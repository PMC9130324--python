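"""Shared fixtures: tiny worked graphs and the planted-module fixture."""

from __future__ import annotations

import numpy as np
import pytest

from netprio import (
    EdgeRecord,
    NodeId,
    SeedSet,
    SyntheticSpec,
    assemble_network,
    build_transition_matrix,
    generate_multilayer_network,
)


def net_from_pairs(pairs, layer="L", node_type="unknown"):
    """Build a network from (source, target) identifier pairs."""
    records = [
        EdgeRecord(NodeId(a, node_type), NodeId(b, node_type), layer)
        for a, b in pairs
    ]
    return assemble_network(records)


def random_connected_network(rng: np.random.Generator, m: int):
    """Random connected graph: a random spanning tree plus extra edges."""
    order = rng.permutation(m)
    pairs = set()
    for i in range(1, m):
        j = int(rng.integers(0, i))
        a, b = int(order[i]), int(order[j])
        pairs.add((min(a, b), max(a, b)))
    n_extra = int(rng.integers(0, m))
    for _ in range(n_extra):
        a, b = rng.integers(0, m, size=2)
        if a != b:
            pairs.add((min(int(a), int(b)), max(int(a), int(b))))
    return net_from_pairs([(f"N{a:02d}", f"N{b:02d}") for a, b in sorted(pairs)])


@pytest.fixture
def single_edge_net():
    return net_from_pairs([("a", "b")])


@pytest.fixture
def path3_net():
    return net_from_pairs([("a", "b"), ("b", "c")])


@pytest.fixture
def star_net():
    """Hub h with leaves A (seed/held-out), B (seed), D (decoy)."""
    return net_from_pairs([("h", "A"), ("h", "B"), ("h", "D")])


@pytest.fixture(scope="session")
def planted_fixture():
    """Default planted-module fixture with its matrix and seed set."""
    fixture = generate_multilayer_network(SyntheticSpec())
    network = fixture.assemble()
    matrix = build_transition_matrix(network)
    seed_set = SeedSet.from_nodes(matrix, fixture.seeds)
    return fixture, network, matrix, seed_set
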