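from __future__ import annotations

import random

import pytest

from netcomorbid.model import GeneNetwork, Relation, Sign, TypedEdge


@pytest.fixture
def toy_triangle() -> GeneNetwork:
    """A->B up, B-C interaction, C->A down."""
    return GeneNetwork(
        "triangle",
        edges=[
            TypedEdge("A", "B", Relation.EXPRESSION_UP),
            TypedEdge("B", "C", Relation.INTERACTION, directed=False),
            TypedEdge("C", "A", Relation.EXPRESSION_DOWN),
        ],
    )


def random_simple_pairs(n_nodes: int, p: float, rng: random.Random):
    """Erdos-Renyi pair set over letter-labelled nodes."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    pairs = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                pairs.add((nodes[i], nodes[j]))
    return nodes, pairs


def random_typed_network(rng: random.Random, n_nodes: int = 10, n_edges: int = 20,
                         name: str = "rand") -> GeneNetwork:
    """Random typed multigraph for round-trip and property tests."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    relations = list(Relation)
    edges = []
    for _ in range(n_edges):
        a, b = rng.sample(nodes, 2)
        rel = rng.choice(relations)
        if rel in (Relation.INTERACTION, Relation.ASSOCIATION):
            directed = rng.random() < 0.5
            sign = Sign.NONE
        else:
            directed = True
            sign = Sign.NONE  # implied by relation where applicable
        edges.append(TypedEdge(a, b, rel, directed=directed, sign=sign))
    return GeneNetwork(name, edges=edges, nodes=nodes)
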