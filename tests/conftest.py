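"""Shared fixtures: canonical small graphs and a tiny survey config."""

import networkx as nx
import numpy as np
import pytest

from cohortnet.synthetic import (
    MultiValuedSpec,
    SurveyConfig,
    TargetSpec,
)


@pytest.fixture
def star6() -> nx.Graph:
    """A hub with 5 leaves (node 0 is the hub)."""
    return nx.star_graph(5)


@pytest.fixture
def path5() -> nx.Graph:
    return nx.path_graph(5)


@pytest.fixture
def bridge11() -> nx.Graph:
    """Two 5-cliques {0..4} and {5..9} joined through bridge node 10."""
    g = nx.Graph()
    g.add_edges_from((i, j) for i in range(5) for j in range(i + 1, 5))
    g.add_edges_from((i, j) for i in range(5, 10) for j in range(i + 1, 10))
    g.add_edge(0, 10)
    g.add_edge(5, 10)
    return g


@pytest.fixture
def two_cliques_bridge_edge() -> nx.Graph:
    """Two 4-cliques joined by a single edge 0–4."""
    g = nx.Graph()
    g.add_edges_from((i, j) for i in range(4) for j in range(i + 1, 4))
    g.add_edges_from((i, j) for i in range(4, 8) for j in range(i + 1, 8))
    g.add_edge(0, 4)
    return g


def random_connected_graph(rng: np.random.Generator, n_max: int = 12) -> nx.Graph:
    """A small connected Erdős–Rényi graph (resampled until connected)."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        p = float(rng.uniform(0.25, 0.6))
        seed = int(rng.integers(0, 2**31))
        g = nx.gnp_random_graph(n, p, seed=seed)
        if g.number_of_nodes() >= 3 and nx.is_connected(g):
            return g


@pytest.fixture
def tiny_survey_config() -> SurveyConfig:
    """120 subjects, 2 clusters, 8 binary + 2 categorical questions, 1 target."""
    profiles = np.array(
        [
            [0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1],
            [0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9],
        ]
    )
    multis = (
        MultiValuedSpec(
            "m1",
            ("a", "b", "c"),
            ((0.8, 0.1, 0.1), (0.1, 0.1, 0.8)),
        ),
        MultiValuedSpec(
            "m2",
            ("lo", "hi"),
            ((0.7, 0.3), (0.3, 0.7)),
        ),
    )
    names = tuple(f"q{i}" for i in range(8))
    return SurveyConfig(
        n_subjects=120,
        cluster_sizes=(60, 60),
        binary_features=names,
        binary_profiles=profiles,
        multivalued=multis,
        missing_rates={n: 0.05 for n in names},
        targets=(TargetSpec("flag", (0.8, 0.1)),),
        seed=7,
        skipped_rate=0.02,
    )
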