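import numpy as np
import pytest

import micronet as mn


@pytest.fixture
def small_counts() -> mn.CountMatrix:
    return mn.CountMatrix(
        ["t1", "t2", "t3"], ["s1", "s2"], np.array([[1, 2], [3, 4], [5, 6]])
    )


@pytest.fixture
def small_meta() -> mn.SampleMetadata:
    return mn.SampleMetadata.from_records(
        [
            {"sample_id": "s1", "subject_id": "r1", "timepoint": "T0",
             "liquid": "alcohol", "pretreatment": "vehicle", "route": "none"},
            {"sample_id": "s2", "subject_id": "r1", "timepoint": "T1",
             "liquid": "alcohol", "pretreatment": "OEA", "route": "oral"},
        ]
    )


@pytest.fixture(scope="session")
def band_truth() -> mn.GroundTruthNetwork:
    return mn.generate_true_network(30, "band", seed=1, bandwidth=1)


@pytest.fixture(scope="session")
def band_counts(band_truth) -> mn.CountMatrix:
    return mn.sample_counts(band_truth, 200, None, None, seed=101)


def random_network(n_nodes: int, p_edge: float, rng) -> mn.AssociationNetwork:
    """Erdos-Renyi signed network over generic node ids (test helper)."""
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                sign = 1 if rng.random() < 0.5 else -1
                edges[(nodes[i], nodes[j])] = (sign, rng.normal())
    return mn.AssociationNetwork(nodes, edges)
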