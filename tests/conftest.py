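import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20170130)


@pytest.fixture
def mixed_records():
    """Tiny annotation table with kinases, phosphatases and other proteins."""
    return pd.DataFrame(
        {
            "id": ["K1", "K2", "K3", "P1", "P2", "X1", "X2"],
            "enzyme_class": ["kinase"] * 3 + ["phosphatase"] * 2 + ["protein"] * 2,
            "subclass": ["ser_thr", "tyrosine", "ser_thr", "ser_thr",
                         "tyrosine", "ser_thr", "ser_thr"],
            "abundance": [10.0, 20.0, np.nan, 50.0, 70.0, 5.0, 8.0],
            "essential": [1.0, 1.0, 0.0, 0.0, 0.0, 1.0, 0.0],
            "de_perturbation_count": [3.0, 0.0, 5.0, 1.0, 0.0, 2.0, 4.0],
        }
    )


def random_digraph(rng, max_nodes=30):
    """A random directed graph as an edge list plus its node universe."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    p = rng.uniform(0.02, 0.4)
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return edges, nodes
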