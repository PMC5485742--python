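import sys
from pathlib import Path

import networkx as nx
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture()
def feature_frame() -> pd.DataFrame:
    """Small hand-written feature table covering all missing-value cases."""
    table = pd.DataFrame(
        {
            "protein_id": ["p1", "p2", "p3", "p4", "p5"],
            "nuclear": [True, True, False, pd.NA, True],
            "disorder_ratio": [0.2, 0.4, 0.6, float("nan"), 0.9],
            "autoact_tested": [True, True, False, False, True],
            "autoact_positive": [True, False, False, False, False],
        }
    ).set_index("protein_id")
    table["nuclear"] = table["nuclear"].astype("boolean")
    return table


@pytest.fixture()
def two_triangles() -> nx.Graph:
    g = nx.Graph()
    for tri in (("a", "b", "c"), ("x", "y", "z")):
        for i in range(3):
            g.add_edge(tri[i], tri[(i + 1) % 3], weight=1.0)
    return g


@pytest.fixture()
def barbell() -> nx.Graph:
    """Two 4-cliques joined by one bridge edge, unit weights."""
    g = nx.Graph()
    left, right = ("a", "b", "c", "d"), ("e", "f", "g", "h")
    for clique in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(clique[i], clique[j], weight=1.0)
    g.add_edge("d", "e", weight=1.0)
    return g
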