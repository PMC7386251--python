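import numpy as np
import pandas as pd
import pytest

from deepdep.network import from_edges


@pytest.fixture
def chain_net():
    """A -> B -> C."""
    return from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def toy_expr():
    """5-sample panel over four genes with exact positive/negative coupling."""
    rng = np.random.default_rng(0)
    a = rng.uniform(1, 10, 5)
    return pd.DataFrame(
        {
            f"S{i}": [a[i], a[i], 10 - a[i], rng.uniform(1, 10)]
            for i in range(5)
        },
        index=["A", "B", "C", "D"],
    )


@pytest.fixture
def random_net():
    rng = np.random.default_rng(42)
    edges = []
    for i in range(50):
        for j in range(i + 1, 50):
            if rng.random() < 0.05:
                edges.append((f"G{i:02d}", f"G{j:02d}"))
    return from_edges(edges, extra_nodes=[f"G{i:02d}" for i in range(50)])
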