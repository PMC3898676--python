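import numpy as np
import pandas as pd
import pytest

from pherocircuit.skeletons import NODE_COLUMNS, DotProps, NeuronSkeleton


def random_tree(rng: np.random.Generator, n_nodes: int = 50) -> NeuronSkeleton:
    """Random rooted tree: each node attaches to a uniformly chosen earlier node."""
    rows = [(1, -1, 0.0, 0.0, 0.0, 1.0)]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        x, y, z = rng.uniform(-50, 50, 3)
        rows.append((i, parent, float(x), float(y), float(z), float(rng.uniform(0.1, 2))))
    return NeuronSkeleton(nodes=pd.DataFrame(rows, columns=NODE_COLUMNS))


def random_dotprops(rng: np.random.Generator, n: int = 100, scale: float = 100.0) -> DotProps:
    pts = rng.uniform(0, scale, (n, 3))
    tg = rng.normal(size=(n, 3))
    tg /= np.linalg.norm(tg, axis=1)[:, None]
    return DotProps(points=pts, tangents=tg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def chain_swc_text():
    return "# test\n1 0 0 0 0 1 -1\n2 0 1 0 0 1 1\n3 0 2 0 0 1 2\n"
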