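import logging

import numpy as np
import pandas as pd
import pytest

from roqsar import dataset as ds
from roqsar import descriptors, molgraph

logging.getLogger("roqsar").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tables():
    return descriptors.default_tables()


@pytest.fixture(scope="session")
def fixture_records():
    return ds.load_fixture()


def _mol(smiles, name=""):
    return molgraph.parse_structure(smiles, name=name)


@pytest.fixture(scope="session")
def mol_factory():
    return _mol


@pytest.fixture(scope="session")
def benzene():
    return _mol("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def tba():
    return _mol("CC(C)(C)O", "tert-Butyl alcohol")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_tree(n_nodes, rng):
    """Uniform-ish random labelled tree as an element-annotated nx graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_node(0, element="C")
    for v in range(1, n_nodes):
        u = int(rng.integers(0, v))
        g.add_node(v, element="C")
        g.add_edge(u, v, order="single")
    return g


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny deterministic QsarDataset for trainer plumbing tests."""
    rng = np.random.default_rng(7)
    n = 60
    X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"),
                     index=[f"c{i}" for i in range(n)])
    y = pd.Series(50 + 10 * X["a"].to_numpy() + rng.standard_normal(n),
                  index=X.index, name="response")
    splits = pd.Series(["training"] * 40 + ["test"] * 10 + ["validation"] * 10,
                       index=X.index, name="split")
    return ds.QsarDataset(X, y, splits)
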