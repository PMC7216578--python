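import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from rdkit import Chem

import molgcn as mg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def record_from_smiles(smiles: str, cid: str = "m0") -> mg.CompoundRecord:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    return mg.CompoundRecord(id=cid, structure=mol, source_index=0)


@pytest.fixture(scope="session")
def planted_fixture():
    """The default synthetic benchmark: 200 molecules, 5% label noise."""
    return mg.generate_fixture(mg.FixtureSpec(n_molecules=200, label_noise=0.05, seed=7))


@pytest.fixture(scope="session")
def planted_split(planted_fixture):
    ds = mg.assemble_dataset(planted_fixture.records, planted_fixture.labels)
    train, test = mg.split_dataset(ds, 0.2, seed=7)
    return ds, train, test


@pytest.fixture(scope="session")
def planted_model(planted_split):
    """Default-architecture classifier fitted to the planted-rule training split."""
    _, train, _ = planted_split
    return mg.GraphConvModel(mg.default_model_spec(seed=0), train).fit(epochs=60, seed=0)


def random_normalized_graph(rng: np.random.Generator, n_max: int = 8, n_types: int = 2,
                            d: int = 5) -> mg.NormalizedGraph:
    """A random small molecule-like graph, already Kipf-normalized."""
    n = int(rng.integers(1, n_max + 1))
    types = [f"t{i}" for i in range(n_types)]
    adj = {t: np.zeros((n, n)) for t in types}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                t = types[int(rng.integers(0, n_types))]
                adj[t][i, j] = adj[t][j, i] = 1.0
    graph = mg.MolecularGraph(
        n_nodes=n, adjacency=adj,
        features=rng.normal(size=(n, d)),
        atom_symbols=["C"] * n, id="rand",
    )
    return mg.normalize_adjacency(graph)
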