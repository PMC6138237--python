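import numpy as np
import pytest

from targetfish import assign_ppp, parse_smiles
from targetfish.synthetic import generate_fixture_molecules


@pytest.fixture(scope="session")
def fixture_smiles():
    """Identifier -> SMILES for the fixed molecular fixtures."""
    return dict(generate_fixture_molecules())


@pytest.fixture(scope="session")
def typed_fixtures(fixture_smiles):
    """Identifier -> TypedMolecule for every fixture structure."""
    return {
        name: assign_ppp(parse_smiles(smi, identifier=name))
        for name, smi in fixture_smiles.items()
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


def random_connected_graph(rng, n_max=30):
    """A random connected graph as a MolecularGraph of carbons.

    Built as a random spanning tree plus a few extra edges, so every
    instance is connected and of bounded size.
    """
    from targetfish import Atom, MolecularGraph

    n = int(rng.integers(2, n_max + 1))
    edges = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.add((j, i))
    for _ in range(int(rng.integers(0, n))):
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
        edges.add((i, j))
    atoms = [Atom(element="C") for _ in range(n)]
    return MolecularGraph(
        atoms=atoms, bonds=[(i, j, 1) for i, j in sorted(edges)]
    )


def bfs_distances(graph):
    """Independent breadth-first-search all-pairs distance oracle."""
    from collections import deque

    n = graph.n_atoms
    adj = [[] for _ in range(n)]
    for i, j, _ in graph.bonds:
        adj[i].append(j)
        adj[j].append(i)
    out = np.full((n, n), np.inf)
    for src in range(n):
        out[src, src] = 0
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if np.isinf(out[src, v]):
                    out[src, v] = out[src, u] + 1
                    queue.append(v)
    return out
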