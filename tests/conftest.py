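import networkx as nx
import numpy as np
import pytest

from epu import synthetic
from epu.gene_features import OntologyDAG


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study bundle (600 genes, 60-gene module,
    half hidden, seed 42)."""
    return synthetic.generate()


@pytest.fixture(scope="session")
def small_bundle():
    """A desk-sized bundle for fast protocol tests."""
    return synthetic.generate(synthetic.SyntheticConfig(n_genes=150, n_disease=20, seed=3))


def make_dag(namespace: str, edges, nodes=()) -> OntologyDAG:
    """Build a typed DAG from (child, parent, relation) triples."""
    g = nx.DiGraph()
    for n in nodes:
        g.add_node(n)
    for child, parent, rel in edges:
        g.add_edge(child, parent, relation=rel, weight=0.8 if rel == "is_a" else 0.6)
    return OntologyDAG(namespace=namespace, graph=g)


def random_dag(seed: int, n_terms: int = 25) -> OntologyDAG:
    """Random layered DAG used by property tests."""
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    terms = [f"T{i:03d}" for i in range(n_terms)]
    g.add_node(terms[0])
    for i in range(1, n_terms):
        n_parents = 1 + (rng.random() < 0.3)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            g.add_edge(terms[i], terms[int(p)], relation=rel, weight=0.8 if rel == "is_a" else 0.6)
    return OntologyDAG(namespace="BP", graph=g)
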