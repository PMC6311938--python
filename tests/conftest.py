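import numpy as np
import pytest

from comorbnet.ontology import OntologyDag


@pytest.fixture(scope="session")
def five_node_dag() -> OntologyDag:
    """Root R with children A (leaves L1, L2) and B (leaf L3)."""
    return OntologyDag(
        [("A", "R"), ("B", "R"), ("L1", "A"), ("L2", "A"), ("L3", "B")]
    )


def random_dag_edges(rng: np.random.Generator, n_nodes: int) -> list[tuple[str, str]]:
    """Random rooted DAG: node i picks 1-2 parents among nodes < i."""
    edges = []
    for i in range(1, n_nodes):
        n_parents = 1 if (i == 1 or rng.random() < 0.7) else 2
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.append((f"N{i}", f"N{p}"))
    return edges
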