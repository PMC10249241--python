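import numpy as np
import pytest

from protfun.ontology import GoDag


@pytest.fixture
def chain_dag():
    """root <- A <- B"""
    return GoDag(
        terms=frozenset({"root", "A", "B"}),
        parents={"root": frozenset(), "A": frozenset({"root"}), "B": frozenset({"A"})},
        namespace="SYN",
        root="root",
    )


@pytest.fixture
def diamond_dag():
    """root <- A, root <- C, A <- B, C <- B"""
    return GoDag(
        terms=frozenset({"root", "A", "B", "C"}),
        parents={
            "root": frozenset(),
            "A": frozenset({"root"}),
            "C": frozenset({"root"}),
            "B": frozenset({"A", "C"}),
        },
        namespace="SYN",
        root="root",
    )


def random_dag(rng, n_terms, max_parents=3):
    """Random rooted DAG built independently of the synth module."""
    terms = [f"t{i}" for i in range(n_terms)]
    parents = {terms[0]: frozenset()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents[terms[i]] = frozenset(
            terms[j] for j in rng.choice(i, size=k, replace=False)
        )
    return GoDag(terms=frozenset(terms), parents=parents, namespace="SYN",
                 root=terms[0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
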