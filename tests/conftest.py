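import numpy as np
import pytest

from pfpwgan.annotations import AnnotationMatrix
from pfpwgan.go_dag import OntologyDag


def make_dag(parent_map, namespace="BP"):
    terms = sorted(parent_map)
    return OntologyDag(terms, {t: namespace for t in terms},
                       {t: set(ps) for t, ps in parent_map.items()})


@pytest.fixture
def chain_dag():
    """r <- a <- b."""
    return make_dag({"GO:0000001": set(),
                     "GO:0000002": {"GO:0000001"},
                     "GO:0000003": {"GO:0000002"}})


@pytest.fixture
def diamond_dag():
    """r <- a, r <- b, a <- c, b <- c."""
    return make_dag({"GO:0000001": set(),
                     "GO:0000002": {"GO:0000001"},
                     "GO:0000003": {"GO:0000001"},
                     "GO:0000004": {"GO:0000002", "GO:0000003"}})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def annotation(dag, rows):
    """rows: list of term-id sets, one per protein."""
    proteins = [f"P{i}" for i in range(len(rows))]
    values = np.zeros((len(rows), len(dag.terms)), dtype=np.int8)
    ti = {t: j for j, t in enumerate(dag.terms)}
    for i, terms in enumerate(rows):
        for t in terms:
            values[i, ti[t]] = 1
    return AnnotationMatrix(proteins, list(dag.terms), values)
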