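import numpy as np
import pytest

from minimotif.annotations import AliasTable, AnnotationSet
from minimotif.filters import FilterResources
from minimotif.ontology import OntologyGraph, TermRecord
from minimotif.synthetic import SyntheticConfig, generate_dataset


def build_graph(parent_map: dict[str, list[str]], namespace: str = "biological_process"):
    """OntologyGraph from {child: [parents]}; terms inferred from both sides."""
    terms = set(parent_map)
    for parents in parent_map.values():
        terms.update(parents)
    records = {
        t: TermRecord(
            id=t,
            namespace=namespace,
            parents=tuple((p, "is_a") for p in parent_map.get(t, ())),
        )
        for t in sorted(terms)
    }
    edges = [(c, p) for c, parents in parent_map.items() for p in parents]
    return OntologyGraph(records, edges, namespace=namespace)


@pytest.fixture(scope="session")
def toy_dag():
    """Six-term DAG: A1,A2 -> A -> R and B1 -> B -> R."""
    return build_graph({"A1": ["A"], "A2": ["A"], "A": ["R"], "B1": ["B"], "B": ["R"]})


@pytest.fixture
def toy_annotations(toy_dag):
    ann = AnnotationSet(namespace=toy_dag.namespace)
    ann.add("SRC", "A1")
    ann.add("TGT", "A2")
    ann.add("SHARED1", "A")
    ann.add("SHARED2", "A")
    return ann


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted benchmark reused across test modules."""
    config = SyntheticConfig(
        seed=7, n_terms=120, n_proteins=500, n_pos=150, n_neg=150,
        plant_probability=0.7, plant_distance=1,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def small_resources(small_dataset):
    ds = small_dataset
    return FilterResources(
        graph=ds.graph, annotations=ds.annotations,
        aliases=ds.aliases, sequences=ds.sequences,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20100819)
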