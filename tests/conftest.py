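"""Shared fixtures: tiny hand-built corpora and one session-wide planted benchmark."""

import pytest

from idmcss.ontology import Ontology, build_annotation_map, compute_ic
from idmcss.ppi_io import Network
from idmcss.synthetic import GeneratorConfig, make_fixture


@pytest.fixture(scope="session")
def planted():
    """One default planted-module benchmark, reused read-only across tests."""
    return make_fixture(GeneratorConfig(rng_seed=0))


@pytest.fixture()
def toy_ontology():
    """A 7-term, two-level DAG:

        root
        ├── a           ├── b
        │   ├── a1 a2   │   ├── b1 b2
    """
    terms = {"root", "a", "b", "a1", "a2", "b1", "b2"}
    parents = {
        "root": set(),
        "a": {"root"},
        "b": {"root"},
        "a1": {"a"},
        "a2": {"a"},
        "b1": {"b"},
        "b2": {"b"},
    }
    return Ontology(terms=terms, parents=parents)


@pytest.fixture()
def toy_corpus(toy_ontology):
    """Four annotated genes over the toy DAG, plus the derived IC.

    g1: a1       g2: a1, a2     g3: b1      g4: b2
    """
    direct = {"g1": {"a1"}, "g2": {"a1", "a2"}, "g3": {"b1"}, "g4": {"b2"}}
    annotations = build_annotation_map(direct, toy_ontology)
    return toy_ontology, annotations, compute_ic(annotations)


@pytest.fixture()
def path_network():
    """A - B - C path."""
    return Network.from_edges([("A", "B"), ("B", "C")])
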