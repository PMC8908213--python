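from __future__ import annotations

import pytest
from rdflib import Graph

from nlq2sparql.annotator import AnnotatorConfig
from nlq2sparql.fixtures import (
    FixtureSpec,
    gen_ontology,
    gen_queries,
    gen_repository,
    worked_example,
)
from nlq2sparql.graph_index import annotations_from_rgi, build_rgi, parse_annotations
from nlq2sparql.ontology_index import build_tfi


@pytest.fixture(scope="session")
def wx():
    return worked_example()


@pytest.fixture(scope="session")
def wx_pipeline(wx):
    """Parsed trees, indexes and config for the worked-example miniature."""
    trees = parse_annotations([wx.rdf_xml])
    rgi = build_rgi(trees)
    annotations, descriptions = annotations_from_rgi(rgi)
    tfi = build_tfi(wx.classes, annotations, descriptions)
    return {
        "trees": trees,
        "rgi": rgi,
        "tfi": tfi,
        "config": AnnotatorConfig(),
        "classes": wx.classes,
    }


def build_fixture(seed: int, *, n_classes: int = 25, n_entities: int = 15, **kw):
    """One fully materialized synthetic fixture: ontology, repository,
    trees, indexes and combined rdflib graph."""
    spec = FixtureSpec(seed=seed, n_classes=n_classes, n_entities=n_entities, **kw)
    classes, dictionary_text = gen_ontology(spec)
    documents, truth = gen_repository(spec, classes)
    trees = parse_annotations(documents)
    rgi = build_rgi(trees)
    annotations, descriptions = annotations_from_rgi(rgi)
    tfi = build_tfi(classes, annotations, descriptions)
    graph = Graph()
    for doc in documents:
        graph.parse(data=doc, format="xml")
    return {
        "spec": spec,
        "classes": classes,
        "dictionary_text": dictionary_text,
        "documents": documents,
        "truth": truth,
        "trees": trees,
        "rgi": rgi,
        "tfi": tfi,
        "graph": graph,
    }


@pytest.fixture(scope="session")
def synth():
    return build_fixture(seed=7)


@pytest.fixture(scope="session")
def synth_queries(synth):
    return gen_queries(synth["classes"], synth["truth"], seed=11, n_queries=12)
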