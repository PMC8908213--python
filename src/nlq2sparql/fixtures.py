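"""Synthetic ontology dictionaries, RDF-annotated model repositories and
ground-truth queries.

The generator emulates the structure of RDF-annotated CellML/SBML
repositories: each model entity is the root of a small annotation tree with
one to three ontology-class leaves (entities are rarely annotated against
more than three classes) and a free-text description literal.  Class labels
are drawn from biology-flavored vocabulary pools (chemical / anatomy /
physics) so that NER-style adapters can be faked deterministically.

``worked_example()`` ships a hand-transcribed miniature: the entity
``#K_e`` ("concentration of potassium in extracellular space") annotated
with OPB_00340, FMA_70022 and CHEBI_29103, plus dictionary entries for the
six candidate classes involved in its annotation walkthrough.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import DCTERMS

from .ontology_index import OntologyClass, normalize, read_dictionary, write_dictionary

__all__ = [
    "FixtureSpec",
    "RepositoryTruth",
    "QueryTruth",
    "WorkedExample",
    "gen_ontology",
    "gen_repository",
    "gen_queries",
    "worked_example",
]

# --- vocabulary pools -------------------------------------------------------

CHEMICAL_TERMS = (
    "potassium sodium calcium chloride glucose atp lactate pyruvate oxygen "
    "proton bicarbonate urea creatinine insulin glycogen phosphate ammonia "
    "citrate acetate magnesium"
).split()

ANATOMY_TERMS = (
    "membrane cytosol nucleus mitochondrion axon dendrite sarcomere lumen "
    "epithelium capillary ventricle atrium tubule glomerulus soma vesicle "
    "reticulum matrix compartment wall"
).split()

PHYSICS_TERMS = (
    "concentration flux current voltage pressure volume temperature rate "
    "density resistance capacitance conductance tension force velocity "
    "charge energy power amount flow"
).split()

# parallel alternatives used as synonym vocabulary (same index = synonym)
PHYSICS_SYNONYMS = (
    "molarity transport amperage potential stress capacity heat pace "
    "compactness impedance storage transmittance strain load speed valence "
    "work output quantity stream"
).split()

_PREDICATE_POOL = (
    "http://bime.uw.edu/semsim/isComputationalComponentFor",
    "http://bime.uw.edu/semsim/physicalPropertyOf",
    "http://bime.uw.edu/semsim/hasPhysicalDefinition",
    "http://www.obofoundry.org/ro/ro.owl#part_of",
    "http://bime.uw.edu/semsim/hasPhysicalEntityReference",
)

_FILLER = "measured simulated steady state baseline model variable".split()


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture; same seed, same bytes."""

    seed: int = 0
    n_classes: int = 30
    n_entities: int = 20
    classes_per_entity_weights: tuple[float, float, float] = (0.50, 0.35, 0.15)
    tree_depth_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)  # path length 1..3
    absent_feature_fraction: float = 0.3
    description_filler: tuple[int, int] = (2, 5)


@dataclass
class RepositoryTruth:
    """Generator bookkeeping mirroring what the graph index must recover."""

    entity_classes: dict[str, set[str]] = field(default_factory=dict)
    entity_description: dict[str, str] = field(default_factory=dict)
    class_paths: dict[tuple[str, str], set[tuple[str, ...]]] = field(default_factory=dict)
    n_paths: int = 0
    distinct_leaves: set[str] = field(default_factory=set)

    @property
    def n_entities(self) -> int:
        return len(self.entity_classes)

    @property
    def distinct_ontology_leaves(self) -> set[str]:
        return {c for cs in self.entity_classes.values() for c in cs}


@dataclass(frozen=True)
class QueryTruth:
    text: str
    phrases: tuple[str, ...]
    class_iris: tuple[str, ...]
    roots: frozenset[str]


def gen_ontology(spec: FixtureSpec) -> tuple[list[OntologyClass], str]:
    """Generate ``n_classes`` dictionary records; returns the parsed classes
    and the dictionary-dialect text.

    Labels are distinct two-term "subject property" phrases (e.g.
    "potassium concentration"); a configurable fraction of classes lack
    synonyms / definitions / parents, exercising the empty-feature path
    that WPL is designed to mitigate.
    """
    if spec.n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    rng = random.Random(spec.seed)
    subjects = CHEMICAL_TERMS + ANATOMY_TERMS
    pairs = [(s, i) for s in subjects for i in range(len(PHYSICS_TERMS))]
    if spec.n_classes > len(pairs):
        raise ValueError("n_classes exceeds the label space")
    chosen = rng.sample(pairs, spec.n_classes)
    records = []
    for idx, (subject, pi) in enumerate(chosen):
        pl = f"{subject} {PHYSICS_TERMS[pi]}"
        syns: list[str] = []
        dfn = ""
        pars: list[str] = []
        if rng.random() >= spec.absent_feature_fraction:
            syns = [f"{subject} {PHYSICS_SYNONYMS[pi]}"]
        if rng.random() >= spec.absent_feature_fraction:
            dfn = f"the {PHYSICS_TERMS[pi]} of {subject} in the {rng.choice(ANATOMY_TERMS)}"
        if rng.random() >= spec.absent_feature_fraction:
            pars = [f"{rng.choice(PHYSICS_TERMS)}"]
        iri = f"http://identifiers.org/synth/SYN_{idx:05d}"
        records.append((iri, "SYN", pl, syns, dfn, pars))
    text = write_dictionary(records)
    return read_dictionary(text), text


def gen_repository(
    spec: FixtureSpec, classes: Sequence[OntologyClass]
) -> tuple[list[str], RepositoryTruth]:
    """Generate one RDF/XML document per entity plus ground truth.

    Each entity tree hangs 1-3 ontology-class leaves off predicate chains of
    length 1-3 and carries one description literal built from the class
    labels plus filler terms.
    """
    rng = random.Random(spec.seed + 1)
    truth = RepositoryTruth()
    documents = []
    for i in range(spec.n_entities):
        base = f"http://models.example/synth/m{i:04d}.xml"
        root = URIRef(f"{base}#entity_{i:04d}")
        g = Graph()
        k = rng.choices((1, 2, 3), weights=spec.classes_per_entity_weights)[0]
        chosen = rng.sample(list(classes), min(k, len(classes)))
        truth.entity_classes[str(root)] = {c.iri for c in chosen}
        node_counter = 0
        for cls in chosen:
            depth = rng.choices((1, 2, 3), weights=spec.tree_depth_weights)[0]
            path = tuple(rng.choice(_PREDICATE_POOL) for _ in range(depth))
            subject = root
            for pred in path[:-1]:
                node = URIRef(f"{base}#n{i:04d}_{node_counter}")
                node_counter += 1
                g.add((subject, URIRef(pred), node))
                subject = node
            g.add((subject, URIRef(path[-1]), URIRef(cls.iri)))
            truth.class_paths.setdefault((cls.iri, str(root)), set()).add(path)
            truth.n_paths += 1
            truth.distinct_leaves.add(cls.iri)
        n_fill = rng.randint(*spec.description_filler)
        words = [t for c in chosen for t in c.preferred_label.terms]
        words += [rng.choice(_FILLER) for _ in range(n_fill)]
        description = " ".join(words)
        g.add((root, DCTERMS.description, Literal(description)))
        truth.n_paths += 1
        truth.distinct_leaves.add(description)
        truth.entity_description[str(root)] = description
        documents.append(g.serialize(format="xml"))
    return documents, truth


_CONNECTIVES = ("of", "in")


def gen_queries(
    classes: Sequence[OntologyClass],
    truth: RepositoryTruth,
    *,
    noise: float = 0.0,
    seed: int = 0,
    n_queries: int = 10,
) -> list[QueryTruth]:
    """Queries planted from entity annotations.

    Noiseless queries concatenate the preferred labels of one entity's
    classes with connective words; with ``noise`` > 0, a planted label is
    swapped for the class's synonym at that rate (classes without synonyms
    keep their label).
    """
    rng = random.Random(seed)
    by_iri = {c.iri: c for c in classes}
    roots = sorted(truth.entity_classes)
    out = []
    for _ in range(n_queries):
        root = rng.choice(roots)
        iris = sorted(truth.entity_classes[root])
        phrases = []
        for iri in iris:
            cls = by_iri[iri]
            label = " ".join(cls.preferred_label.terms)
            if cls.synonyms and rng.random() < noise:
                label = " ".join(cls.synonyms[0].terms)
            phrases.append(label)
        text = ""
        for j, phrase in enumerate(phrases):
            text += phrase if j == 0 else f" {rng.choice(_CONNECTIVES)} {phrase}"
        matching = frozenset(
            r for r, cs in truth.entity_classes.items() if set(iris) <= cs
        )
        out.append(QueryTruth(text, tuple(phrases), tuple(iris), matching))
    return out


# --- the worked example -----------------------------------------------------

SEMSIM = Namespace("http://bime.uw.edu/semsim/")
RO_PART_OF = URIRef("http://www.obofoundry.org/ro/ro.owl#part_of")

OPB_00340 = "http://identifiers.org/opb/OPB_00340"
OPB_00592 = "http://identifiers.org/opb/OPB_00592"
CHEBI_29103 = "http://identifiers.org/chebi/CHEBI_29103"
CHEBI_26216 = "http://identifiers.org/chebi/CHEBI_26216"
FMA_70022 = "http://identifiers.org/fma/FMA_70022"
FMA_17555 = "http://identifiers.org/fma/FMA_17555"

_KE_BASE = "http://models.example/ke_model.xml"
KE_ROOT = f"{_KE_BASE}#K_e"

_WORKED_RECORDS = [
    (OPB_00340, "OPB", "concentration of chemical", [], "", []),
    (OPB_00592, "OPB", "volumetric concentration", [], "", []),
    (CHEBI_29103, "CHEBI", "potassium", ["k+"], "", []),
    (CHEBI_26216, "CHEBI", "potassium molecular entity", [], "", []),
    (
        FMA_70022,
        "FMA",
        "extracellular space",
        ["intercellular space"],
        "",
        ["interstitial space"],
    ),
    (FMA_17555, "FMA", "vascular space", [], "", []),
]


@dataclass(frozen=True)
class WorkedExample:
    query: str
    dictionary_text: str
    rdf_xml: str
    ner_lexicon: dict[str, str]
    expected_phrases: tuple[str, ...]
    expected_root: str
    expected_classes: frozenset[str]

    @property
    def classes(self) -> list[OntologyClass]:
        return read_dictionary(self.dictionary_text)

    def graph(self) -> Graph:
        g = Graph()
        g.parse(data=self.rdf_xml, format="xml", publicID=_KE_BASE)
        return g


def _ke_graph() -> Graph:
    g = Graph()
    root = URIRef(KE_ROOT)
    prop = URIRef(f"{_KE_BASE}#K_e.property")
    ent = URIRef(f"{_KE_BASE}#K_e.entity")
    ent2 = URIRef(f"{_KE_BASE}#K_e.entity_2")
    g.add((root, DCTERMS.description, Literal("Concentration of potassium in extracellular space")))
    g.add((root, SEMSIM.isComputationalComponentFor, prop))
    g.add((prop, SEMSIM.hasPhysicalDefinition, URIRef(OPB_00340)))
    g.add((prop, SEMSIM.physicalPropertyOf, ent))
    g.add((ent, SEMSIM.hasPhysicalDefinition, URIRef(CHEBI_29103)))
    g.add((ent, RO_PART_OF, ent2))
    g.add((ent2, SEMSIM.hasPhysicalDefinition, URIRef(FMA_70022)))
    return g


def worked_example() -> WorkedExample:
    """The ``#K_e`` walkthrough fixture: a single annotated entity, the six
    candidate classes, the NLQ and its expected outcome."""
    return WorkedExample(
        query="concentration of potassium in extracellular space",
        dictionary_text=write_dictionary(_WORKED_RECORDS),
        rdf_xml=_ke_graph().serialize(format="xml"),
        ner_lexicon={"potassium": "SIMPLE_CHEMICAL", "extracellular space": "ANATOMY"},
        expected_phrases=("concentration", "potassium", "extracellular space"),
        expected_root=KE_ROOT,
        expected_classes=frozenset({OPB_00340, CHEBI_29103, FMA_70022}),
    )
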