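"""RDF annotation trees and the RDF Graph Index (RGI).

Model entities in biosimulation repositories are annotated compositely: the
entity is the root of a small RDF tree whose leaves are ontology-class IRIs
or text literals, connected through chains of predicates.  The RGI records,
for every ontology class, which entity roots it annotates and by which
predicate paths, so that annotation patterns can be looked up without
traversing the repository.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import rdflib
from rdflib import RDF, Graph, Literal, URIRef

from .ontology_index import TermSequence, normalize

__all__ = [
    "DEFAULT_ONTOLOGY_PREFIXES",
    "AnnotationTree",
    "PredicatePath",
    "RdfGraphIndex",
    "RdfAnnotationError",
    "parse_annotations",
    "build_rgi",
    "roots_for",
    "paths_for",
    "corpus_stats",
    "annotations_from_rgi",
    "save_rgi",
    "load_rgi",
]

#: IRI prefixes recognized as ontology-class leaves (OBO PURLs,
#: identifiers.org, BioModels-qualifier style); configurable per parse.
DEFAULT_ONTOLOGY_PREFIXES = (
    "http://purl.obolibrary.org/obo/",
    "http://identifiers.org/",
    "https://identifiers.org/",
    "urn:miriam:",
)

PredicatePath = tuple[str, ...]


class RdfAnnotationError(ValueError):
    """Malformed or cyclic annotation input."""


@dataclass
class AnnotationTree:
    """One entity's composite annotation: edges from the root entity down to
    ontology-class or literal leaves."""

    root: str
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    leaves: set[tuple[str, str, str]] = field(default_factory=set)  # (node, kind, value)

    def leaf_paths(self) -> list[tuple[str, str, PredicatePath]]:
        """(kind, value, predicate path) for every root-to-leaf path.

        Blank nodes appear only as interior nodes, so the path key is the
        predicate sequence alone.
        """
        children: dict[str, list[tuple[str, str]]] = {}
        for parent, pred, child in self.edges:
            children.setdefault(parent, []).append((pred, child))
        leaf_by_node: dict[str, list[tuple[str, str]]] = {}
        for node, kind, value in self.leaves:
            leaf_by_node.setdefault(node, []).append((kind, value))
        out: list[tuple[str, str, PredicatePath]] = []

        def walk(node: str, path: tuple[str, ...]) -> None:
            for kind, value in leaf_by_node.get(node, ()):
                if path:
                    out.append((kind, value, path))
            for pred, child in sorted(children.get(node, ())):
                walk(child, path + (pred,))

        walk(self.root, ())
        return sorted(out)


def _is_ontology_iri(iri: str, prefixes: Sequence[str]) -> bool:
    return any(iri.startswith(p) for p in prefixes)


def parse_annotations(
    rdf_documents: Iterable[str | Path],
    *,
    ontology_prefixes: Sequence[str] = DEFAULT_ONTOLOGY_PREFIXES,
    roots: Iterable[str] | None = None,
    formats: str | Sequence[str] | None = None,
) -> list[AnnotationTree]:
    """Parse RDF/XML or Turtle documents into per-entity annotation trees.

    A node is a root iff it occurs as a subject and never as an object
    (rdf:type scaffolding excluded), unless an explicit ``roots`` list is
    given.  IRI objects matching ``ontology_prefixes`` become ontology-class
    leaves; literals and unmatched terminal IRIs become literal leaves.
    """
    trees: list[AnnotationTree] = []
    explicit = set(roots) if roots is not None else None
    docs = list(rdf_documents)
    if isinstance(formats, str) or formats is None:
        formats = [formats] * len(docs)  # type: ignore[list-item]
    for doc, fmt in zip(docs, formats):
        g = Graph()
        source = str(doc)
        try:
            if isinstance(doc, Path):
                g.parse(doc, format=fmt)
                source = doc.name
            else:
                guess = fmt or ("xml" if doc.lstrip().startswith("<") else "turtle")
                g.parse(data=doc, format=guess, publicID="http://example.org/model")
                source = "<string>"
        except Exception as exc:  # rdflib raises assorted parse errors
            raise RdfAnnotationError(f"cannot parse RDF document {source}: {exc}") from exc
        trees.extend(_trees_from_graph(g, ontology_prefixes, explicit, source))
    return trees


def _trees_from_graph(
    g: Graph,
    prefixes: Sequence[str],
    explicit_roots: set[str] | None,
    source: str,
) -> list[AnnotationTree]:
    triples = [(s, p, o) for s, p, o in g if p != RDF.type]
    subjects = {s for s, _, _ in triples}
    objects = {o for _, _, o in triples if not isinstance(o, Literal)}
    if explicit_roots is not None:
        roots = [s for s in subjects if str(s) in explicit_roots]
    else:
        roots = [s for s in subjects if s not in objects and isinstance(s, URIRef)]
    out: dict[str, AnnotationTree] = {}
    children: dict[object, list[tuple[object, object]]] = {}
    for s, p, o in triples:
        children.setdefault(s, []).append((p, o))
    for root in sorted(roots, key=str):
        tree = AnnotationTree(root=str(root))
        stack: list[str] = []
        on_stack: set[object] = set()

        def walk(node: object) -> None:
            if node in on_stack:
                raise RdfAnnotationError(
                    f"cyclic annotation in {source}: cycle through node {node}"
                )
            on_stack.add(node)
            for p, o in children.get(node, ()):
                nid = _node_id(node)
                if isinstance(o, Literal):
                    # literals get a synthetic leaf node so the final
                    # predicate is part of the root-to-leaf path
                    leaf_id = f"{nid}|{p}|literal"
                    tree.edges.add((nid, str(p), leaf_id))
                    tree.leaves.add((leaf_id, "literal", str(o)))
                elif isinstance(o, URIRef) and _is_ontology_iri(str(o), prefixes):
                    tree.edges.add((nid, str(p), _node_id(o)))
                    tree.leaves.add((_node_id(o), "ontology_class", str(o)))
                elif o in children:
                    tree.edges.add((nid, str(p), _node_id(o)))
                    walk(o)
                else:
                    # terminal IRI not matching an ontology namespace
                    tree.edges.add((nid, str(p), _node_id(o)))
                    tree.leaves.add((_node_id(o), "literal", _local_name(str(o))))
            on_stack.discard(node)

        walk(root)
        out[tree.root] = tree
    return [out[k] for k in sorted(out)]


def _node_id(node: object) -> str:
    if isinstance(node, rdflib.BNode):
        return f"_:{node}"
    return str(node)


def _local_name(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            tail = iri.rsplit(sep, 1)[1]
            if tail:
                return tail
    return iri


@dataclass
class RdfGraphIndex:
    class_to_roots: dict[str, set[str]] = field(default_factory=dict)
    class_root_to_paths: dict[tuple[str, str], set[PredicatePath]] = field(default_factory=dict)
    predicate_labels: dict[str, TermSequence] = field(default_factory=dict)
    root_descriptions: dict[str, str] = field(default_factory=dict)
    # corpus bookkeeping
    n_entities: int = 0
    n_distinct_leaves: int = 0
    n_paths: int = 0
    n_distinct_ontology_leaves: int = 0


def build_rgi(trees: Iterable[AnnotationTree]) -> RdfGraphIndex:
    rgi = RdfGraphIndex()
    distinct_leaves: set[str] = set()
    distinct_onto: set[str] = set()
    for tree in trees:
        rgi.n_entities += 1
        descriptions: list[str] = []
        for kind, value, path in tree.leaf_paths():
            rgi.n_paths += 1
            distinct_leaves.add(value)
            for pred in path:
                rgi.predicate_labels.setdefault(pred, normalize(_local_name(pred)))
            if kind == "ontology_class":
                distinct_onto.add(value)
                rgi.class_to_roots.setdefault(value, set()).add(tree.root)
                rgi.class_root_to_paths.setdefault((value, tree.root), set()).add(path)
            else:
                descriptions.append(value)
        if descriptions:
            rgi.root_descriptions[tree.root] = " ".join(sorted(set(descriptions)))
    rgi.n_distinct_leaves = len(distinct_leaves)
    rgi.n_distinct_ontology_leaves = len(distinct_onto)
    return rgi


def roots_for(rgi: RdfGraphIndex, classes: Iterable[str]) -> set[str]:
    """Roots annotated with *all* the given classes."""
    classes = list(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    result: set[str] | None = None
    for c in classes:
        roots = rgi.class_to_roots.get(c, set())
        result = set(roots) if result is None else result & roots
        if not result:
            return set()
    return result or set()


def paths_for(rgi: RdfGraphIndex, class_iri: str, root: str) -> tuple[PredicatePath, ...]:
    """All stored predicate paths for (class, root), order-stable."""
    return tuple(sorted(rgi.class_root_to_paths.get((class_iri, root), ())))


def corpus_stats(rgi: RdfGraphIndex) -> tuple[int, int, int, int]:
    """(entities, distinct leaves, root-to-leaf paths, distinct ontology leaves)."""
    return (rgi.n_entities, rgi.n_distinct_leaves, rgi.n_paths, rgi.n_distinct_ontology_leaves)


def annotations_from_rgi(rgi: RdfGraphIndex) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Per-entity class sets and descriptions, as needed by the TFI build."""
    annotations: dict[str, set[str]] = {}
    for cls, roots in rgi.class_to_roots.items():
        for root in roots:
            annotations.setdefault(root, set()).add(cls)
    return annotations, dict(rgi.root_descriptions)


# --- on-disk form: versioned, content-addressed JSON -----------------------

_RGI_FORMAT_VERSION = 1


def _rgi_payload(rgi: RdfGraphIndex) -> dict:
    return {
        "version": _RGI_FORMAT_VERSION,
        "class_to_roots": {c: sorted(r) for c, r in sorted(rgi.class_to_roots.items())},
        "class_root_to_paths": [
            [c, r, sorted(list(p) for p in paths)]
            for (c, r), paths in sorted(rgi.class_root_to_paths.items())
        ],
        "predicate_labels": {p: list(t) for p, t in sorted(rgi.predicate_labels.items())},
        "root_descriptions": dict(sorted(rgi.root_descriptions.items())),
        "stats": list(corpus_stats(rgi)),
    }


def save_rgi(rgi: RdfGraphIndex, directory: str | Path) -> Path:
    """Write the RGI as ``rgi-<sha256 prefix>.json``; returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(_rgi_payload(rgi), sort_keys=True, ensure_ascii=False)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
    path = directory / f"rgi-{digest}.json"
    path.write_text(blob, encoding="utf-8")
    return path


def load_rgi(path: str | Path) -> RdfGraphIndex:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if data.get("version") != _RGI_FORMAT_VERSION:
        raise ValueError(f"unsupported RGI format version: {data.get('version')}")
    rgi = RdfGraphIndex()
    rgi.class_to_roots = {c: set(r) for c, r in data["class_to_roots"].items()}
    rgi.class_root_to_paths = {
        (c, r): {tuple(p) for p in paths} for c, r, paths in data["class_root_to_paths"]
    }
    rgi.predicate_labels = {p: tuple(t) for p, t in data["predicate_labels"].items()}
    rgi.root_descriptions = dict(data["root_descriptions"])
    (rgi.n_entities, rgi.n_distinct_leaves, rgi.n_paths, rgi.n_distinct_ontology_leaves) = data[
        "stats"
    ]
    return rgi
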