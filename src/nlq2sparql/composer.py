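"""Class-combination enumeration, annotation-pattern lookup and SPARQL
composition/ranking.

Each final phrase carries one or more candidate ontology classes.  A
*combination* picks exactly one class per phrase; a combination is viable
iff some entity root is annotated with all its classes.  For every viable
combination, the distinct choices of predicate path per class realized by
at least one root form the *annotation patterns*; each pattern compiles to
one SPARQL query.  Queries are ranked by the summed degree of association
of their classes plus a bonus for predicate evidence from NER context
phrases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from rdflib import Graph

from .annotator import Association, CandidatePhrase, PredicateAssociation
from .graph_index import PredicatePath, RdfGraphIndex, paths_for, roots_for

__all__ = [
    "ClassCombination",
    "AnnotationPattern",
    "ComposedQuery",
    "enumerate_combinations",
    "viable_combinations",
    "patterns_for",
    "compose_sparql",
    "rank_queries",
    "retrieve_entities",
    "compose_and_rank",
    "execute_sparql",
]


@dataclass(frozen=True)
class ClassCombination:
    """One (phrase, class, score) choice per final phrase."""

    items: tuple[tuple[CandidatePhrase, str, float], ...]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(iri for _, iri, _ in self.items)

    @property
    def score(self) -> float:
        return sum(s for _, _, s in self.items)


@dataclass(frozen=True)
class AnnotationPattern:
    """A viable combination together with one predicate path per class and
    the roots realizing that exact choice of paths."""

    combination: ClassCombination
    paths: tuple[PredicatePath, ...]  # aligned with combination.items
    roots: frozenset[str]


@dataclass(frozen=True)
class ComposedQuery:
    sparql: str
    score: float
    pattern: AnnotationPattern


def enumerate_combinations(
    associations_by_phrase: Mapping[CandidatePhrase, Sequence[Association]],
    cap: int | None = None,
) -> list[ClassCombination]:
    """Cartesian product of candidate classes across the final phrases.

    With a ``cap``, only the top-scoring combinations are kept (pruned
    lowest-score-first) to guard pathological fan-out.
    """
    if not associations_by_phrase:
        raise ValueError("no final phrases to combine")
    phrases = sorted(associations_by_phrase, key=lambda p: p.span)
    per_phrase = [
        [(p, a.class_iri, a.score) for a in associations_by_phrase[p]] for p in phrases
    ]
    if any(not choices for choices in per_phrase):
        raise ValueError("every final phrase must carry at least one class")
    combos = [ClassCombination(tuple(choice)) for choice in itertools.product(*per_phrase)]
    combos.sort(key=lambda c: (-c.score, c.classes))
    if cap is not None:
        combos = combos[:cap]
    return combos


def viable_combinations(
    combinations: Iterable[ClassCombination], rgi: RdfGraphIndex
) -> list[ClassCombination]:
    """Combinations whose class set annotates at least one common root."""
    return [c for c in combinations if roots_for(rgi, c.classes)]


def patterns_for(combination: ClassCombination, rgi: RdfGraphIndex) -> list[AnnotationPattern]:
    """All distinct per-class path choices realized by the combination's
    roots, each with the set of roots exhibiting exactly those paths."""
    roots = roots_for(rgi, combination.classes)
    grouped: dict[tuple[PredicatePath, ...], set[str]] = {}
    for root in sorted(roots):
        per_class = [paths_for(rgi, iri, root) for iri in combination.classes]
        if any(not p for p in per_class):
            continue
        for choice in itertools.product(*per_class):
            grouped.setdefault(choice, set()).add(root)
    return [
        AnnotationPattern(combination, choice, frozenset(grouped[choice]))
        for choice in sorted(grouped)
    ]


def compose_sparql(pattern: AnnotationPattern) -> ComposedQuery:
    """Compile one annotation pattern into a SPARQL 1.1 query.

    One triple-pattern chain per class path, fresh interior variables in
    path-major order, class leaves bound as exact IRIs; byte-stable for a
    fixed pattern.
    """
    if not pattern.combination.items:
        raise ValueError("empty pattern")
    lines = ["SELECT DISTINCT ?entity", "WHERE {"]
    v = 0
    for (_, class_iri, _), path in zip(pattern.combination.items, pattern.paths):
        subject = "?entity"
        for pred in path[:-1]:
            lines.append(f"    {subject} <{pred}> ?v{v} .")
            subject = f"?v{v}"
            v += 1
        lines.append(f"    {subject} <{path[-1]}> <{class_iri}> .")
    # entity roots are never objects; without this a pattern whose path is a
    # suffix of a longer chain would also bind interior nodes
    lines.append("    FILTER NOT EXISTS { ?anySubject ?anyPredicate ?entity . }")
    lines.append("}")
    return ComposedQuery("\n".join(lines), pattern.combination.score, pattern)


def rank_queries(
    queries: Iterable[ComposedQuery],
    predicate_associations: Sequence[PredicateAssociation] = (),
) -> list[ComposedQuery]:
    """Descending by score; a predicate association adds its score once per
    matched predicate appearing in the pattern's paths; ties break by query
    text."""
    ranked = []
    for q in queries:
        predicates = {p for path in q.pattern.paths for p in path}
        bonus = sum(pa.score for pa in predicate_associations if pa.predicate in predicates)
        ranked.append(ComposedQuery(q.sparql, q.score + bonus, q.pattern) if bonus else q)
    ranked.sort(key=lambda q: (-q.score, q.sparql))
    return ranked


def retrieve_entities(combination: ClassCombination, rgi: RdfGraphIndex) -> set[str]:
    """SPARQL-free retrieval straight from the index.

    Equals the union of results of the combination's composed queries over
    the indexed documents; it cannot see entities added to the repository
    after the last index rebuild.
    """
    return roots_for(rgi, combination.classes)


def compose_and_rank(
    associations_by_phrase: Mapping[CandidatePhrase, Sequence[Association]],
    rgi: RdfGraphIndex,
    predicate_associations: Sequence[PredicateAssociation] = (),
    cap: int | None = 64,
) -> list[ComposedQuery]:
    """End of the pipeline: enumerate, keep viable, compile, rank."""
    combos = enumerate_combinations(associations_by_phrase, cap)
    queries = [
        compose_sparql(pattern)
        for combo in viable_combinations(combos, rgi)
        for pattern in patterns_for(combo, rgi)
    ]
    return rank_queries(queries, predicate_associations)


def translate(
    query,
    tfi,
    rgi: RdfGraphIndex,
    config=None,
    adapter=None,
):
    """Full query-to-SPARQL pipeline: annotate, compose, rank.

    Returns the annotation result and the ranked composed queries.
    """
    from .annotator import AnnotatorConfig, annotate

    config = config or AnnotatorConfig()
    result = annotate(query, tfi, config, rgi=rgi, adapter=adapter)
    if not result.phrases:
        return result, []
    ranked = compose_and_rank(
        result.associations, rgi, result.predicate_associations, config.combination_cap
    )
    return result, ranked


def execute_sparql(query: ComposedQuery | str, graph: Graph) -> set[str]:
    """Run a composed query against a local rdflib graph (test/offline
    oracle and the CLI's optional local execution)."""
    text = query.sparql if isinstance(query, ComposedQuery) else query
    return {str(row[0]) for row in graph.query(text)}
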