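"""Ontology dictionaries and the Text Feature Index (TFI).

An ontology class is represented by a handful of short textual features --
preferred label, synonyms, definition, parent labels -- plus a *description*
feature aggregated from the free-text descriptions of the model entities the
class annotates.  The TFI is an inverted index from terms to
(class, feature) postings; it is used to shortlist the classes that can
possibly be associated with a query phrase before any scoring happens.

Feature terms carry *dependency levels* (``dl``): the depth of a term in the
phrase's dependency tree plus one, so the head of a noun phrase sits at
level 1 and modifiers sit deeper.  Levels for dictionary features are
produced by the same deterministic provider used for query phrases (see
:func:`heuristic_dependency_levels`).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "FUNCTION_WORDS",
    "normalize",
    "heuristic_dependency_levels",
    "FeatureRecord",
    "OntologyClass",
    "DescriptionStats",
    "TextFeatureIndex",
    "apply_wpl",
    "build_tfi",
    "candidate_classes",
    "read_dictionary",
    "write_dictionary",
    "make_feature",
    "make_class",
]

TermSequence = tuple[str, ...]

# tokens start alphanumeric; '+' and '-' survive inside/at the end so that
# chemical tokens like "k+" and "ca2+" stay intact
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:[+\-]+[a-z0-9]*)*")

#: closed-class words used by the built-in chunker / dependency heuristic
FUNCTION_WORDS = frozenset(
    "a an the of in on at by for to with within across from into and or".split()
)

FEATURE_KINDS = ("preferred_label", "synonym", "definition", "parent_label", "description")


def normalize(text: str, stop_words: Iterable[str] = ()) -> TermSequence:
    """Lowercase, strip punctuation (keeping '+'/'-' inside chemical tokens)
    and whitespace-tokenize.  Idempotent; empty text gives an empty tuple."""
    stop = frozenset(stop_words)
    return tuple(t for t in _TOKEN_RE.findall(text.lower()) if t not in stop)


def heuristic_dependency_levels(terms: Sequence[str]) -> tuple[int, ...]:
    """Deterministic dependency levels (depth + 1) for a normalized phrase.

    The phrase is split into maximal runs of content words ("chunks") at
    function words.  Within a chunk the final token is the head and earlier
    tokens attach to it one level deeper (head-final noun phrase).  The head
    of the first chunk is the root (level 1); heads of later chunks attach to
    the root (level 2); function words attach to the head of the following
    chunk (or the previous one at the end of the phrase), one level deeper.

    Examples: "concentration of potassium" -> (1, 3, 2);
    "concentration of simple chemical" -> (1, 3, 3, 2).
    """
    n = len(terms)
    if n == 0:
        return ()
    levels = [0] * n
    # chunk spans of content words
    chunks: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if terms[i] in FUNCTION_WORDS:
            i += 1
            continue
        j = i
        while j < n and terms[j] not in FUNCTION_WORDS:
            j += 1
        chunks.append((i, j))
        i = j
    if not chunks:  # all function words: chain off the first token
        return tuple(range(1, n + 1))
    head_level: dict[int, int] = {}
    for ci, (s, e) in enumerate(chunks):
        head = e - 1
        head_level[head] = 1 if ci == 0 else 2
        levels[head] = head_level[head]
        for k in range(s, e - 1):
            levels[k] = head_level[head] + 1
    # function words attach to the head of the following chunk
    for k in range(n):
        if levels[k] == 0:
            nxt = next((e - 1 for (s, e) in chunks if s > k), None)
            anchor = nxt if nxt is not None else chunks[-1][1] - 1
            levels[k] = levels[anchor] + 1
    return tuple(levels)


@dataclass(frozen=True)
class FeatureRecord:
    """One textual feature of an ontology class with per-term dependency
    levels.  ``length`` is |F|, the number of term positions (duplicates
    counted)."""

    kind: str
    terms: TermSequence
    dl: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind: {self.kind!r}")
        if not self.terms:
            raise ValueError("feature must contain at least one term")
        if len(self.terms) != len(self.dl):
            raise ValueError("dl must be defined for every term")
        if any(not t for t in self.terms):
            raise ValueError("empty token in feature")
        if any(l < 1 for l in self.dl):
            raise ValueError("dependency levels must be >= 1")

    @property
    def length(self) -> int:
        return len(self.terms)

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(self.terms)

    def term_dl(self, term: str) -> int:
        """Level of ``term`` in this feature; duplicated terms take the
        shallowest (most head-like) occurrence."""
        return min(l for t, l in zip(self.terms, self.dl) if t == term)


def make_feature(
    kind: str,
    text: str,
    *,
    stop_words: Iterable[str] = (),
    dl_provider: Callable[[Sequence[str]], tuple[int, ...]] = heuristic_dependency_levels,
) -> FeatureRecord | None:
    """Normalize ``text`` into a :class:`FeatureRecord`; ``None`` if empty."""
    terms = normalize(text, stop_words)
    if not terms:
        return None
    return FeatureRecord(kind, terms, dl_provider(terms))


@dataclass(frozen=True)
class OntologyClass:
    iri: str
    ontology_id: str
    preferred_label: FeatureRecord
    synonyms: tuple[FeatureRecord, ...] = ()
    definition: FeatureRecord | None = None
    parent_labels: tuple[FeatureRecord, ...] = ()

    def features(self) -> Iterable[FeatureRecord]:
        yield self.preferred_label
        yield from self.synonyms
        if self.definition is not None:
            yield self.definition
        yield from self.parent_labels

    def records_of(self, kind: str) -> tuple[FeatureRecord, ...]:
        if kind == "preferred_label":
            return (self.preferred_label,)
        if kind == "synonym":
            return self.synonyms
        if kind == "definition":
            return (self.definition,) if self.definition is not None else ()
        if kind == "parent_label":
            return self.parent_labels
        raise ValueError(f"no dictionary feature of kind {kind!r}")


def make_class(
    iri: str,
    ontology_id: str,
    preferred_label: str,
    synonyms: Sequence[str] = (),
    definition: str = "",
    parent_labels: Sequence[str] = (),
    *,
    stop_words: Iterable[str] = (),
) -> OntologyClass:
    pl = make_feature("preferred_label", preferred_label, stop_words=stop_words)
    if pl is None:
        raise ValueError(f"class {iri} has an empty preferred label")
    syn = tuple(
        f for s in synonyms if (f := make_feature("synonym", s, stop_words=stop_words))
    )
    dfn = make_feature("definition", definition, stop_words=stop_words)
    par = tuple(
        f for p in parent_labels if (f := make_feature("parent_label", p, stop_words=stop_words))
    )
    return OntologyClass(iri, ontology_id, pl, syn, dfn, par)


@dataclass
class DescriptionStats:
    """Terms from descriptions of entities annotated with a class.

    ``te_a`` is the total number of description terms appearing with the
    class (with multiplicity); ``te_o`` the number of annotated entities.
    """

    class_iri: str
    term_multiset: Counter = field(default_factory=Counter)
    te_o: int = 0

    @property
    def te_a(self) -> int:
        return sum(self.term_multiset.values())

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(self.term_multiset)


Posting = tuple[str, str, int, int]  # (class_iri, feature kind, dl_tf, |F|)


@dataclass
class TextFeatureIndex:
    postings: dict[str, set[Posting]] = field(default_factory=dict)
    class_store: dict[str, OntologyClass] = field(default_factory=dict)
    desc_store: dict[str, DescriptionStats] = field(default_factory=dict)

    def _post(self, term: str, posting: Posting) -> None:
        self.postings.setdefault(term, set()).add(posting)


def apply_wpl(cls: OntologyClass, enabled: bool = True) -> OntologyClass:
    """Distribute the preferred label into the other features (WPL).

    Every non-preferred dictionary feature becomes the concatenation of the
    preferred-label terms and its own terms, with |F| and dependency levels
    recomputed on the concatenation; absent features become a copy of the
    preferred label.  Applied exactly once at index-build time.
    """
    if not enabled:
        return cls
    pl = cls.preferred_label

    def extend(rec: FeatureRecord) -> FeatureRecord:
        terms = pl.terms + rec.terms
        return FeatureRecord(rec.kind, terms, heuristic_dependency_levels(terms))

    def copy_pl(kind: str) -> FeatureRecord:
        return FeatureRecord(kind, pl.terms, pl.dl)

    synonyms = tuple(extend(r) for r in cls.synonyms) or (copy_pl("synonym"),)
    definition = extend(cls.definition) if cls.definition is not None else copy_pl("definition")
    parents = tuple(extend(r) for r in cls.parent_labels) or (copy_pl("parent_label"),)
    return replace(cls, synonyms=synonyms, definition=definition, parent_labels=parents)


def build_tfi(
    classes: Iterable[OntologyClass],
    entity_annotations: Mapping[str, Iterable[str]] | None = None,
    entity_descriptions: Mapping[str, str] | None = None,
    *,
    wpl: bool = True,
    stop_words: Iterable[str] = (),
) -> TextFeatureIndex:
    """Build the inverted index over class features and description stats.

    ``entity_annotations`` maps entity IRIs to the class IRIs annotating
    them; ``entity_descriptions`` maps entity IRIs to free text.  The
    description is a sharing feature: every class annotating an entity
    receives that entity's description terms.
    """
    tfi = TextFeatureIndex()
    for cls in classes:
        if cls.iri in tfi.class_store:
            raise ValueError(f"duplicate class IRI: {cls.iri}")
        cls = apply_wpl(cls, wpl)
        tfi.class_store[cls.iri] = cls
        for rec in cls.features():
            for term in rec.term_set:
                tfi._post(term, (cls.iri, rec.kind, rec.term_dl(term), rec.length))

    annotations = entity_annotations or {}
    descriptions = entity_descriptions or {}
    for entity, class_iris in annotations.items():
        terms = normalize(descriptions.get(entity, ""), stop_words)
        for iri in class_iris:
            stats = tfi.desc_store.setdefault(iri, DescriptionStats(iri))
            stats.te_o += 1
            stats.term_multiset.update(terms)
    for iri, stats in tfi.desc_store.items():
        flen = len(stats.term_set)
        for term in stats.term_set:
            tfi._post(term, (iri, "description", 1, flen))
    return tfi


def candidate_classes(tfi: TextFeatureIndex, phrase: Sequence[str]) -> set[str]:
    """Classes having at least one indexed feature sharing a term with
    ``phrase``."""
    if not phrase:
        raise ValueError("phrase must be non-empty")
    found: set[str] = set()
    for term in set(phrase):
        for iri, _kind, _dl, _flen in tfi.postings.get(term, ()):
            found.add(iri)
    return found


# ---------------------------------------------------------------------------
# dictionary file dialect: one record per line, tab-separated:
#   iri <TAB> ontology_id <TAB> preferred label <TAB> syn|syn <TAB> definition
#   <TAB> parent|parent
# ---------------------------------------------------------------------------

def write_dictionary(classes: Iterable[tuple[str, str, str, Sequence[str], str, Sequence[str]]]) -> str:
    """Serialize raw records (iri, ontology, pl, synonyms, definition,
    parents) to the dictionary dialect."""
    lines = []
    for iri, ont, pl, syns, dfn, pars in classes:
        lines.append("\t".join([iri, ont, pl, "|".join(syns), dfn, "|".join(pars)]))
    return "\n".join(lines) + "\n"


def read_dictionary(text: str, *, stop_words: Iterable[str] = ()) -> list[OntologyClass]:
    classes = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"dictionary line {lineno}: expected 6 tab-separated fields")
        iri, ont, pl, syns, dfn, pars = parts
        classes.append(
            make_class(
                iri,
                ont,
                pl,
                [s for s in syns.split("|") if s],
                dfn,
                [p for p in pars.split("|") if p],
                stop_words=stop_words,
            )
        )
    return classes
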