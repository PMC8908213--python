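"""Phrase chunking and degree-of-association scoring.

A natural-language query (NLQ) is chunked into candidate phrases; each
phrase is scored against the ontology classes shortlisted by the TFI with a
weighted sum of per-feature similarities (the *degree of association* S);
low-scoring associations are filtered by a threshold; finally a
non-overlapping set of phrases covering the query is selected.

Similarity model, for a phrase P and a feature F (set semantics on terms,
|P| and |F| counting term positions):

* coverage:        S = |P ∩ F| / |F|
* length-normed:   S = Σ_{t∈P∩F} 1 / (|F| + ln(max(1, |P|-|F|)))
  (reduces to coverage whenever |P| <= |F|)
* dependency:      S = Σ_{t∈P∩F} ln(max(k1, |F|+k1-max(dl_tp, dl_tf)))
                       / ((1 + ln(max(1,|P|-|F|))/|F|) · ln((|F|+k2)!))
  where dl is the dependency level (tree depth + 1) of the term, so terms
  closer to the phrase head contribute more.
* description:     S = Σ_{t∈P∩D} (1+ln(1+te_o))
                       / ((1+ln|P|) · (1+ln(1+te_a)))
  where te_a is the total number of description terms appearing with the
  class and te_o the number of entities it annotates.

The degree of association is
S = α·S(P,pl) + β·S(P,syn) + γ·S(P,def) + δ·S(P,par) + θ·S_desc(P,desc).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Protocol, Sequence

import yaml

from .graph_index import RdfGraphIndex
from .ontology_index import (
    FUNCTION_WORDS,
    DescriptionStats,
    FeatureRecord,
    OntologyClass,
    TermSequence,
    TextFeatureIndex,
    candidate_classes,
    heuristic_dependency_levels,
    normalize,
)

__all__ = [
    "AnnotatorConfig",
    "NLQuery",
    "CandidatePhrase",
    "Association",
    "PredicateAssociation",
    "AnnotationResult",
    "ParserAdapter",
    "HeuristicParser",
    "DictionaryNerParser",
    "chunk_parse",
    "chunk_ner",
    "dependency_levels",
    "sim_coverage",
    "sim_length_norm",
    "sim_dependency",
    "sim_description",
    "degree_of_association",
    "annotate",
    "select_final_phrases",
]


@dataclass(frozen=True)
class AnnotatorConfig:
    """Scoring weights and switches.

    alpha..theta weight the preferred-label, synonym, definition,
    parent-label and description similarities; k1/k2 shape the
    dependency-level contribution; tau is the association filtering
    threshold; wpl distributes the preferred label into the other features
    at index-build time; dep switches between the dependency-level and the
    length-normalized similarity.
    """

    alpha: float = 3.0
    beta: float = 3.0
    gamma: float = 0.0
    delta: float = 0.0
    theta: float = 0.38
    k1: int = 2
    k2: int = 1
    tau: float = 0.5
    wpl: bool = True
    dep: bool = True
    parser: str = "builtin"
    stop_words: tuple[str, ...] = ()
    teo_in_numerator: bool = True
    combination_cap: int = 64

    def __post_init__(self) -> None:
        if self.k1 < 2:
            raise ValueError("k1 must be >= 2")
        if self.k2 < 1:
            raise ValueError("k2 must be >= 1")
        for name in ("alpha", "beta", "gamma", "delta", "theta", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_file(cls, path) -> "AnnotatorConfig":
        data = yaml.safe_load(open(path, encoding="utf-8")) or {}
        if "stop_words" in data:
            data["stop_words"] = tuple(data["stop_words"])
        return cls(**data)


@dataclass(frozen=True)
class NLQuery:
    raw: str
    terms: TermSequence

    @classmethod
    def from_text(cls, text: str, stop_words: Iterable[str] = ()) -> "NLQuery":
        terms = normalize(text, stop_words)
        if not terms:
            raise ValueError("empty query")
        return cls(text, terms)


@dataclass(frozen=True)
class CandidatePhrase:
    """A span of the query (0-based half-open token offsets) with per-term
    dependency levels.  ``ner_context`` phrases substitute an entity-type
    label for the original span text, so their terms may differ from the
    query tokens they cover."""

    span: tuple[int, int]
    terms: TermSequence
    dl_tp: tuple[int, ...]
    source: str = "parse"  # parse | ner | ner_context
    entity_type: str | None = None

    def __post_init__(self) -> None:
        if self.span[0] >= self.span[1]:
            raise ValueError("span must be non-empty")
        if len(self.terms) != len(self.dl_tp) or any(l < 1 for l in self.dl_tp):
            raise ValueError("dl_tp must be >= 1 for every term")

    @property
    def text(self) -> str:
        return " ".join(self.terms)

    def overlaps(self, other: "CandidatePhrase") -> bool:
        return self.span[0] < other.span[1] and other.span[0] < self.span[1]


@dataclass(frozen=True)
class Association:
    phrase: CandidatePhrase
    class_iri: str
    score: float
    contributions: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class PredicateAssociation:
    phrase: CandidatePhrase
    predicate: str
    score: float


class ParserAdapter(Protocol):
    """Pluggable NLP backend: constituency spans, dependency levels and
    (optionally) NER spans for a normalized token sequence.  Must be
    deterministic for a fixed input."""

    def constituents(self, terms: Sequence[str]) -> list[tuple[int, int]]: ...

    def dependency_levels(self, terms: Sequence[str]) -> tuple[int, ...]: ...

    def ner_spans(self, terms: Sequence[str]) -> list[tuple[int, int, str]]: ...


class HeuristicParser:
    """Deterministic built-in chunker with no external dependency.

    Candidate spans are: the full query; every cumulative prefix ending at a
    content-chunk boundary (left-branching PP attachment); every maximal
    content-word chunk (base noun phrase); and every chunk head (final
    token).  For "concentration of potassium in extracellular space" this
    yields exactly the six phrases a constituency parser produces.
    """

    def _chunks(self, terms: Sequence[str]) -> list[tuple[int, int]]:
        chunks, i = [], 0
        while i < len(terms):
            if terms[i] in FUNCTION_WORDS:
                i += 1
                continue
            j = i
            while j < len(terms) and terms[j] not in FUNCTION_WORDS:
                j += 1
            chunks.append((i, j))
            i = j
        return chunks

    def constituents(self, terms: Sequence[str]) -> list[tuple[int, int]]:
        n = len(terms)
        spans: set[tuple[int, int]] = {(0, n)}
        for s, e in self._chunks(terms):
            spans.add((0, e))  # cumulative prefix constituent
            spans.add((s, e))  # base noun phrase
            spans.add((e - 1, e))  # head noun
        return sorted(spans)

    def dependency_levels(self, terms: Sequence[str]) -> tuple[int, ...]:
        return heuristic_dependency_levels(terms)

    def ner_spans(self, terms: Sequence[str]) -> list[tuple[int, int, str]]:
        return []


class DictionaryNerParser(HeuristicParser):
    """NER faked from a lexicon mapping phrase text to an entity type, for
    deterministic tests of the NER/context path (greedy longest match)."""

    def __init__(self, lexicon: Mapping[str, str]):
        self.lexicon = {tuple(normalize(k)): v for k, v in lexicon.items()}
        self._max_len = max((len(k) for k in self.lexicon), default=0)

    def ner_spans(self, terms: Sequence[str]) -> list[tuple[int, int, str]]:
        spans: list[tuple[int, int, str]] = []
        i = 0
        while i < len(terms):
            hit = None
            for l in range(min(self._max_len, len(terms) - i), 0, -1):
                key = tuple(terms[i : i + l])
                if key in self.lexicon:
                    hit = (i, i + l, self.lexicon[key])
                    break
            if hit:
                spans.append(hit)
                i = hit[1]
            else:
                i += 1
        return spans


def chunk_parse(query: NLQuery, adapter: ParserAdapter) -> list[CandidatePhrase]:
    """All candidate phrases from the constituency chunking (full query,
    noun phrases, noun heads), duplicates merged, sorted by span."""
    try:
        spans = set(adapter.constituents(query.terms))
    except Exception as exc:
        raise RuntimeError(f"parser adapter {type(adapter).__name__} failed: {exc}") from exc
    spans.add((0, len(query.terms)))
    out = []
    for s, e in sorted(spans):
        terms = query.terms[s:e]
        out.append(CandidatePhrase((s, e), terms, adapter.dependency_levels(terms)))
    return out


def chunk_ner(
    query: NLQuery,
    adapter: ParserAdapter,
    parse_candidates: Sequence[CandidatePhrase] | None = None,
) -> tuple[list[CandidatePhrase], list[CandidatePhrase]]:
    """NER candidate phrases and their context phrases.

    Each NER span yields one candidate carrying its entity type.  Its
    context phrase replaces the span with the entity-type label inside the
    smallest enclosing parse constituent; whether a context phrase acts as
    an extra class phrase or as predicate evidence is decided during
    :func:`annotate` by comparing class vs predicate association.
    """
    if parse_candidates is None:
        parse_candidates = chunk_parse(query, adapter)
    ner: list[CandidatePhrase] = []
    contexts: list[CandidatePhrase] = []
    for s, e, etype in adapter.ner_spans(query.terms):
        terms = query.terms[s:e]
        ner.append(
            CandidatePhrase((s, e), terms, adapter.dependency_levels(terms), "ner", etype)
        )
        enclosing = [
            c
            for c in parse_candidates
            if c.span[0] <= s and e <= c.span[1] and c.span != (s, e)
        ]
        if not enclosing:
            continue
        host = min(enclosing, key=lambda c: (c.span[1] - c.span[0], c.span))
        ctx_terms = (
            query.terms[host.span[0] : s]
            + normalize(etype)
            + query.terms[e : host.span[1]]
        )
        contexts.append(
            CandidatePhrase(
                host.span, ctx_terms, adapter.dependency_levels(ctx_terms), "ner_context", etype
            )
        )
    return ner, contexts


def dependency_levels(terms: Sequence[str], adapter: ParserAdapter) -> tuple[int, ...]:
    """Per-term dependency level (node depth + 1) of a phrase."""
    if not terms:
        raise ValueError("phrase must be non-empty")
    return adapter.dependency_levels(terms)


# --- similarity measures ----------------------------------------------------


def _check_feature(f_len: int) -> None:
    if f_len < 1:
        raise ValueError("feature must contain at least one term")


def sim_coverage(p_terms: Sequence[str], feature: FeatureRecord) -> float:
    """Overlap normalized by feature length."""
    _check_feature(feature.length)
    return len(set(p_terms) & feature.term_set) / feature.length


def _length_penalty(p_len: int, f_len: int) -> float:
    return math.log(max(1, p_len - f_len))


def sim_length_norm(p_terms: Sequence[str], feature: FeatureRecord) -> float:
    """Coverage with a damped penalty for phrases longer than the feature."""
    _check_feature(feature.length)
    overlap = set(p_terms) & feature.term_set
    return len(overlap) / (feature.length + _length_penalty(len(p_terms), feature.length))


def sim_dependency(
    p_terms: Sequence[str],
    feature: FeatureRecord,
    dl_tp: Mapping[str, int],
    k1: int = 2,
    k2: int = 1,
) -> float:
    """Length-normalized similarity weighted by dependency levels: terms
    nearer the phrase/feature head (lower level) contribute more; the
    contribution floors at ln(k1) so deep terms still count."""
    _check_feature(feature.length)
    if k1 < 2 or k2 < 1:
        raise ValueError("k1 >= 2 and k2 >= 1 required")
    f_len = feature.length
    denom = (1.0 + _length_penalty(len(p_terms), f_len) / f_len) * math.lgamma(f_len + k2 + 1)
    total = 0.0
    for t in set(p_terms) & feature.term_set:
        dl = max(dl_tp.get(t, 1), feature.term_dl(t))
        total += math.log(max(k1, f_len + k1 - dl))
    return total / denom


def sim_description(
    p_terms: Sequence[str],
    stats: DescriptionStats | None,
    *,
    teo_in_numerator: bool = True,
) -> float:
    """Similarity against the aggregated entity-description feature,
    rewarding classes that annotate many entities (te_o) and damping very
    verbose description vocabularies (te_a)."""
    if stats is None or stats.te_a == 0:
        return 0.0
    overlap = set(p_terms) & stats.term_set
    if not overlap:
        return 0.0
    p_norm = 1.0 + math.log(len(p_terms))
    tea_norm = 1.0 + math.log(1 + stats.te_a)
    teo_term = 1.0 + math.log(1 + stats.te_o)
    if teo_in_numerator:
        per_term = teo_term / (p_norm * tea_norm)
    else:
        per_term = 1.0 / (p_norm * tea_norm * teo_term)
    return len(overlap) * per_term


_WEIGHTED_KINDS = (
    ("preferred_label", "alpha"),
    ("synonym", "beta"),
    ("definition", "gamma"),
    ("parent_label", "delta"),
)


def degree_of_association(
    phrase: CandidatePhrase,
    cls: OntologyClass,
    desc_stats: DescriptionStats | None,
    config: AnnotatorConfig,
) -> Association:
    """Weighted sum of per-feature similarities (degree of association S).

    Multi-record features (synonyms, parents) score each record separately
    and keep the maximum, so a class is rewarded for match quality rather
    than synonym count.
    """
    dl_tp = {t: l for t, l in zip(phrase.terms, phrase.dl_tp)}
    for t, l in zip(phrase.terms, phrase.dl_tp):
        dl_tp[t] = min(dl_tp[t], l)

    def feature_sim(rec: FeatureRecord) -> float:
        if config.dep:
            return sim_dependency(phrase.terms, rec, dl_tp, config.k1, config.k2)
        return sim_length_norm(phrase.terms, rec)

    contributions = []
    score = 0.0
    for kind, weight_name in _WEIGHTED_KINDS:
        weight = getattr(config, weight_name)
        records = cls.records_of(kind)
        sim = max((feature_sim(r) for r in records), default=0.0) if weight > 0 else 0.0
        contributions.append((kind, weight * sim))
        score += weight * sim
    desc_sim = (
        sim_description(phrase.terms, desc_stats, teo_in_numerator=config.teo_in_numerator)
        if config.theta > 0
        else 0.0
    )
    contributions.append(("description", config.theta * desc_sim))
    score += config.theta * desc_sim
    return Association(phrase, cls.iri, score, tuple(contributions))


# --- phrase selection and the full annotation pass -------------------------


def select_final_phrases(
    associations_by_phrase: Mapping[CandidatePhrase, Sequence[Association]],
) -> list[CandidatePhrase]:
    """Select a pairwise non-overlapping phrase set maximizing, in order:
    summed best association score, query tokens covered, fewer phrases.
    Ties break by earliest span start.  Only phrases with at least one
    surviving association participate."""
    cands = [
        (p, max(a.score for a in assocs))
        for p, assocs in associations_by_phrase.items()
        if assocs
    ]
    if not cands:
        return []
    # weighted interval scheduling over token spans, lexicographic objective
    cands.sort(key=lambda pa: (pa[0].span[1], pa[0].span[0], pa[0].source, pa[0].terms))
    n = len(cands)
    # states: (score, covered, -count), then earliest-start span tuple
    State = tuple[tuple[float, int, int], tuple[tuple[int, int], ...], list[CandidatePhrase]]
    empty: State = ((0.0, 0, 0), (), [])
    best: list[State] = [empty] * (n + 1)
    for i in range(1, n + 1):
        phrase, score = cands[i - 1]
        skip = best[i - 1]
        # last state whose phrases all end at or before this start
        j = i - 1
        while j > 0 and cands[j - 1][0].span[1] > phrase.span[0]:
            j -= 1
        prev_key, prev_spans, prev_sel = best[j]
        take_key = (
            prev_key[0] + score,
            prev_key[1] + (phrase.span[1] - phrase.span[0]),
            prev_key[2] - 1,
        )
        take: State = (take_key, prev_spans + (phrase.span,), prev_sel + [phrase])
        if take[0] > skip[0] or (take[0] == skip[0] and take[1] < skip[1]):
            best[i] = take
        else:
            best[i] = skip
    return sorted(best[n][2], key=lambda p: p.span)


@dataclass
class AnnotationResult:
    query: NLQuery
    phrases: list[CandidatePhrase]
    associations: dict[CandidatePhrase, list[Association]]
    predicate_associations: list[PredicateAssociation] = field(default_factory=list)

    def flat(self) -> list[Association]:
        return [a for p in self.phrases for a in self.associations[p]]

    def top_class(self, phrase: CandidatePhrase) -> str:
        return self.associations[phrase][0].class_iri


def _score_phrase(
    phrase: CandidatePhrase, tfi: TextFeatureIndex, config: AnnotatorConfig
) -> list[Association]:
    out = []
    for iri in candidate_classes(tfi, phrase.terms):
        cls = tfi.class_store.get(iri)
        if cls is None:
            continue
        assoc = degree_of_association(phrase, cls, tfi.desc_store.get(iri), config)
        if assoc.score >= config.tau and assoc.score > 0:
            out.append(assoc)
    out.sort(key=lambda a: (-a.score, a.class_iri))
    return out


def _predicate_associations(
    phrase: CandidatePhrase, rgi: RdfGraphIndex | None
) -> list[PredicateAssociation]:
    if rgi is None:
        return []
    out = []
    for pred, terms in rgi.predicate_labels.items():
        if not terms:
            continue
        rec = FeatureRecord("description", terms, (1,) * len(terms))
        score = sim_length_norm(phrase.terms, rec)
        if score > 0:
            out.append(PredicateAssociation(phrase, pred, score))
    out.sort(key=lambda a: (-a.score, a.predicate))
    return out


def annotate(
    query: str | NLQuery,
    tfi: TextFeatureIndex,
    config: AnnotatorConfig | None = None,
    *,
    rgi: RdfGraphIndex | None = None,
    adapter: ParserAdapter | None = None,
) -> AnnotationResult:
    """Full annotation pass: chunk, score against TFI-shortlisted classes,
    filter by tau, and select the final non-overlapping phrase set.

    With an NER-capable adapter, context phrases whose best class
    association beats their best predicate association join the candidate
    pool; the others contribute :class:`PredicateAssociation` evidence used
    later for SPARQL ranking.
    """
    config = config or AnnotatorConfig()
    adapter = adapter or HeuristicParser()
    if isinstance(query, str):
        query = NLQuery.from_text(query, config.stop_words)
    candidates = chunk_parse(query, adapter)
    ner_phrases, context_phrases = chunk_ner(query, adapter, candidates)
    seen = {c.span for c in candidates}
    candidates.extend(c for c in ner_phrases if c.span not in seen)

    scored: dict[CandidatePhrase, list[Association]] = {}
    for phrase in candidates:
        assocs = _score_phrase(phrase, tfi, config)
        if assocs:
            scored[phrase] = assocs

    predicate_assocs: list[PredicateAssociation] = []
    for ctx in context_phrases:
        class_assocs = _score_phrase(ctx, tfi, config)
        pred_assocs = _predicate_associations(ctx, rgi)
        best_class = class_assocs[0].score if class_assocs else 0.0
        best_pred = pred_assocs[0].score if pred_assocs else 0.0
        if class_assocs and best_class >= best_pred:
            scored[ctx] = class_assocs
        elif pred_assocs:
            predicate_assocs.append(pred_assocs[0])

    final = select_final_phrases(scored)
    return AnnotationResult(
        query, final, {p: scored[p] for p in final}, predicate_assocs
    )
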