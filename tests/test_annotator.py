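import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlq2sparql.annotator import (
    AnnotatorConfig,
    CandidatePhrase,
    DictionaryNerParser,
    HeuristicParser,
    NLQuery,
    annotate,
    chunk_ner,
    chunk_parse,
    degree_of_association,
    dependency_levels,
    select_final_phrases,
    sim_coverage,
    sim_dependency,
    sim_description,
    sim_length_norm,
)
from nlq2sparql.fixtures import gen_queries
from nlq2sparql.ontology_index import DescriptionStats, FeatureRecord, make_class

from conftest import build_fixture

ADAPTER = HeuristicParser()
EXAMPLE_QUERY = "concentration of potassium in extracellular space"


def _feature(text, dl=None, kind="preferred_label"):
    terms = tuple(text.split())
    if dl is None:
        dl = ADAPTER.dependency_levels(terms)
    return FeatureRecord(kind, terms, tuple(dl))


class TestChunking:
    def test_example_query_produces_six_phrases(self):
        query = NLQuery.from_text(EXAMPLE_QUERY)
        texts = {c.text for c in chunk_parse(query, ADAPTER)}
        assert texts == {
            "concentration of potassium in extracellular space",
            "concentration of potassium",
            "concentration",
            "potassium",
            "extracellular space",
            "space",
        }

    def test_single_token_query(self):
        query = NLQuery.from_text("potassium")
        assert [c.text for c in chunk_parse(query, ADAPTER)] == ["potassium"]

    @pytest.mark.parametrize(
        "text", ["flux of potassium", "apical plasma membrane", "glucose transporter in the cell membrane"]
    )
    def test_spans_within_bounds_and_unique(self, text):
        query = NLQuery.from_text(text)
        phrases = chunk_parse(query, ADAPTER)
        spans = [c.span for c in phrases]
        assert len(set(spans)) == len(spans)
        for s, e in spans:
            assert 0 <= s < e <= len(query.terms)
        for c in phrases:
            assert c.terms == query.terms[c.span[0] : c.span[1]]


class TestNerChunking:
    def test_context_phrase_substitutes_entity_type(self):
        query = NLQuery.from_text(EXAMPLE_QUERY)
        adapter = DictionaryNerParser(
            {"potassium": "SIMPLE_CHEMICAL", "extracellular space": "ANATOMY"}
        )
        ner, contexts = chunk_ner(query, adapter)
        assert {c.text for c in ner} == {"potassium", "extracellular space"}
        assert {c.entity_type for c in ner} == {"SIMPLE_CHEMICAL", "ANATOMY"}
        ctx_texts = {c.text for c in contexts}
        assert "concentration of simple chemical" in ctx_texts

    def test_no_spans_no_result(self):
        query = NLQuery.from_text(EXAMPLE_QUERY)
        ner, contexts = chunk_ner(query, ADAPTER)
        assert ner == [] and contexts == []


class TestDependencyLevels:
    @pytest.mark.parametrize(
        "phrase,expected",
        [
            ("concentration of potassium", (1, 3, 2)),
            ("concentration of simple chemical", (1, 3, 3, 2)),
            ("potassium", (1,)),
        ],
    )
    def test_depth_plus_one(self, phrase, expected):
        terms = tuple(phrase.split())
        assert dependency_levels(terms, ADAPTER) == expected

    @pytest.mark.parametrize(
        "phrase", ["flux of potassium in the cell", "basolateral plasma membrane", "rate"]
    )
    def test_single_root_at_level_one(self, phrase):
        levels = dependency_levels(tuple(phrase.split()), ADAPTER)
        assert all(l >= 1 for l in levels)
        assert levels.count(1) == 1


class TestSimCoverage:
    def test_full_overlap(self):
        f = _feature("extracellular space")
        assert sim_coverage(("extracellular", "space"), f) == 1.0

    def test_long_phrase_same_as_short(self):
        """A six-term phrase containing the feature scores the same as the
        exact phrase: the motivation for length normalization."""
        f = _feature("extracellular space")
        cp1 = tuple(EXAMPLE_QUERY.split())
        assert sim_coverage(cp1, f) == sim_coverage(("extracellular", "space"), f)

    def test_disjoint(self):
        assert sim_coverage(("ribosome",), _feature("extracellular space")) == 0.0

    def test_empty_feature_rejected(self):
        with pytest.raises(ValueError):
            FeatureRecord("synonym", (), ())


class TestSimLengthNorm:
    def test_reduces_to_coverage_for_short_phrases(self):
        f = _feature("extracellular space")
        p = ("extracellular", "space")
        assert sim_length_norm(p, f) == pytest.approx(sim_coverage(p, f), abs=1e-12)

    def test_hand_value(self):
        f = _feature("extracellular space")
        cp1 = tuple(EXAMPLE_QUERY.split())
        assert sim_length_norm(cp1, f) == pytest.approx(2 / (2 + math.log(4)), abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(min_value=1, max_value=4), st.integers(min_value=0, max_value=8))
    def test_reduction_property(self, f_len, extra):
        """Length-normalized similarity equals coverage whenever the phrase
        is no longer than the feature."""
        vocab = [f"w{i}" for i in range(12)]
        f = _feature(" ".join(vocab[:f_len]))
        p_len = max(1, f_len - extra) if extra % 2 == 0 else f_len
        p = tuple(vocab[:p_len])
        if len(p) <= f.length:
            assert sim_length_norm(p, f) == pytest.approx(sim_coverage(p, f), abs=1e-12)

    def test_strictly_decreasing_beyond_feature_length(self):
        f = _feature("extracellular space")
        filler = [f"x{i}" for i in range(8)]
        scores = [
            sim_length_norm(("extracellular", "space", *filler[:n]), f) for n in range(6)
        ]
        assert scores[0] == pytest.approx(scores[1])  # |P| = |F|+1 still exempt
        for a, b in zip(scores[1:], scores[2:]):
            assert b < a


class TestSimDependency:
    def test_unit_case(self):
        f = _feature("potassium", dl=[1])
        assert sim_dependency(("potassium",), f, {"potassium": 1}) == pytest.approx(1.0, abs=1e-9)

    def test_lower_level_contributes_more(self):
        f = _feature("extracellular space", dl=[2, 1])
        # overlap on "space" only; at max dl 1 vs max dl 2
        high = sim_dependency(("space",), _feature("a space", dl=[2, 1]), {"space": 1})
        low = sim_dependency(("space",), _feature("a space", dl=[2, 1]), {"space": 2})
        assert high == pytest.approx(math.log(3) / math.log(6), abs=1e-9)
        assert low == pytest.approx(math.log(2) / math.log(6), abs=1e-9)
        assert low < high

    def test_disjoint_zero(self):
        assert sim_dependency(("ribosome",), _feature("space"), {"ribosome": 1}) == 0.0

    def test_monotone_non_increasing_in_dl(self):
        f = _feature("basolateral plasma membrane")
        scores = [
            sim_dependency(("membrane",), f, {"membrane": dl}) for dl in range(1, 8)
        ]
        for a, b in zip(scores, scores[1:]):
            assert b <= a + 1e-12
        # floors at ln(k1) once |F|+k1-dl <= k1
        assert scores[-1] == pytest.approx(scores[3], abs=1e-12)

    def test_invalid_k(self):
        f = _feature("space")
        with pytest.raises(ValueError):
            sim_dependency(("space",), f, {"space": 1}, k1=1)


class TestSimDescription:
    def test_no_overlap(self):
        stats = DescriptionStats("c", {"potassium": 2}, te_o=1)
        assert sim_description(("ribosome",), stats) == 0.0

    def test_hand_value(self):
        stats = DescriptionStats("c", {"potassium": 3, "channel": 1, "model": 1}, te_o=1)
        expected = (1 + math.log(2)) / ((1 + math.log(2)) * (1 + math.log(6)))
        assert sim_description(("potassium", "flux"), stats) == pytest.approx(expected, abs=1e-9)

    def test_increases_with_entity_count(self):
        low = DescriptionStats("c", {"potassium": 5}, te_o=1)
        high = DescriptionStats("c", {"potassium": 5}, te_o=2)
        p = ("potassium", "flux")
        assert sim_description(p, high) > sim_description(p, low)

    def test_alternative_reading_flag(self):
        stats = DescriptionStats("c", {"potassium": 5}, te_o=3)
        p = ("potassium",)
        assert sim_description(p, stats, teo_in_numerator=False) < sim_description(p, stats)


class TestDegreeOfAssociation:
    def _phrase(self, text):
        terms = tuple(text.split())
        return CandidatePhrase((0, len(terms)), terms, ADAPTER.dependency_levels(terms))

    def test_zero_weights_zero_score(self):
        cls = make_class("c", "FMA", "extracellular space")
        cfg = AnnotatorConfig(alpha=0, beta=0, gamma=0, delta=0, theta=0, tau=0)
        assoc = degree_of_association(self._phrase("extracellular space"), cls, None, cfg)
        assert assoc.score == 0.0

    def test_alpha_only_reduces_to_preferred_label(self):
        cls = make_class("c", "FMA", "extracellular space", synonyms=["intercellular space"])
        cfg = AnnotatorConfig(alpha=1, beta=0, theta=0, dep=False)
        p = self._phrase("extracellular space")
        assoc = degree_of_association(p, cls, None, cfg)
        assert assoc.score == pytest.approx(sim_length_norm(p.terms, cls.preferred_label))

    def test_default_config_matches_hand_computed_sum(self):
        """Independent hand evaluation: pl 'extracellular space' scores 1.0
        under the dependency similarity ((ln2+ln3)/ln6); the WPL synonym
        [extracellular space intercellular space] scores (ln4+ln5)/ln120;
        weights alpha=beta=3, gamma=delta=0, theta=0.38 with the
        description term giving (1+ln2)/((1+ln2)(1+ln7)) per shared term."""
        from nlq2sparql.ontology_index import apply_wpl

        cls = apply_wpl(
            make_class(
                "c",
                "FMA",
                "extracellular space",
                synonyms=["intercellular space"],
                parent_labels=["interstitial space"],
            )
        )
        stats = DescriptionStats(
            "c",
            {t: 1 for t in "concentration of potassium in extracellular space".split()},
            te_o=1,
        )
        p = self._phrase("extracellular space")
        expected_pl = (math.log(2) + math.log(3)) / math.log(6)
        expected_syn = (math.log(4) + math.log(5)) / math.log(120)
        expected_desc = 2 * (1 + math.log(2)) / ((1 + math.log(2)) * (1 + math.log(7)))
        expected = 3.0 * expected_pl + 3.0 * expected_syn + 0.38 * expected_desc
        assoc = degree_of_association(p, cls, stats, AnnotatorConfig())
        assert assoc.score == pytest.approx(expected, abs=1e-9)

    def test_multiple_synonyms_take_maximum(self):
        cls = make_class(
            "c", "CHEBI", "potassium", synonyms=["k+", "potassium ion"]
        )
        cfg = AnnotatorConfig(alpha=0, beta=1, theta=0, wpl=False, dep=False, tau=0)
        p = self._phrase("potassium ion")
        assoc = degree_of_association(p, cls, None, cfg)
        best = max(sim_length_norm(p.terms, rec) for rec in cls.synonyms)
        assert assoc.score == pytest.approx(best)

    def test_scores_finite_and_non_negative(self, synth):
        tfi = synth["tfi"]
        cfg = AnnotatorConfig(tau=0)
        p = self._phrase("potassium concentration of the membrane")
        for cls in list(tfi.class_store.values())[:20]:
            a = degree_of_association(p, cls, tfi.desc_store.get(cls.iri), cfg)
            assert a.score >= 0 and math.isfinite(a.score)


def _brute_force_selection(scored):
    """Oracle: enumerate every non-overlapping subset and maximize
    (summed best score, tokens covered, fewer phrases)."""
    items = list(scored.items())
    best_key = None
    for r in range(len(items) + 1):
        for combo in itertools.combinations(items, r):
            phrases = [p for p, _ in combo]
            if any(a.overlaps(b) for a, b in itertools.combinations(phrases, 2)):
                continue
            score = sum(max(x.score for x in assocs) for _, assocs in combo)
            covered = len({i for p in phrases for i in range(*p.span)})
            key = (score, covered, -len(phrases))
            if best_key is None or key > best_key:
                best_key = key
    return best_key


class _FakeAssoc:
    def __init__(self, score):
        self.score = score


class TestSelectFinalPhrases:
    def test_single_candidate_covering_all(self):
        p = CandidatePhrase((0, 3), ("a1", "b1", "c1"), (1, 2, 2))
        assert select_final_phrases({p: [_FakeAssoc(1.0)]}) == [p]

    def test_empty(self):
        assert select_final_phrases({}) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        import random

        rng = random.Random(seed)
        n_tokens = rng.randint(3, 8)
        scored = {}
        for _ in range(rng.randint(1, 10)):
            s = rng.randrange(n_tokens)
            e = rng.randint(s + 1, n_tokens)
            terms = tuple(f"t{i}" for i in range(s, e))
            p = CandidatePhrase((s, e), terms, (1,) * (e - s))
            if p not in scored:
                scored[p] = [_FakeAssoc(round(rng.uniform(0.1, 5.0), 3))]
        selected = select_final_phrases(scored)
        assert all(
            not a.overlaps(b) for a, b in itertools.combinations(selected, 2)
        )
        score = sum(max(x.score for x in scored[p]) for p in selected)
        covered = len({i for p in selected for i in range(*p.span)})
        key = (score, covered, -len(selected))
        expected = _brute_force_selection(scored)
        assert key[0] == pytest.approx(expected[0], abs=1e-9)
        assert key[1:] == expected[1:]


class TestAnnotate:
    def test_worked_example_selection(self, wx, wx_pipeline):
        result = annotate(wx.query, wx_pipeline["tfi"], rgi=wx_pipeline["rgi"])
        assert tuple(p.text for p in result.phrases) == wx.expected_phrases
        # each selected phrase carries its two candidate classes
        by_text = {
            p.text: {a.class_iri.rsplit("/", 1)[1] for a in result.associations[p]}
            for p in result.phrases
        }
        assert by_text == {
            "concentration": {"OPB_00340", "OPB_00592"},
            "potassium": {"CHEBI_29103", "CHEBI_26216"},
            "extracellular space": {"FMA_70022", "FMA_17555"},
        }
        # every expected class is some phrase's candidate
        flat = {a.class_iri for p in result.phrases for a in result.associations[p]}
        assert wx.expected_classes <= flat

    def test_every_final_phrase_has_association(self, wx, wx_pipeline):
        result = annotate(wx.query, wx_pipeline["tfi"])
        assert all(result.associations[p] for p in result.phrases)

    def test_threshold_above_max_empties_result(self, wx, wx_pipeline):
        cfg = AnnotatorConfig(tau=1e6)
        result = annotate(wx.query, wx_pipeline["tfi"], cfg)
        assert result.phrases == []

    def test_threshold_monotonicity(self, wx, wx_pipeline):
        """Raising tau never adds associations."""
        tfi = wx_pipeline["tfi"]
        previous = None
        for tau in (0.0, 0.5, 1.5, 3.0, 5.0):
            result = annotate(wx.query, tfi, AnnotatorConfig(tau=tau))
            current = {(a.phrase.span, a.class_iri) for p in result.phrases for a in result.associations[p]}
            if previous is not None:
                assert current <= previous
            previous = current

    def test_empty_query_rejected(self, wx_pipeline):
        with pytest.raises(ValueError):
            annotate("", wx_pipeline["tfi"])

    def test_recovery_on_noiseless_queries(self, synth, synth_queries):
        """Queries that are verbatim planted preferred labels recover the
        planted classes with precision = recall = 1."""
        for q in synth_queries:
            result = annotate(q.text, synth["tfi"])
            predicted = {result.top_class(p) for p in result.phrases}
            assert predicted == set(q.class_iris), q.text

    def test_recovery_under_synonym_noise(self, synth):
        """Synonym-swapped queries still recover the planted classes via
        the synonym feature."""
        noisy = gen_queries(synth["classes"], synth["truth"], noise=1.0, seed=13, n_queries=8)
        for q in noisy:
            result = annotate(q.text, synth["tfi"])
            predicted = {result.top_class(p) for p in result.phrases}
            assert predicted == set(q.class_iris), q.text

    def test_ner_context_adds_class_phrase(self, wx, wx_pipeline):
        adapter = DictionaryNerParser(wx.ner_lexicon)
        result = annotate(
            wx.query, wx_pipeline["tfi"], rgi=wx_pipeline["rgi"], adapter=adapter
        )
        # context "concentration of simple chemical" associates with the
        # concentration classes more strongly than with any predicate
        assert tuple(p.text for p in result.phrases) == wx.expected_phrases
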