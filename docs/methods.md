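# Methods

## Problem and model

The package grounds free-text queries in the composite RDF annotations of
biosimulation-model entities. An entity is the root of an annotation tree;
leaves are ontology-class IRIs or text literals; interior nodes (possibly
blank) are linked by predicates. Translation proceeds in the order the
modules are laid out: `ontology_index` (TFI) → `annotator` (scoring and
phrase selection) → `graph_index` (RGI) → `composer` (SPARQL generation
and ranking), with `fixtures` supplying deterministic synthetic data and
`evaluation` the metrics.

### Degree of association

A candidate phrase P is scored against an ontology class as a weighted sum
of per-feature similarities over preferred label, synonyms, definition,
parent labels and the aggregated entity-description feature, with
multipliers α, β, γ, δ, θ. Set semantics are used for term overlap; |P|
and |F| count term positions. Three similarity variants are implemented:

* plain coverage |P∩F|/|F|;
* length-normalized coverage, penalizing phrases longer than the feature
  by ln(max(1, |P|−|F|)) in the denominator — so a short exact match
  outranks a long phrase containing the feature, while the damped log
  keeps the penalty from overwhelming the score;
* the dependency-level similarity (the default), which additionally
  weights each overlapping term by ln(max(k1, |F|+k1−max(dl_tp, dl_tf)))
  and normalizes by ln((|F|+k2)!). Dependency level dl = node depth in the
  phrase's dependency tree + 1; the max over phrase and feature sides is
  used, so a term counts as peripheral if it is peripheral on either side.
  k1 ≥ 2 floors the contribution of deep terms; k2 ≥ 1 tempers the
  factorial normalizer.

The description feature is scored separately: each overlapping term
contributes (1+ln(1+te_o)) / ((1+ln|P|)(1+ln(1+te_a))), where te_o is the
number of entities the class annotates and te_a the total number of
description terms seen with it. The te_o factor sits in the numerator
(classes used more often are more trustworthy); a config flag
(`teo_in_numerator=False`) exposes the alternative reading in which it
joins the normalizer.

Multi-record features (several synonyms or parents) score each record
separately and keep the maximum, so classes are rewarded for match
quality, not for synonym count.

### WPL (preferred-label distribution)

Many dictionary records lack synonyms, definitions or parents; an empty
feature contributes nothing and systematically deflates S for
sparsely-described classes. With `wpl=True` (default) the preferred-label
terms are prepended to every other feature at index-build time, and absent
features become copies of the preferred label; |F| and dependency levels
are recomputed on the concatenation. WPL is applied exactly once, at build
time, and is intentionally not idempotent.

### Chunking and dependency levels

The parser interface (`ParserAdapter`) asks for constituency spans,
per-term dependency levels and optional NER spans, so CoreNLP-, Benepar-
or Stanza-backed adapters can be plugged in. The built-in deterministic
fallback:

* splits the normalized query into maximal content-word chunks at a fixed
  closed-class word list;
* emits as candidates the full query, every cumulative prefix ending at a
  chunk boundary (left-branching PP attachment), every chunk, and every
  chunk head — which reproduces the canonical six-phrase chunking of
  "concentration of potassium in extracellular space";
* assigns dependency levels head-finally within a chunk, with modifiers
  attached flat to the head (all at head level + 1), the first chunk head
  as root (level 1), later chunk heads at level 2, and function words one
  below the head of the following chunk. This yields (1, 3, 2) for
  "concentration of potassium" and (1, 3, 3, 2) for "concentration of
  simple chemical". The same provider is used for dictionary features, so
  dl_tf and dl_tp are commensurable; for plain noun-phrase labels it
  reduces to the head-final heuristic.

NER context phrases replace a recognized span with its entity-type label
inside the smallest enclosing constituent; a context phrase joins the
class-candidate pool if its best class association beats its best
predicate association (predicates scored by length-normalized similarity
against their local-name tokens), otherwise it is kept as predicate
evidence for ranking. The built-in NER adapter is a greedy
longest-match lexicon, sufficient for deterministic tests; real NER
models are deliberately out of the package.

### Thresholding and phrase selection

Associations with S < τ are removed; surviving phrases must carry at
least one association. Default τ = 0.5: a single shared term scored only
through the θ-weighted description feature reaches ≈ 0.22 under the
default weights, while any genuine label overlap scores well above 1, so
0.5 separates description-only noise from dictionary evidence without
suppressing partial label matches (e.g. "concentration" against
"concentration of chemical"). τ is fully configurable and the
threshold sweep in `scripts/acceptance.py` traces the whole
precision-recall curve rather than privileging the default.

Final phrases are chosen as the pairwise non-overlapping set maximizing,
in order: summed best association score, query tokens covered, and fewer
phrases, with a deterministic earliest-span tie-break. This is solved
exactly by weighted-interval scheduling over token spans; the test suite
checks it against brute-force subset enumeration. Score comes before
coverage deliberately: the full query span always covers everything yet
is usually a poor ontology match, and score-first selection is what makes
"concentration" + "potassium" + "extracellular space" beat the
whole-query phrase.

### RGI and SPARQL generation

Annotation documents (RDF/XML or Turtle) are parsed with rdflib. A root
is a subject that never occurs as an object (rdf:type scaffolding
excluded), overridable by an explicit root list; fragment-bearing roots
are keyed as document IRI + fragment. Ontology leaves are recognized by a
configurable namespace prefix map (OBO PURLs, identifiers.org,
MIRIAM-style URNs); unmatched terminal IRIs count as literals via their
local names. Blank nodes may appear inside trees but never in index keys:
paths are predicate sequences only. Cycles raise an error naming a node on
the cycle. The RGI is saved as versioned, content-addressed JSON
(`rgi-<sha256 prefix>.json`), so a rebuilt identical index maps to the
identical file; the CLI stores the dictionary beside it and rebuilds the
TFI at load time under the active configuration (WPL and stop words are
configuration-dependent, so baking a configured TFI to disk would pin
those choices).

Combinations assign one class to each final phrase (full Cartesian
product, capped at 64 combinations pruned lowest-score-first); a
combination is viable iff its classes share a root. Every realized choice
of one predicate path per class becomes a pattern, compiled to a single
SPARQL 1.1 `SELECT DISTINCT ?entity` basic graph pattern with fresh
interior variables in path-major order, plus one `FILTER NOT EXISTS`
clause asserting that `?entity` is not an object — entity roots are
non-objects by definition, and without the clause a pattern whose path is
a suffix of a longer chain would also bind interior nodes, breaking the
equivalence between SPARQL execution and index retrieval. Queries are
ranked by summed association score (summed once per class, not per path),
plus each matching predicate association's score added once per query;
ties break lexicographically on query text.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α, β | 3.0, 3.0 | weights of preferred label and synonym (dominant features) |
| γ, δ | 0.0, 0.0 | weights of definition and parent label |
| θ | 0.38 | weight of the entity-description feature |
| k1 | 2 | floor inside the dependency-level contribution (min 2) |
| k2 | 1 | factorial-normalizer offset (min 1) |
| τ | 0.5 | association filtering threshold |
| wpl | on | distribute preferred label into other features |
| dep | on | dependency-level similarity (off: length-normalized) |
| combination cap | 64 | max enumerated class combinations |

All are settable via `AnnotatorConfig` or a YAML config file
(`alpha, beta, gamma, delta, theta, k1, k2, tau, wpl, dep, parser,
stop_words`). The stop-word list is empty by default; normalization
lowercases, strips punctuation except '+'/'-' inside chemical tokens
("k+", "ca2+"), and applies no stemming.

## Synthetic data

The generator emulates the structure, not the scale, of annotated
repositories: classes with two-term labels drawn from chemical/anatomy
and physics vocabularies (distinct term sets, so planted labels are
unambiguous); 30% of classes lack each optional feature, exercising the
WPL path; entities annotated with 1–3 classes (matching how rarely real
entities carry more) through predicate chains of length 1–3 drawn from a
SemSim-flavored predicate pool; one description literal per entity built
from its class labels plus filler. Queries concatenate planted preferred
labels with connectives; noise swaps a label for the class's synonym at a
given rate. Everything is driven by a single seed and is byte-reproducible.

What passing tests on these fixtures show: the indexes, equations,
selection and composition are implemented exactly (oracle equivalence and
hand-derived values), and the pipeline is correct end-to-end on data
whose vocabulary matches the dictionary. What they do not show:
performance on real repositories, where labels are longer and morphology,
lexical variation (synonymy beyond the dictionary, hyponymy) and parser
quality dominate — the built-in chunker is a stand-in for a full
constituency parser and will chunk complex queries more crudely.

## Numerical and degenerate-input choices

* ln((|F|+k2)!) is computed via `lgamma` for stability.
* Empty features are rejected at construction; similarity against a
  zero-length feature is undefined by contract.
* Empty queries raise; unmatched phrases simply yield no associations;
  a τ above the maximum score yields an empty (not erroneous) result.
* Duplicate terms in a feature take the shallowest dependency level.
* All orderings (postings, paths, combinations, SPARQL text, rankings)
  are explicitly sorted, so identical inputs give identical bytes.

## Acceptance quantities

`scripts/acceptance.py` recomputes, at run time: the walkthrough counts
(6 candidate phrases, 3 selected, 8 combinations, 1 viable, 1 entity);
recovery precision/recall/F on 20 noiseless planted queries (40 classes,
25 entities); retrieval mAP@10 on planted queries; and AuC_PR from a
13-point τ sweep on synonym-noised queries. Problem sizes were chosen so
the whole script runs in about a second while every stage (indexing,
scoring, composition, execution) is exercised; the script asserts nothing
— it reports what the pipeline measures under the given seed.

## Known limitations

* No lexical semantics: "K+" only matches classes whose dictionary
  entries contain that token; hyponymy/synonymy beyond the dictionary is
  out of scope.
* Ranking is per generated SPARQL query, not per returned entity;
  entities retrieved by the same query tie.
* Index-free retrieval cannot see documents added after the last index
  rebuild; regenerating TFI and RGI is the intended refresh path.
* The group-wise query-log analysis (proportion-based query grouping) is
  documented but not implemented against real logs, which are not
  distributable.
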