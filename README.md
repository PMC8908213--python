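# nlq2sparql

Natural-language search over RDF-annotated biosimulation-model
repositories.

Biosimulation models (CellML, SBML) in repositories such as the Physiome
Model Repository and BioModels carry *composite* semantic annotations:
each model entity (a variable, component or species) is the root of a
small RDF tree whose leaves are ontology classes (GO, OPB, FMA, ChEBI, …)
connected through chains of predicates. Finding an entity therefore means
writing a SPARQL query that mirrors the annotation tree — something most
users cannot do. `nlq2sparql` translates a free-text query such as

> concentration of potassium in extracellular space

into ranked SPARQL queries, in two stages:

1. **Query annotation.** The query is chunked into candidate phrases, and
   each phrase is scored against ontology classes shortlisted by an
   inverted **Text Feature Index (TFI)** over class features (preferred
   label *pl*, synonyms *syn*, definition *def*, parent labels *par*, and
   the entity-description feature *desc*). The degree of association is

   ```
   S = α·S(P,pl) + β·S(P,syn) + γ·S(P,def) + δ·S(P,par) + θ·S_desc(P,desc)
   ```

   where the per-feature similarity weights overlapping terms by their
   *dependency level* (depth in the phrase's dependency tree + 1, so
   phrase heads count more) and normalizes by feature length:

   ```
   S(P,F) = Σ_{t∈P∩F} ln(max(k1, |F|+k1−max(dl_tp, dl_tf)))
            / ((1 + ln(max(1, |P|−|F|))/|F|) · ln((|F|+k2)!))
   ```

   Associations below a threshold τ are dropped, and a non-overlapping
   set of phrases covering the query is selected.

2. **SPARQL generation.** An **RDF Graph Index (RGI)** records which
   entity roots each ontology class annotates and by which predicate
   paths. Per-phrase class candidates are combined (Cartesian product),
   combinations with no common root are discarded, and every realized
   choice of predicate paths compiles to one SPARQL query, ranked by the
   summed degrees of association (plus predicate evidence from NER
   context phrases). Entities can also be retrieved straight from the
   index without running SPARQL.

## Worked example

Materialize the built-in fixtures (a synthetic repository plus the
single-entity miniature around `#K_e`, the extracellular potassium
concentration variable) and build its indexes:

```sh
nlq2sparql fixtures --out demo --seed 1
nlq2sparql index build \
    --ontology demo/worked_example/dictionary.tsv \
    --rdf demo/worked_example/ke_model.xml --out demo_idx
nlq2sparql annotate "concentration of potassium in extracellular space" --index demo_idx
```

prints the three selected phrases, each with its two candidate classes
and degree of association:

```
concentration	http://identifiers.org/opb/OPB_00592	3.678883
concentration	http://identifiers.org/opb/OPB_00340	2.835655
potassium	http://identifiers.org/chebi/CHEBI_29103	4.378962
potassium	http://identifiers.org/chebi/CHEBI_26216	2.074123
extracellular space	http://identifiers.org/fma/FMA_70022	5.135209
extracellular space	http://identifiers.org/fma/FMA_17555	3.678883
```

The chunker found six candidate phrases; the full query and the spans
"concentration of potassium" and "space" were discarded in favour of the
three phrases above (higher summed association without overlap). Of the
2×2×2 = 8 class combinations, only (OPB_00340, CHEBI_29103, FMA_70022)
matches an annotation pattern in the repository, so

```sh
nlq2sparql query "concentration of potassium in extracellular space" --index demo_idx
```

prints one ranked SPARQL query (score 12.349825, the sum of the three
winning associations) whose execution returns exactly
`http://models.example/ke_model.xml#K_e`; `--format entities` retrieves
the same root directly from the index.

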