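# cdmo — bilingual diabetes-ontology toolkit

`cdmo` is a Python library and CLI for building and applying a Chinese
disease ontology for diabetes mellitus. It is aimed at biomedical
knowledge engineers who need to bootstrap a bilingual (Chinese/English)
terminology from clinical-guideline text, align it with established
English ontologies such as SNOMED CT, and then put it to work in two
downstream applications: rule-based clinical decision support and
retrieval-augmented question answering.

The toolkit covers:

- **Ontology core** (`cdmo.onto_core`) — a named-class OWL subset
  (Chinese preferred labels, English names, synonyms, sourced
  definitions, annotations, `rdfs:subClassOf`) with Turtle / RDF-XML /
  JSON I/O, reflexive-transitive subsumption queries, a definition-source
  priority rule (termonline > Baidu Encyclopedia > CHPO > MedDRA), and a
  QC report (is_a cycles, orphans, missing definitions, duplicate
  labels, domain/range violations).
- **Term harvesting** (`cdmo.term_harvest`) — Aho-Corasick dictionary
  matching over a corpus with document-level frequency counting,
  grade/degree exclusion (``1级``, ``3期``, …), a conjunctive
  lexicon-presence AND ≥ *k*-documents filter, and union-find synonym
  merging via shared English names (``黑棘皮症``/``黑棘皮病`` → one
  concept for *acanthosis nigricans*).
- **Cross-lingual mapping** (`cdmo.crossmap`) — English-name lexical
  search against a target ontology (exact and normalized match types,
  word-order-insensitive keys, ``(disorder)``-suffix stripping) and
  mapping-based is_a **hierarchy induction**: when two mapped concepts'
  target classes stand in a subsumption relation inside one target
  ontology, the edge is transferred back, with cycle and conflict
  rejection and transitive reduction.
- **Rule engine** (`cdmo.rule_engine`) — a parser and semi-naive
  forward-chaining evaluator for SWRL-style positive Horn rules with
  subsumption-aware class atoms, numeric `swrlb:` builtins, unit-safe
  comparisons and per-derivation explanations. Four clinical rules for
  diabetes diagnosis, therapy, contraindication and diet ship in
  `cdmo/rules/diabetes_core.rules`.
- **QA knowledge injection** (`cdmo.qa_inject`) — Okapi BM25 retrieval
  of concept definitions as evidence, the prompt template
  ``Question: {Q}, Evidences: {D1}, …, {Dn}``, and character-level
  ROUGE-1/2/L F1 scoring.
- **Fixtures** (`cdmo.fixtures`) — seeded generators for a ~46-concept
  bilingual micro-ontology, an English target ontology with planted
  subsumptions, a corpus with controlled document frequencies, and
  patient ABoxes with known ground-truth inferences.

## Worked example

```python
from cdmo import fixtures, rule_engine

tbox = fixtures.make_micro_ontology(7)        # bilingual TBox, QC-clean
rules = rule_engine.load_rules(
    __import__("pathlib").Path(rule_engine.__file__).parent / "rules" / "diabetes_core.rules"
)

kb = rule_engine.KnowledgeBase(tbox)
from cdmo.fixtures import CANONICAL_INDIVIDUALS
from cdmo.onto_core import concept_iri
for name, zh in CANONICAL_INDIVIDUALS.items():
    kb.add_individual(name, concept_iri(zh))

kb.add_individual("patient_a", concept_iri("患者"))
for s in ("polyphagia", "polyuria", "polydipsia", "weight_loss"):
    kb.assert_object("patient_has_symptom", "patient_a", f"{s}_canonical")
kb.add_individual("fbg", concept_iri("空腹血糖测定"))
kb.assert_object("patient_has_test", "patient_a", "fbg")
kb.assert_data("test_has_value", "fbg", 8.0, "mmol/L")

result = rule_engine.forward_chain(kb, rules)
print(sorted(result.derived))
```

prints

```
[('obj', 'patient_has_diagnosis', 'patient_a', 'dm_canonical'),
 ('obj', 'patient_has_diagnosis', 'patient_a', 't2dm_canonical')]
```

meaning: a patient presenting polyphagia, polyuria, polydipsia and
weight loss with a fasting blood glucose of 8.0 mmol/L satisfies the
diagnosis rule (threshold ≥ 7.0 mmol/L), so the reasoner asserts a
diabetes-mellitus diagnosis — and, because class atoms match by
subsumption and the knowledge base carries one canonical individual per
diagnosable condition, the type-2 individual (a subclass of diabetes
mellitus) is diagnosed as well. `rule_engine.explain(result, fact)`
returns the firing rule, the full variable binding (here
``?v1 = 8.0 mmol/L``) and the rule's natural-language comment.

The same pipelines are available from the shell:

```bash
cdmo fixtures --seed 7 --out fx/
cdmo qc fx/micro_ontology.ttl --out report.json
cdmo infer --ontology fx/micro_ontology.json --patients fx/patients.json \
     --out inferred.json --explain
cdmo harvest --corpus fx/corpus.jsonl --lexicon fx/lexicon.tsv --min-docs 3 \
     --out candidates.csv
cdmo induce --source fx/micro_ontology.json --mappings fx/mappings.csv \
     --target fx/target_ontology.json --target-name SNOMEDCT --out edges.csv
cdmo retrieve --ontology fx/micro_ontology.json --question "糖尿病视网膜病变是什么" -n 3
```

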