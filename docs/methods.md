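# Methods

This note records what the package models, the defaults that matter and
why, what the synthetic fixtures do and do not emulate, and the design
choices made where the design was genuinely open.

## Ontology model

The ontology layer models the expressivity a terminology-centred
clinical ontology actually uses: named classes with a Chinese preferred
label (`rdfs:label@zh`), English names (`rdfs:label@en`), Chinese
synonyms (`skos:altLabel@zh`), one definition with a provenance source
(`skos:definition` plus a source annotation), free annotation properties
(e.g. ``正常参考值`` normal reference value, ``诊断切点`` diagnostic
cut-off), and simple named-class `rdfs:subClassOf` links. Class
expressions and restrictions in input files are skipped with a logged
warning, never an error; there is deliberately no tableau reasoner —
subsumption is reflexive-transitive reachability over parent links, and
consistency checking is the structural QC report below.

Concept IRIs are opaque (`cdmo:C` + SHA-1 prefix of the Chinese label)
so English names and synonyms can change without breaking links.
Chinese label lookup is exact and case-sensitive; English lookup is
case-insensitive and folds `_`, `-` and `/` to spaces so rule
predicates such as `glucagon_like_peptide_1_receptor_agonist` resolve
against "glucagon-like peptide-1 receptor agonist". Annotation and
property IRIs embed the UTF-8 hex of the Chinese name — unlike
percent-encoding this survives RDF/XML serialisation, whose predicates
must form valid XML QNames.

Definition selection follows a fixed source-priority order,
termonline > Baidu Encyclopedia > CHPO > MedDRA > manual, with list
order breaking ties within a source. The order is a data-quality
judgement (curated term bank over crowd encyclopedia over translated
phenotype/regulatory vocabularies), not a tunable.

The QC report checks: is_a cycles (every cycle listed), orphans
(non-root concepts with zero parents; the root set is the fixed
SNOMED-CT-style first level, so parentlessness elsewhere is a defect),
missing definitions, duplicate Chinese labels (exact string equality
only — near-duplicate detection is out of scope), and, given an ABox,
object-property assertions whose subject/object types do not fall under
the property's declared domain/range (subsumption-aware).

Round-trip guarantees: the JSON dialect mirrors the in-memory fields
exactly and round-trips losslessly; Turtle/RDF-XML round-trips preserve
concepts, labels, definitions, annotations, property declarations and
the edge multiset. Serialisation is deterministic (concepts and
properties sorted by IRI/name), so repeated saves are byte-identical.

## Term harvesting

Matching uses an Aho-Corasick automaton (trie + BFS failure links) over
raw Unicode codepoints with an NFC normalisation pass on both lexicon
and text — Chinese clinical text has no case, but OCR-derived text can
mix composed/decomposed forms. All overlapping hits are reported; the
test suite holds the automaton equal to a naive all-positions substring
scan on randomized inputs.

Pipeline order is part of the contract: scan → exclude → frequency
filter → synonym merge.

- Frequency is **document-level** (distinct documents containing the
  surface), not occurrence-level.
- The grade/degree exclusion removes full surfaces matching
  ``[digits or Chinese numerals][级期度型]`` plus an editable stoplist
  seeded with ``全部``. The published examples only illustrate the
  pattern; the regex plus stoplist is this package's operationalisation.
- The retention filter is conjunctive: a candidate survives only if a
  dictionary/term-bank/encyclopedia entry exists for it AND it appears
  in at least `min_docs` documents (default 3, the boundary inclusive).
- Synonym merging is union-find over "shares ≥ 1 English name" plus
  explicitly listed pairs; the canonical surface is the
  lexicographically smallest member, which absorbs the group's document
  sets. The ≥ `min_docs` threshold is applied **before** merging, with
  doc_ids re-aggregated per group afterwards; the alternative
  (merge-then-filter) is defensible but not what this package does.
- The neural NER stage that a production pipeline would add is
  represented by a pluggable term source (any iterable of candidates),
  not a model dependency.

## Cross-lingual mapping and hierarchy induction

Name normalisation lowercases, strips one trailing parenthesised
qualifier (the SNOMED CT "(disorder)", "(substance)" style), folds
punctuation to spaces, collapses whitespace and sorts tokens, so
translation variants like "hyperosmolar hyperglycemic state" /
"hyperglycemic hyperosmolar status" collide on one key. Token sorting
is on by default; an exact-order mode is a flag. Exact (case-sensitive,
raw-string) label hits rank before normalized hits; within a match type
results sort by target id, making proposal deterministic and
order-independent.

Hierarchy induction transfers target-ontology subsumptions back to the
source: for each pair of source concepts mapped into the **same** target
ontology, the edge child is_a parent is proposed when the target asserts
it. Evidence is never chained across two target ontologies — English
ontologies disagree about hierarchy often enough that mixed evidence is
unreliable. `direct` mode requires a direct target parent link;
`transitive` (the default) uses reachability and then transitively
reduces the proposal set, keeping the source graph minimal. Proposed
edges that would create a cycle are returned as `rejected_cycle`; edges
contradicting a pre-existing source edge (the proposed parent already
strictly below the child) are `rejected_conflict`; the source graph is
validated acyclic after every application. Similarity scores from
alignment tools are carried as metadata only, with no automatic
acceptance threshold: lexical aligners can score an outright wrong match
(a stage-2 disease against a stage-4 class) above 0.93, so acceptance
stays a human or structural decision.

## Rule engine

The rule dialect is positive Horn clauses: `name: atom ^ … -> atom ^ …`,
atoms `pred(arg, …)`, variables `?x`, numeric literals, `swrlb:`
builtins, optional `CDMO:`/`cdmo:` prefixes, both `->` and the
typographic `—>`. A stray right single quote after a predicate name (a
typesetting artifact that occurs in published rule tables) is stripped
so the affected atom unifies with its siblings. `#` comment lines above
a rule become its natural-language explanation, surfaced by
`explain()`. Consequents must not contain builtins and may not
introduce new variables; rule names are unique.

Semantics and evaluation:

- **Class atoms** match every individual whose asserted or derived type
  is the atom's class *or any subclass* (standard OWL instance
  semantics). Predicates are resolved against English names or Chinese
  labels of the TBox.
- **Property atoms** match the asserted property only, by default; a
  flag enables sub-property expansion over the declared property
  hierarchy. The shipped rules use leaf properties, so the default is
  off.
- **Data atoms** bind variables to value+unit pairs. Builtins
  (`greaterThanOrEqual`, `greaterThan`, `lessThanOrEqual`, `lessThan`,
  `equal`, `notEqual`) compare raw numbers exactly and raise if the two
  sides carry *different non-empty* units — no unit conversion is
  attempted; a unitless rule literal compares against any measured
  value. Builtins never bind variables; evaluation defers them until
  their arguments are bound.
- **Fixpoint** is set-at-a-time semi-naive: after the first pass, each
  rule is evaluated with one atom restricted to the previous pass's
  delta. Derived type and object assertions feed back until closure.
  The closure is idempotent (re-running derives nothing), monotone under
  added facts or rules, and independent of rule/assertion order; the
  test suite checks all three plus equivalence with an independent naive
  full-rescan evaluator. `max_iterations` (default 100) guards against
  pathological rule sets.
- Syntax cannot distinguish object from data properties; the evaluator
  dispatches on whether a predicate occurs among the knowledge base's
  data assertions.
- There is no negation, retraction or priority — every shipped rule is
  a positive Horn clause — and no DL-safety machinery beyond the
  grounded evaluation itself.

Diagnosable conditions, drugs, foods and therapies are represented as
one **canonical individual per class** in the ABox (e.g.
`dm_canonical` typed diabetes mellitus), mirroring instance-level
evaluation of such rule sets. A consequence worth knowing: a class atom
over diabetes mellitus matches both the diabetes individual and the
type-2 individual (subsumption), so a patient satisfying the diagnosis
rule receives both diagnosis assertions, and the derived type-2
diagnosis can cascade into the therapy rule when BMI ≥ 27. The fixture
generator's ground truth encodes exactly this closure.

Two quirks of the shipped rule file are preserved rather than repaired:
the diet rule tests `patient_has_diagnosis(?p, ?s1)` against a
hypoglycemia class atom (arguably a symptom property was meant), and
the therapy rule recommends both a GLP-1 receptor agonist and orlistat
even though prose descriptions of the same scenario sometimes mention
only the former. The engine evaluates the rules as written.

## QA knowledge injection

Retrieval is Okapi BM25 with the smoothed non-negative IDF
`log(1 + (N − df + 0.5)/(df + 0.5))`, defaults `k1 = 1.5`, `b = 0.75`
(the standard Okapi values) and `n = 3` evidences; all three are config
values, chosen once as conventional defaults rather than tuned.
Tokenisation defaults to overlapping character bigrams — robust for
Chinese without a word segmenter; a regex `word` mode (latin/digit runs
plus single CJK characters) exists for mixed text. Ties in ranking keep
document order, making retrieval fully deterministic. The prompt is the
exact template `Question: {Q}, Evidences: {D1}, …, {Dn}` with evidences
joined by `", "`; truncation to a model's context limit is the caller's
concern. The module's contract ends at the prompt string and at scoring
generated-vs-reference pairs: no language model is trained or invoked.

ROUGE-1/2 are F1 over clipped n-gram counts and ROUGE-L is F1 from the
longest common subsequence, computed at character level (the standard
unit for Chinese). Identical texts score 1.0 on all three (for ROUGE-2
this presupposes ≥ 2 tokens); character-disjoint texts score 0.0.

## Synthetic fixtures: what they emulate, and what they don't

The generators emulate *structure*, not *language*: the micro-ontology
(46 concepts under the SNOMED-CT-style first level, plus a social-context
root housing the patient class) carries real bilingual clinical
vocabulary but only a curated sliver of it; corpus documents are
planted-term concatenations with controlled document frequencies, not
guideline prose — so harvesting tests exercise counting, exclusion,
filtering and merging logic, not entity-boundary ambiguity; the target
ontology contains exactly the planted subsumption structure, so
induction recovery (precision = recall = 1.0) shows the transfer logic
is correct, not that real SNOMED CT mappings are this clean; patient
ABoxes place test values at threshold ± {0, 0.1, 1.0} including the
exact boundary. Passing these tests therefore demonstrates algorithmic
correctness under known conditions, and says nothing about NER quality,
translation quality or mapping precision on real corpora.

Each generator draws from its own `random.Random` stream derived from
the single seed (`seed × 1000003 + stream-id`, reduced mod 2³¹), so
generators cannot perturb one another; the two published worked
scenarios (four symptoms + fasting glucose 8.0 mmol/L; type 2 diabetes
+ BMI 28) are hard-coded, never sampled. The micro-ontology and target
ontology are fully determined constants — the seed parameter keeps the
generator signatures uniform.

Ground truth for patient inference is computed by closed-form
bookkeeping over the four rules (symptom-set completeness, threshold
comparisons, the canonical-individual cascade) — never by running the
engine — so engine tests against it are non-circular.

## Numerical and degenerate-input choices

- Threshold comparisons are exact floating-point (`≥ 7.0` fires at
  7.0); scanned glucose values are rounded to one decimal before
  assertion so `5.0 + 0.1·k` artifacts cannot straddle the boundary.
- Retention percentage is `round(100 × retained / recognized, 2)`.
- Empty inputs: empty definition-candidate list, empty lexicon, empty
  BM25 corpus, zero recognized terms, and empty-after-tokenisation
  ROUGE inputs all raise `ValueError`; an empty ontology file loads as
  an empty graph with a warning.
- Tie-breaks are lexicographic everywhere a canonical element is
  needed (synonym-group canonicals, serialisation order, mapping sort).

## Problem sizes

The shipped test suite and the acceptance script run at desk scale by
design: 50-node random DAGs for subsumption, 200 random automaton
cases, ≤ 50-individual knowledge bases, a 10-document BM25 fixture, a
51-value glucose scan and a 16-value BMI scan. These sizes make every
brute-force oracle exact and keep the full suite in seconds.

## Known limitations

- No OWL-DL reasoning: restrictions, equivalence axioms and property
  characteristics are ignored on load.
- Duplicate-label QC is exact-string only.
- The rule dialect has no negation-as-failure, so "absence of a
  finding" cannot be expressed; the shipped rules do not need it.
- BM25 length normalisation means adding matched terms to a document
  interacts with document length; scores are comparable within one
  corpus only.
- Cross-lingual mapping proposal is purely lexical over supplied
  English names; translation itself is out of scope, and a concept with
  no English names yields no proposals (flagged for manual
  translation).
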